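"""Surface-EMG conditioning.

The standard four-step chain that turns a raw interference signal into a
normalized linear envelope:

1. zero-lag high-pass Butterworth (30 Hz) to remove motion artifact,
2. full-wave rectification,
3. zero-lag low-pass Butterworth (2 Hz) — or, alternatively, a moving
   average (MAV) over a 0.25–0.5 s window,
4. division by the peak of the maximum-voluntary-contraction (MVC) trial.

"Zero-lag Nth order" means forward–backward application of an N/2-order
Butterworth design, so the net magnitude response is order N and the phase
response is identically zero.  A ``zero_phase=False`` switch runs a
single-direction order-N filter instead, for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .series import UniformSeries


@dataclass(frozen=True)
class EnvelopeConfig:
    """Parameters of the EMG conditioning chain.

    ``hp_order`` / ``lp_order`` are the *net* orders of the zero-lag
    filters (each realized as a half-order design run forward–backward).
    When ``mav_window`` is set, it replaces the low-pass step with a
    centered moving average of that length in seconds.
    """

    hp_cutoff: float = 30.0
    hp_order: int = 4
    lp_cutoff: float = 2.0
    lp_order: int = 2
    mav_window: float | None = None
    mvc_peak: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lp_cutoff < self.hp_cutoff):
            raise ValueError(
                f"need 0 < lp_cutoff < hp_cutoff, got {self.lp_cutoff}, {self.hp_cutoff}"
            )
        if self.mvc_peak is not None and not (self.mvc_peak > 0):
            raise ValueError(f"mvc_peak must be positive, got {self.mvc_peak}")


def butter_coefficients(cutoff: float, order: int, kind: str, fs: float):
    """Single-pass Butterworth (b, a) used by :func:`zero_lag_butterworth`.

    Exposed so tests can build an independent frequency-response oracle
    from the same coefficients.
    """
    if kind not in ("high", "low"):
        raise ValueError(f"kind must be 'high' or 'low', got {kind!r}")
    if not (0 < cutoff < fs / 2):
        raise ValueError(f"cutoff {cutoff} Hz must lie below the Nyquist {fs / 2} Hz")
    return sps.butter(order, cutoff, btype=kind, fs=fs)


def zero_lag_butterworth(
    x: UniformSeries,
    cutoff: float,
    order: int,
    kind: str,
    zero_phase: bool = True,
) -> UniformSeries:
    """Zero-phase Butterworth filter of net ``order``.

    The filter is designed at order ``order // 2`` and applied forward and
    backward (``filtfilt``), so the magnitude response is the squared
    single-pass response and the phase shift is zero.  Startup transients
    are suppressed by reflected padding of length 3x the filter order.
    """
    if zero_phase:
        if order < 2 or order % 2:
            raise ValueError(f"zero-lag net order must be even and >= 2, got {order}")
        design_order = order // 2
    else:
        design_order = order
    b, a = butter_coefficients(cutoff, design_order, kind, x.fs)
    min_len = 3 * order + 1
    if len(x) < min_len:
        raise ValueError(f"series too short for filtering: {len(x)} < {min_len} samples")
    if zero_phase:
        padlen = min(3 * max(len(a), len(b)), len(x) - 1)
        y = sps.filtfilt(b, a, x.values, padlen=padlen)
    else:
        y = sps.lfilter(b, a, x.values)
    return x.with_values(y)


def rectify(x: UniformSeries) -> UniformSeries:
    """Full-wave rectification (elementwise absolute value)."""
    return x.with_values(np.abs(x.values))


def moving_average(x: UniformSeries, window_s: float) -> UniformSeries:
    """Centered moving average; edge windows shrink to the valid range.

    Shrinking (rather than padding) keeps the output inside the range of
    the input at the edges.
    """
    n_win = int(round(window_s / x.dt))
    if n_win < 1:
        raise ValueError(
            f"mav_window {window_s}s is shorter than one sample at dt={x.dt}s"
        )
    half = n_win // 2
    csum = np.concatenate(([0.0], np.cumsum(x.values)))
    idx = np.arange(len(x))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx - half + n_win, len(x))
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return x.with_values(out)


def envelope(x_rectified: UniformSeries, cfg: EnvelopeConfig) -> UniformSeries:
    """Linear envelope of a rectified signal.

    Moving average when ``cfg.mav_window`` is set, otherwise a zero-lag
    low-pass at ``cfg.lp_cutoff``.
    """
    if cfg.mav_window is not None:
        return moving_average(x_rectified, cfg.mav_window)
    return zero_lag_butterworth(x_rectified, cfg.lp_cutoff, cfg.lp_order, "low")


def normalize_mvc(x: UniformSeries, mvc_peak: float) -> UniformSeries:
    """Divide by the MVC-trial envelope peak."""
    if not (mvc_peak > 0):
        raise ValueError(f"mvc_peak must be positive, got {mvc_peak}")
    return x.with_values(x.values / mvc_peak)


def process_emg(
    raw: UniformSeries, cfg: EnvelopeConfig, mvc_peak: float | None = None
) -> UniformSeries:
    """Full conditioning chain: high-pass, rectify, envelope, normalize.

    ``mvc_peak`` overrides ``cfg.mvc_peak``; when neither is given the
    un-normalized envelope is returned (as needed to process the MVC trial
    itself, whose own peak then defines the normalizer).
    """
    hp = zero_lag_butterworth(raw, cfg.hp_cutoff, cfg.hp_order, "high")
    env = envelope(rectify(hp), cfg)
    peak = mvc_peak if mvc_peak is not None else cfg.mvc_peak
    if peak is None:
        return env
    return normalize_mvc(env, peak)
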