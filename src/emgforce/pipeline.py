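"""End-to-end estimation: raw EMG channels -> normalized joint torque.

The flow mirrors the estimation chain: envelope extraction and MVC
normalization, activation dynamics, the chosen contractile-element
model per muscle, projection through pennation and moment arm, summation
and MVC-torque normalization.  An MVC trial is processed first to fix
the per-muscle envelope peaks, the chemical thresholds and the torque
normalizer, which are then reused for every other trial of the session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import ActivationParams, muscle_activation, neural_activation
from .emg import moving_average, process_emg, rectify, zero_lag_butterworth
from .hill import simulate_hill
from .joint import muscle_torque
from .physio import make_chemical_input, recruitment_alpha, simulate_physio
from .config import RunConfig
from .series import UniformSeries


@dataclass(frozen=True)
class MvcReference:
    """Normalizers extracted from the MVC trial."""

    env_peaks: dict[str, float]
    chem_peaks: dict[str, float]
    torque_peak: float


#: Moving-average window (s) used to read the MVC level off a stochastic
#: envelope.  The raw sample maximum of an interference-EMG envelope is
#: biased upward by its own fluctuations (extreme-value bias of order
#: +1.5 sd over a few-second hold), which would deflate every normalized
#: estimate; the highest windowed mean is the standard robust peak.
MVC_PEAK_WINDOW_S = 1.0


def _robust_peak(x: UniformSeries, window_s: float = MVC_PEAK_WINDOW_S) -> float:
    return float(moving_average(x, min(window_s, x.duration)).values.max())


@dataclass(frozen=True)
class EstimationResult:
    per_muscle_torque: dict[str, UniformSeries]  # N*m
    torque: UniformSeries  # summed, N*m
    normalized: UniformSeries | None  # torque / MVC torque peak


def _chem_envelope_peak(raw: UniformSeries, cfg: RunConfig) -> float:
    hp = zero_lag_butterworth(raw, cfg.envelope.hp_cutoff, cfg.envelope.hp_order, "high")
    env = zero_lag_butterworth(rectify(hp), 30.0, 2, "low")
    return _robust_peak(env)


def _activation_params(cfg: RunConfig, dt: float) -> ActivationParams:
    return ActivationParams.from_seconds(
        dt,
        d_s=cfg.activation.d_ms / 1000.0,
        C1=cfg.activation.C1,
        C2=cfg.activation.C2,
        A=cfg.activation.A,
    )


def estimate_torque(
    emg: dict[str, UniformSeries],
    cfg: RunConfig,
    mvc: MvcReference | None,
    model: str | None = None,
    A: float | None = None,
) -> EstimationResult:
    """Run one estimator on a trial's EMG channels.

    ``mvc=None`` processes without normalization (used to bootstrap the
    MVC reference itself).  ``A`` overrides the configured shape factor
    (calibration loop).
    """
    model = model or cfg.model
    A = cfg.activation.A if A is None else A
    dt_int = cfg.physio.dt_int_ms / 1000.0
    per_muscle: dict[str, UniformSeries] = {}
    for name, raw in emg.items():
        mt = cfg.muscles[name]
        env_peak = mvc.env_peaks[name] if mvc else None
        e = process_emg(raw, cfg.envelope, mvc_peak=env_peak)
        if mvc:
            e = e.with_values(np.clip(e.values, 0.0, 1.0))
        ap = _activation_params(cfg, raw.dt)
        p = neural_activation(e, ap)
        p = p.with_values(np.clip(p.values, 0.0, 1.0))
        if model == "hill_linear":
            fc = simulate_hill(p, mt, dt_int=dt_int).Fc
        elif model == "hill_nonlinear":
            fc = simulate_hill(muscle_activation(p, A), mt, dt_int=dt_int).Fc
        elif model == "physio":
            pp = cfg.physio_params(name)
            chem_peak = mvc.chem_peaks[name] if mvc else _chem_envelope_peak(raw, cfg)
            drive = make_chemical_input(
                raw,
                cfg.envelope,
                threshold=cfg.physio.threshold_frac_mvc * chem_peak,
                Uc=pp.Uc,
                Ur=pp.Ur,
                delay_samples=ap.d,
            )
            alpha = recruitment_alpha(p, drive.pi_c, mode=cfg.physio.recruitment_mode)
            fc = simulate_physio(drive, alpha, pp, dt_int=dt_int).Fc
        else:
            raise ValueError(f"unknown model {model!r}")
        per_muscle[name] = muscle_torque(fc, mt.phi, cfg.moment_arms[name])

    names = list(per_muscle)
    total = per_muscle[names[0]].with_values(
        np.sum([per_muscle[n].values for n in names], axis=0)
    )
    normalized = None
    if mvc is not None:
        normalized = total.with_values(total.values / mvc.torque_peak)
    return EstimationResult(per_muscle_torque=per_muscle, torque=total, normalized=normalized)


def mvc_reference(
    mvc_emg: dict[str, UniformSeries],
    cfg: RunConfig,
    model: str | None = None,
    A: float | None = None,
) -> MvcReference:
    """Extract envelope peaks, chemical thresholds and the MVC torque
    peak from the MVC trial by running the estimator on it."""
    env_peaks = {
        name: _robust_peak(process_emg(raw, cfg.envelope))
        for name, raw in mvc_emg.items()
    }
    chem_peaks = {name: _chem_envelope_peak(raw, cfg) for name, raw in mvc_emg.items()}
    partial = MvcReference(env_peaks=env_peaks, chem_peaks=chem_peaks, torque_peak=1.0)
    res = estimate_torque(mvc_emg, cfg, partial, model=model, A=A)
    return MvcReference(
        env_peaks=env_peaks,
        chem_peaks=chem_peaks,
        torque_peak=_robust_peak(res.torque),
    )
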