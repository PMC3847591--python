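"""Uniformly sampled scalar time series.

A single light container carries every signal in the pipeline: raw EMG,
rectified EMG, envelopes, neural/muscle activation, chemical input,
contractile force, stiffness, strain and joint torque.  Keeping one type
for all of them makes it trivial to assert that two stages share a time
base before combining them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    dt : float
        Seconds per sample, strictly positive.
    values : numpy.ndarray
        Samples, 1-D, finite.  Sample ``k`` is taken at ``t0 + k * dt``.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a 1-D array with at least one sample")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (len(self) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        """A new series on the same time base with replaced samples."""
        return UniformSeries(dt=self.dt, values=np.asarray(values, dtype=float), t0=self.t0)

    def same_base(self, other: "UniformSeries", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.dt, other.dt, rtol=rtol)
            and np.isclose(self.t0, other.t0, rtol=rtol, atol=1e-12)
        )


def require_same_base(*series: UniformSeries) -> None:
    """Raise ``ValueError`` unless all series share dt, t0 and length."""
    first = series[0]
    for s in series[1:]:
        if not first.same_base(s):
            raise ValueError(
                "series do not share a time base: "
                f"(dt={first.dt}, n={len(first)}) vs (dt={s.dt}, n={len(s)})"
            )


def constant_like(template: UniformSeries, value: float) -> UniformSeries:
    return template.with_values(np.full(len(template), float(value)))
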