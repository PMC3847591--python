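"""Joint-level assembly and evaluation.

Per-muscle contractile forces are projected on the tendon axis
(cos(phi)), multiplied by the muscle's plantar-flexion moment arm, and
summed into an ankle torque, which is then compared with the measured
torque on an MVC-normalized scale.  Also here: RMS and peak error
metrics, the anatomical contribution ratio of the muscles, and the
calibration of the nonlinear shape factor A against an MVC trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .series import UniformSeries, require_same_base

#: Plantar-flexion moment arms [m] at the measured posture.
DEFAULT_MOMENT_ARMS = {"gas": 0.0515, "sol": 0.0464}


@dataclass(frozen=True)
class JointConfig:
    """Moment arms, per-muscle pennation angles and Fm0, MVC torque.

    ``muscles`` maps a muscle name to a ``(Fm0, phi, moment_arm)``
    triple; ``mvc_torque`` (N*m) normalizes the summed torque.
    """

    muscles: dict[str, tuple[float, float, float]]
    mvc_torque: float | None = None

    def __post_init__(self) -> None:
        if not self.muscles:
            raise ValueError("at least one muscle is required")
        for name, (fm, phi, arm) in self.muscles.items():
            if arm <= 0 or fm <= 0:
                raise ValueError(f"invalid parameters for muscle {name!r}")


def muscle_torque(Fc: UniformSeries, phi: float, moment_arm: float) -> UniformSeries:
    """Joint torque of one muscle: tendon-axis force times moment arm."""
    return Fc.with_values(Fc.values * np.cos(phi) * moment_arm)


def contribution_ratio(cfg: JointConfig) -> dict[str, float]:
    """Anatomical torque share of each muscle at maximal force.

    fraction_i = Fm0_i cos(phi_i) arm_i / sum_j Fm0_j cos(phi_j) arm_j;
    the fractions sum to 1 exactly (round only at reporting time).
    """
    if len(cfg.muscles) < 2:
        raise ValueError("contribution ratio needs at least two muscles")
    weights = {
        name: fm * np.cos(phi) * arm for name, (fm, phi, arm) in cfg.muscles.items()
    }
    total = sum(weights.values())
    return {name: w / total for name, w in weights.items()}


def normalized_sum_torque(
    per_muscle: Sequence[UniformSeries], cfg: JointConfig
) -> UniformSeries:
    """Sum of per-muscle torques divided by the MVC torque."""
    if cfg.mvc_torque is None or cfg.mvc_torque <= 0:
        raise ValueError(f"mvc_torque must be positive, got {cfg.mvc_torque}")
    require_same_base(*per_muscle)
    total = np.sum([t.values for t in per_muscle], axis=0)
    return per_muscle[0].with_values(total / cfg.mvc_torque)


def rms_error(
    estimated: UniformSeries,
    measured: UniformSeries,
    window: tuple[int, int] | None = None,
) -> float:
    """Root-mean-square difference over an index window (whole trial
    when omitted)."""
    require_same_base(estimated, measured)
    diff = estimated.values - measured.values
    if window is not None:
        diff = diff[window[0] : window[1]]
    if diff.size == 0:
        raise ValueError("empty evaluation window")
    return float(np.sqrt(np.mean(diff**2)))


def peak_error(
    estimated: UniformSeries,
    measured: UniformSeries,
    burst_window: tuple[int, int],
) -> float:
    """Absolute difference of the window maxima (alignment-insensitive)."""
    require_same_base(estimated, measured)
    lo, hi = burst_window
    est = estimated.values[lo:hi]
    mea = measured.values[lo:hi]
    if est.size == 0:
        raise ValueError("empty burst window")
    return float(abs(est.max() - mea.max()))


def calibrate_shape_factor(
    measured_mvc: UniformSeries,
    model_runner: Callable[[float], UniformSeries],
    bounds: tuple[float, float] = (-3.0, -1e-6),
    xatol: float = 1e-4,
) -> float:
    """Shape factor A minimizing the RMS error on the MVC trial.

    ``model_runner`` maps a candidate A in [-3, 0) to the estimated
    (normalized) torque series; bounded scalar minimization makes the
    result deterministic given the inputs.
    """

    def objective(A: float) -> float:
        err = rms_error(model_runner(A), measured_mvc)
        if not np.isfinite(err):
            raise RuntimeError(f"non-finite calibration objective at A={A}")
        return err

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    # the bounded minimizer does not probe the boundary itself
    best = float(res.x)
    for edge in bounds:
        if objective(edge) < res.fun:
            best = edge
    return best
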