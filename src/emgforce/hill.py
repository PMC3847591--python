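"""Hill-type contractile element with a series linear tendon.

The muscle-tendon unit is a contractile element (CE) of rest length Lc0,
pennated at angle phi, in series with a linear tendon of stiffness kt and
rest length Lt0.  Under isometric conditions the whole-unit length is
fixed at Lc0*cos(phi) + Lt0, so any CE shortening (strain eps_c < 0)
stretches the tendon.  The CE force is

    Fc = a(t) * fl(eps_c) * fv(deps_c/dt) * Fm,

with a Gaussian force-length relation fl(eps) = exp(-(eps/b)^2) and a
hyperbolic concentric force-velocity relation

    fv(v) = Vsh * (vmax + Lc0 v) / (Vsh * vmax - Lc0 v),   v = deps_c/dt.

At each step the tendon/CE force balance Ft = Fc*cos(phi) is solved for
the required fv, which is inverted algebraically to the CE strain rate;
the strain is then advanced by classical 4th-order Runge-Kutta.  Only
concentric contraction is modeled: when the balance would require fv > 1
(lengthening), fv is clamped at 1 and the strain is held; the fraction of
steps where this engages is reported.  No parallel elastic element is
included (its length does not change isometrically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .series import UniformSeries

#: Floor applied to fv before inversion, to stay away from the pole at
#: maximum shortening speed.
FV_FLOOR = 1e-3

#: Activation*fl*Fm below this fraction of Fm is treated as a slack CE.
_SLACK_FRAC = 1e-9


@dataclass(frozen=True)
class MuscleTendonParams:
    """Macroscopic muscle-tendon constants shared by all three models.

    Units: Fm0 [N], Lc0/Lt0 [m], phi [rad], kt [N/m], vmax [m/s];
    b and Vsh are dimensionless.
    """

    Fm0: float
    Lc0: float
    Lt0: float
    phi: float
    kt: float = 180e3
    b: float = 0.5
    Vsh: float = 0.3
    vmax: float | None = None  # default 10*Lc0 per second

    def __post_init__(self) -> None:
        for name in ("Fm0", "Lc0", "Lt0", "kt", "b", "Vsh"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.phi < math.pi / 2):
            raise ValueError(f"pennation must lie in [0, pi/2), got {self.phi}")
        if self.vmax is None:
            object.__setattr__(self, "vmax", 10.0 * self.Lc0)
        elif not (self.vmax > 0):
            raise ValueError("vmax must be strictly positive")

    @property
    def cos_phi(self) -> float:
        return math.cos(self.phi)

    @classmethod
    def gastrocnemius(cls, **overrides) -> "MuscleTendonParams":
        """Medial+lateral gastrocnemius (two heads pooled through Fm0)."""
        base = dict(Fm0=1600.0, Lc0=0.051, Lt0=0.40, phi=math.radians(14.0))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def soleus(cls, **overrides) -> "MuscleTendonParams":
        base = dict(Fm0=2830.0, Lc0=0.030, Lt0=0.268, phi=math.radians(30.0))
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class HillTrace:
    """Output of :func:`simulate_hill`."""

    Fc: UniformSeries
    eps_c: UniformSeries
    fv_clamped_fraction: float


def force_length(eps_c: float, b: float) -> float:
    """Gaussian force-length relation, maximal at the optimal length."""
    return float(np.exp(-((np.asarray(eps_c) / b) ** 2)))


def force_velocity(eps_c_dot: float, params: MuscleTendonParams) -> float:
    """Concentric force-velocity relation; 1 at rest, 0 at -vmax/Lc0.

    Velocities at or beyond the maximum shortening speed clamp to 0.
    """
    v = params.Lc0 * eps_c_dot
    if v <= -params.vmax:
        return 0.0
    return params.Vsh * (params.vmax + v) / (params.Vsh * params.vmax - v)


def invert_force_velocity(fv: float, params: MuscleTendonParams) -> float:
    """Algebraic inverse of :func:`force_velocity`.

    Maps fv = 1 to zero strain rate and fv -> 0+ to -vmax/Lc0.
    """
    if fv <= 0:
        raise ValueError(f"fv must be positive, got {fv}")
    return params.Vsh * params.vmax * (fv - 1.0) / (params.Lc0 * (params.Vsh + fv))


def tendon_force(eps_c: float, params: MuscleTendonParams) -> float:
    """Series tendon force under isometric whole-unit length.

    Lt - Lt0 = -Lc0 * eps_c * cos(phi); a slack tendon carries no load.
    """
    return max(-params.kt * params.Lc0 * eps_c * params.cos_phi, 0.0)


def _strain_rate(eps_c: float, a: float, params: MuscleTendonParams) -> tuple[float, bool]:
    """CE strain rate from the instantaneous force balance.

    Returns (deps_c/dt, clamped) where ``clamped`` marks the fv = 1 clamp
    (required fv >= 1, i.e. the concentric relation cannot balance).
    """
    capacity = a * force_length(eps_c, params.b) * params.Fm0
    if capacity < _SLACK_FRAC * params.Fm0:
        # inactive CE: no force, and (concentric-only) no strain recovery;
        # flagged as clamped whenever the tendon still carries load
        return 0.0, tendon_force(eps_c, params) > 0.0
    fv_req = tendon_force(eps_c, params) / (params.cos_phi * capacity)
    if fv_req >= 1.0:
        return 0.0, True
    return invert_force_velocity(max(fv_req, FV_FLOOR), params), False


def simulate_hill(
    a: UniformSeries,
    params: MuscleTendonParams,
    dt_int: float = 1e-3,
    eps_c_limit: float = 0.5,
) -> HillTrace:
    """Integrate the Hill CE strain under isometric whole-unit length.

    Activation is held zero-order within each integration step of length
    ``dt_int``; traces are returned on the input time base.  From rest
    with a = 0 the state is a fixed point and the force is identically 0.
    """
    vals = a.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("activation contains non-finite samples")
    n_int = max(int(round(a.duration / dt_int)), 1) + 1
    t_int = a.t0 + dt_int * np.arange(n_int)
    idx = np.minimum(((t_int - a.t0) / a.dt).astype(int), len(a) - 1)
    a_int = vals[idx]

    eps = 0.0
    eps_trace = np.empty(n_int)
    n_clamped = 0
    for k in range(n_int):
        eps_trace[k] = eps
        if k == n_int - 1:
            break
        ak = a_int[k]
        k1, c1 = _strain_rate(eps, ak, params)
        k2, _ = _strain_rate(eps + 0.5 * dt_int * k1, ak, params)
        k3, _ = _strain_rate(eps + 0.5 * dt_int * k2, ak, params)
        k4, _ = _strain_rate(eps + dt_int * k3, ak, params)
        eps += dt_int * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        n_clamped += c1
        if abs(eps) > eps_c_limit:
            raise RuntimeError(
                f"CE strain {eps:.3f} beyond physical limit {eps_c_limit} "
                f"at step {k} (t = {t_int[k]:.4f} s)"
            )

    # report Fc = a * fl * fv * Fm with the per-sample balanced (clamped) fv
    fc_trace = np.empty(n_int)
    for k in range(n_int):
        ak = a_int[k]
        capacity = ak * force_length(eps_trace[k], params.b) * params.Fm0
        if capacity < _SLACK_FRAC * params.Fm0:
            fc_trace[k] = 0.0
            continue
        fv_req = tendon_force(eps_trace[k], params) / (params.cos_phi * capacity)
        fc_trace[k] = capacity * min(fv_req, 1.0)

    fc_out = np.interp(a.times, t_int, fc_trace)
    eps_out = np.interp(a.times, t_int, eps_trace)
    return HillTrace(
        Fc=a.with_values(fc_out),
        eps_c=a.with_values(eps_out),
        fv_clamped_fraction=n_clamped / max(n_int - 1, 1),
    )
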