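"""Multi-scale cross-bridge contractile element.

Instead of the memoryless Hill relation, the contractile element is
driven by two inputs derived from the EMG:

* a *chemical input* u(t) that switches the cross-bridge cycling rate
  between contraction (Uc) and relaxation (Ur) kinetics, obtained by
  thresholding a 30 Hz envelope of the rectified EMG; and
* a *recruitment rate* alpha(t) in [0, 1], the fraction of motor units
  engaged, taken from the neural activation p(t).

Aggregating the two-state (attached/detached) cross-bridge population
with bond-length-independent rates yields exact ODEs for the first two
distribution moments — the active stiffness kc and the contractile force
Fc:

    dkc/dt = -(u + |deps_c/dt|) kc + alpha * km(eps_c) * Pi_c * Uc
    dFc/dt = -(u + |deps_c/dt|) Fc + alpha * Fm(eps_c) * Pi_c * Uc
             + kc * Lc0 * deps_c/dt

where km(eps) = km0 * fl(eps) and Fm(eps) = Fm0 * fl(eps) carry the
force-length relation at the microscopic scale (it limits the number of
available actin/myosin sites).  Coupling with the series tendon under a
prescribed whole-unit velocity gives the strain rate algebraically:

    deps_c/dt = T / (kt Lc0 / cos(phi) + kc Lc0 - sign(T) Fc),
    T = kt L0 v / cos(phi) + Fc u - alpha Fm(eps_c) Pi_c Uc,

valid while kt Lc0/cos(phi) + kc Lc0 - Fc > 0.  The detachment rate
grows with speed in *either* direction (faster sliding breaks more
bridges), hence |deps_c/dt| in the loss terms; this is also what makes
the strain-rate denominator above carry the sign factor.

Because the force *derivative* is driven by the neural command, peak
force depends on contraction duration, not just envelope amplitude —
the time hysteresis that a Hill model cannot represent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hill import MuscleTendonParams, force_length
from .emg import EnvelopeConfig, rectify, zero_lag_butterworth
from .series import UniformSeries, require_same_base

#: Chemical kinetic rates (1/s): contraction and relaxation cycling.
DEFAULT_UC = 5.0
DEFAULT_UR = 10.0

#: Maximum active stiffness as a multiple of Fm0: the muscle's active
#: stiffness reaches the tendon stiffness near maximal contraction.
DEFAULT_KM_OVER_FM = 20.0

#: Chemical threshold as a fraction of the MVC peak of the 30 Hz
#: envelope; anywhere "a little above baseline" works.
DEFAULT_THRESHOLD_FRAC = 0.05


@dataclass(frozen=True)
class PhysioParams:
    """Constants of the multi-scale contractile element.

    ``km0`` defaults to 20*Fm0 (active stiffness reaching the tendon
    stiffness near maximum contraction); the macroscopic constants are
    shared with the Hill branch.
    """

    Fm0: float
    Lc0: float
    Lt0: float
    phi: float
    kt: float = 180e3
    b: float = 0.5
    Uc: float = DEFAULT_UC
    Ur: float = DEFAULT_UR
    km0: float | None = None

    def __post_init__(self) -> None:
        for name in ("Fm0", "Lc0", "Lt0", "kt", "b", "Uc", "Ur"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.phi < math.pi / 2):
            raise ValueError(f"pennation must lie in [0, pi/2), got {self.phi}")
        if self.km0 is None:
            object.__setattr__(self, "km0", DEFAULT_KM_OVER_FM * self.Fm0)
        elif not (self.km0 > 0):
            raise ValueError("km0 must be strictly positive")

    @property
    def cos_phi(self) -> float:
        return math.cos(self.phi)

    @classmethod
    def from_muscle(cls, mt: MuscleTendonParams, **overrides) -> "PhysioParams":
        base = dict(Fm0=mt.Fm0, Lc0=mt.Lc0, Lt0=mt.Lt0, phi=mt.phi, kt=mt.kt, b=mt.b)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ChemicalDrive:
    """Contraction indicator Pi_c(t) and switched kinetic rate u(t)."""

    pi_c: UniformSeries
    u: UniformSeries
    threshold: float
    lp_cutoff: float = 30.0

    def __post_init__(self) -> None:
        require_same_base(self.pi_c, self.u)
        if not np.all(np.isin(self.pi_c.values, (0.0, 1.0))):
            raise ValueError("pi_c must be binary")


@dataclass(frozen=True)
class PhysioState:
    """Internal state (kc, Fc, eps_c) of the contractile element."""

    kc: float = 0.0
    Fc: float = 0.0
    eps_c: float = 0.0


@dataclass(frozen=True)
class PhysioTrace:
    Fc: UniformSeries
    kc: UniformSeries
    eps_c: UniformSeries
    n_clipped: int = 0


def chemical_drive_from_indicator(
    pi_c: UniformSeries, Uc: float = DEFAULT_UC, Ur: float = DEFAULT_UR,
    threshold: float = 0.0, lp_cutoff: float = 30.0,
) -> ChemicalDrive:
    """Build a drive directly from a binary contraction indicator."""
    u = pi_c.with_values(pi_c.values * Uc + (1.0 - pi_c.values) * Ur)
    return ChemicalDrive(pi_c=pi_c, u=u, threshold=threshold, lp_cutoff=lp_cutoff)


def make_chemical_input(
    emg_raw: UniformSeries,
    cfg: EnvelopeConfig | None = None,
    threshold: float = 0.0,
    Uc: float = DEFAULT_UC,
    Ur: float = DEFAULT_UR,
    lp_cutoff: float = 30.0,
    delay_samples: int = 0,
) -> ChemicalDrive:
    """Chemical input by thresholding a 30 Hz envelope of the raw EMG.

    Pipeline: zero-lag high-pass (artifact removal) -> rectify ->
    zero-lag low-pass at ``lp_cutoff`` -> threshold -> u(t) switched
    between Uc (contraction) and Ur (relaxation).  ``delay_samples``
    shifts the indicator to account for the electromechanical delay.
    A threshold above the global maximum yields Pi_c identically 0
    (warning case handled by the caller); it is not an error.
    """
    if not (threshold > 0):
        raise ValueError(f"threshold must be positive, got {threshold}")
    cfg = cfg or EnvelopeConfig()
    hp = zero_lag_butterworth(emg_raw, cfg.hp_cutoff, cfg.hp_order, "high")
    env = zero_lag_butterworth(rectify(hp), lp_cutoff, 2, "low")
    pi = (env.values > threshold).astype(float)
    if delay_samples > 0:
        pi = np.concatenate([np.zeros(delay_samples), pi[:-delay_samples]])
    pi_c = emg_raw.with_values(pi)
    return chemical_drive_from_indicator(
        pi_c, Uc=Uc, Ur=Ur, threshold=threshold, lp_cutoff=lp_cutoff
    )


def recruitment_alpha(
    p: UniformSeries, pi_c: UniformSeries, mode: str = "continuous"
) -> UniformSeries:
    """Recruitment ratio from neural activation.

    ``continuous`` uses p(t) sample by sample.  The per-phase variants
    freeze alpha over each Pi_c = 1 run: ``hold_at_onset`` at the value
    of p when the phase starts, ``hold_phase_max`` at the maximum of p
    over the phase.  Outside contraction phases alpha follows p (it is
    gated by Pi_c in the dynamics anyway).
    """
    require_same_base(p, pi_c)
    vals = np.clip(p.values, 0.0, 1.0)
    if mode == "continuous":
        return p.with_values(vals)
    if mode not in ("hold_at_onset", "hold_phase_max"):
        raise ValueError(f"unknown recruitment mode {mode!r}")
    out = vals.copy()
    active = pi_c.values > 0.5
    # run-length scan over contraction phases
    starts = np.flatnonzero(active & ~np.concatenate(([False], active[:-1])))
    for s in starts:
        e = s
        while e < len(active) and active[e]:
            e += 1
        out[s:e] = vals[s] if mode == "hold_at_onset" else vals[s:e].max()
    return p.with_values(out)


def physio_rhs(
    state: PhysioState,
    u_t: float,
    pi_c_t: float,
    alpha_t: float,
    mt_velocity: float,
    params: PhysioParams,
    eps_c_dot: float | None = None,
) -> tuple[float, float, float]:
    """Time derivatives (dkc/dt, dFc/dt, deps_c/dt) of the state.

    ``mt_velocity`` is the whole-unit lengthening speed L0 * deps/dt in
    m/s (0 when isometric).  Passing ``eps_c_dot`` bypasses the tendon
    coupling and prescribes the CE strain rate directly (used for
    clamped-velocity and oracle comparisons).
    """
    kc, Fc, eps = state.kc, state.Fc, state.eps_c
    fl = force_length(eps, params.b)
    km_eps = params.km0 * fl
    Fm_eps = params.Fm0 * fl
    source = alpha_t * pi_c_t * params.Uc

    if eps_c_dot is None:
        if params.kt * params.Lc0 / params.cos_phi + kc * params.Lc0 - Fc <= 0:
            raise RuntimeError(
                "tendon/CE stability condition violated: "
                f"kt={params.kt}, kc={kc}, Fc={Fc}"
            )
        T = params.kt * mt_velocity / params.cos_phi + Fc * u_t - Fm_eps * source
        denom = (
            params.kt * params.Lc0 / params.cos_phi
            + kc * params.Lc0
            - math.copysign(1.0, T) * Fc
        )
        edot = T / denom
    else:
        edot = eps_c_dot

    loss = u_t + abs(edot)
    kdot = -loss * kc + km_eps * source
    fdot = -loss * Fc + Fm_eps * source + kc * params.Lc0 * edot
    return kdot, fdot, edot


def simulate_physio(
    drive: ChemicalDrive,
    alpha: UniformSeries,
    params: PhysioParams,
    dt_int: float = 1e-3,
    mt_velocity: UniformSeries | None = None,
    eps_c_dot: UniformSeries | None = None,
) -> PhysioTrace:
    """Integrate the moment ODEs from rest by 4th-order Runge-Kutta.

    Inputs are held zero-order within each integration step; traces are
    returned on the input time base.  kc and Fc are clipped at zero
    after each step (floating-point undershoot during fast relaxation),
    with the number of clips reported.
    """
    require_same_base(drive.pi_c, alpha)
    base = alpha
    n_int = max(int(round(base.duration / dt_int)), 1) + 1
    t_int = base.t0 + dt_int * np.arange(n_int)
    idx = np.minimum(((t_int - base.t0) / base.dt).astype(int), len(base) - 1)
    u_i = drive.u.values[idx]
    pi_i = drive.pi_c.values[idx]
    al_i = np.clip(alpha.values, 0.0, 1.0)[idx]
    mtv_i = mt_velocity.values[idx] if mt_velocity is not None else np.zeros(n_int)
    edot_i = eps_c_dot.values[idx] if eps_c_dot is not None else None

    kc = fc = eps = 0.0
    out = np.empty((n_int, 3))
    n_clipped = 0
    for k in range(n_int):
        out[k] = (kc, fc, eps)
        if k == n_int - 1:
            break
        args = (u_i[k], pi_i[k], al_i[k], mtv_i[k], params)
        edot_k = None if edot_i is None else edot_i[k]

        def rhs(kc_, fc_, eps_):
            try:
                return physio_rhs(PhysioState(kc_, fc_, eps_), *args, eps_c_dot=edot_k)
            except RuntimeError as err:
                raise RuntimeError(f"{err} at t = {t_int[k]:.4f} s") from None

        d1 = rhs(kc, fc, eps)
        d2 = rhs(kc + 0.5 * dt_int * d1[0], fc + 0.5 * dt_int * d1[1], eps + 0.5 * dt_int * d1[2])
        d3 = rhs(kc + 0.5 * dt_int * d2[0], fc + 0.5 * dt_int * d2[1], eps + 0.5 * dt_int * d2[2])
        d4 = rhs(kc + dt_int * d3[0], fc + dt_int * d3[1], eps + dt_int * d3[2])
        kc += dt_int * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0]) / 6.0
        fc += dt_int * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1]) / 6.0
        eps += dt_int * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2]) / 6.0
        if kc < 0 or fc < 0:
            n_clipped += 1
            kc, fc = max(kc, 0.0), max(fc, 0.0)

    t_out = base.times
    return PhysioTrace(
        Fc=base.with_values(np.interp(t_out, t_int, out[:, 1])),
        kc=base.with_values(np.interp(t_out, t_int, out[:, 0])),
        eps_c=base.with_values(np.interp(t_out, t_int, out[:, 2])),
        n_clipped=n_clipped,
    )


def isotonic_force_velocity(
    params: PhysioParams,
    kc0: float,
    alpha: float,
    velocity_grid,
) -> list[tuple[float, float]]:
    """Steady-state force over a grid of concentric strain rates.

    Setting dFc/dt = 0 in the moment ODEs at fixed eps_c (reference
    length, fl = 1) gives a Hill-type hyperbola

        Fc = (alpha Fm0 Uc + kc0 Lc0 v) / (Uc + |v|),   v = deps_c/dt < 0,

    equivalently Fc = alpha Fm0 (1 + A0 v) / (1 - B v) with
    A0 = Lc0 kc0 / (alpha Fm0 Uc) and B = 1/Uc: the force-velocity
    relation emerges from the cross-bridge kinetics rather than being
    imposed.  Valid for Uc + v > 0.
    """
    out = []
    for v in velocity_grid:
        if v > 0:
            raise ValueError(f"concentric grid expected (v <= 0), got {v}")
        if params.Uc + v <= 0:
            raise ValueError(f"velocity {v} at or beyond the kinetic limit -Uc")
        fc = (alpha * params.Fm0 * params.Uc + kc0 * params.Lc0 * v) / (
            params.Uc + abs(v)
        )
        out.append((float(v), float(fc)))
    return out
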