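"""Two-state cross-bridge PDE: the verification oracle for the moment ODEs.

The fraction n(y, t) of attached cross-bridges at normalized bond length
y obeys the sliding-filament transport equation

    dn/dt + (S0/h) deps_c/dt * dn/dy = f(y,t) (1 - n) - g(y,t) n,

with attachment permitted only on the window y in [0, 1] and rates that
do not depend on y:

    contraction:  f = alpha * fl(eps_c) * Uc,   f + g = u + |deps_c/dt|
    relaxation:   f = 0,                        g = u + |deps_c/dt|.

Because the rates are independent of y, the first two moments of n —
stiffness k0 * integral(n dy) and force k0 * h * integral(y n dy) —
close exactly into the ODEs integrated by
:func:`emgforce.physio.simulate_physio`; solving the PDE on a grid and
taking its moments therefore provides an independent check with no
closure gap, only discretization error.

The sarcomere constants h, S0, k0 are not separately observable from
the macroscopic aggregates km0 and Fm0; :meth:`HuxleyGrid.for_params`
picks a consistent set (one sarcomere spans the fiber, S0 = Lc0) such
that the PDE moments land directly on the muscle scale:
k0 = km0 and h = 2 Fm0 / km0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hill import force_length
from .physio import ChemicalDrive, PhysioParams
from .series import UniformSeries, require_same_base


@dataclass
class HuxleyGrid:
    """Discretized bond-length axis and sarcomere constants.

    ``y`` must be uniform and cover the attachment window [0, 1] with
    margin for advection.  ``n`` holds the attached fraction and is
    initialized to zero (rest).
    """

    y: np.ndarray
    h: float
    S0: float
    k0: float
    N: float = 1.0
    n: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        dy = np.diff(self.y)
        if self.y.size < 8 or not np.allclose(dy, dy[0]):
            raise ValueError("y must be a uniform grid with at least 8 points")
        if self.y[0] > 0 or self.y[-1] < 1:
            raise ValueError("y grid must cover the attachment window [0, 1]")
        if self.n is None:
            self.n = np.zeros_like(self.y)

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @classmethod
    def for_params(
        cls,
        params: PhysioParams,
        n_points: int = 400,
        y_min: float = -1.0,
        y_max: float = 2.0,
    ) -> "HuxleyGrid":
        """Grid whose aggregate constants match the muscle-scale params."""
        k0 = params.km0  # with S0 = Lc0 and N = 1, km0 = S0 N k0 / Lc0 = k0
        return cls(
            y=np.linspace(y_min, y_max, n_points),
            h=2.0 * params.Fm0 / k0,
            S0=params.Lc0,
            k0=k0,
        )


def huxley_pde_moments(
    drive: ChemicalDrive,
    eps_c_dot: UniformSeries,
    grid: HuxleyGrid,
    params: PhysioParams,
    alpha: float = 1.0,
) -> tuple[UniformSeries, UniformSeries]:
    """Integrate the PDE and return muscle-scale (kc, Fc) moment traces.

    First-order upwind transport plus an exact exponential reaction
    substep, stepped at the drive's sampling interval.  Raises a grid
    error when the advection Courant number exceeds 1.
    """
    require_same_base(drive.pi_c, eps_c_dot)
    dt = drive.pi_c.dt
    y, dy = grid.y, grid.dy
    window = (y >= 0.0) & (y <= 1.0)
    n = grid.n.copy()
    eps = 0.0
    scale_k = grid.N * grid.S0 / params.Lc0 * grid.k0
    scale_f = grid.N * grid.k0 * grid.h

    n_t = len(eps_c_dot)
    ks = np.empty(n_t)
    fs = np.empty(n_t)
    edot_v = eps_c_dot.values
    u_v = drive.u.values
    pi_v = drive.pi_c.values
    for k in range(n_t):
        ks[k] = scale_k * np.trapezoid(n, y)
        fs[k] = scale_f * np.trapezoid(y * n, y)
        if k == n_t - 1:
            break
        edot = edot_v[k]
        c = grid.S0 / grid.h * edot  # advection speed in y-units/s
        cfl = abs(c) * dt / dy
        if cfl > 1.0:
            raise ValueError(
                f"CFL violated (Courant {cfl:.2f} at step {k}); use a finer dt"
            )
        if c > 0:
            n = n - cfl * (n - np.concatenate(([0.0], n[:-1])))
        elif c < 0:
            n = n + cfl * (np.concatenate((n[1:], [0.0])) - n)
        # reaction with y-independent rates, exact over the step
        f = np.where(window, alpha * force_length(eps, params.b) * params.Uc * pi_v[k], 0.0)
        total = u_v[k] + abs(edot)
        n_inf = f / total
        n = n_inf + (n - n_inf) * np.exp(-total * dt)
        eps += edot * dt

    base = eps_c_dot
    return base.with_values(ks), base.with_values(fs)
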