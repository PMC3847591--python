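"""Activation dynamics: normalized EMG envelope -> muscle activation.

The envelope e(t) is mapped to *neural activation* p(t) by a delayed
second-order recursion that stands in for the twitch response of the
fiber pool,

    p(t_k) = gamma * e(t_{k-d}) - beta1 * p(t_{k-1}) - beta2 * p(t_{k-2}),

with beta1 = C1 + C2, beta2 = C1*C2, |C1|, |C2| < 1 for stability, and
gamma - beta1 - beta2 = 1 so the filter has unit DC gain.  d is the
electromechanical delay in samples.

For the nonlinear Hill model, p(t) is further shaped into *muscle
activation* a(t) by

    a = (exp(A p) - 1) / (exp(A) - 1),    -3 <= A < 0,

which amplifies low activation levels (A = 0 is the linear limit a = p).
The linear Hill model uses a(t) = p(t) directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sps

from .series import UniformSeries

#: Default electromechanical delay (seconds).  Typical surface-EMG to
#: force latency for lower-limb muscles; configurable per muscle.
DEFAULT_DELAY_S = 0.040

#: Default recursion roots: a critically damped discrete twitch.
DEFAULT_C1 = -0.5
DEFAULT_C2 = -0.5


@dataclass(frozen=True)
class ActivationParams:
    """Delay and recursion coefficients of the activation dynamics.

    ``d`` is the delay in *samples* (use :meth:`from_seconds` to convert
    from seconds at a given sampling step).  gamma, beta1 and beta2 are
    derived from the roots C1, C2.
    """

    d: int = 0
    C1: float = DEFAULT_C1
    C2: float = DEFAULT_C2
    A: float = -1.7

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"delay must be >= 0 samples, got {self.d}")
        if not (abs(self.C1) < 1 and abs(self.C2) < 1):
            raise ValueError(
                f"recursion roots must satisfy |C1|,|C2| < 1, got {self.C1}, {self.C2}"
            )
        if not (-3.0 <= self.A <= 0.0):
            raise ValueError(f"shape factor A must lie in [-3, 0], got {self.A}")

    @property
    def beta1(self) -> float:
        return self.C1 + self.C2

    @property
    def beta2(self) -> float:
        return self.C1 * self.C2

    @property
    def gamma(self) -> float:
        # unit DC gain: gamma - beta1 - beta2 = 1
        return 1.0 + self.beta1 + self.beta2

    @classmethod
    def from_seconds(
        cls,
        dt: float,
        d_s: float = DEFAULT_DELAY_S,
        C1: float = DEFAULT_C1,
        C2: float = DEFAULT_C2,
        A: float = -1.7,
    ) -> "ActivationParams":
        """Build params with the delay rounded to the nearest sample."""
        return cls(d=int(round(d_s / dt)), C1=C1, C2=C2, A=A)


def neural_activation(e: UniformSeries, params: ActivationParams) -> UniformSeries:
    """Apply the delayed second-order recursion to the envelope.

    Initial rest: p and e are taken as zero before the first sample.  The
    recursion is linear with unit DC gain, so a constant input converges
    to itself.
    """
    vals = e.values
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-6:
        warnings.warn(
            "envelope outside [0, 1]; was it normalized by the MVC peak?",
            stacklevel=2,
        )
    # p(k) + beta1 p(k-1) + beta2 p(k-2) = gamma e(k-d)
    b = np.zeros(params.d + 1)
    b[params.d] = params.gamma
    a = np.array([1.0, params.beta1, params.beta2])
    return e.with_values(sps.lfilter(b, a, vals))


def muscle_activation(p: UniformSeries, A: float, tol: float = 1e-6) -> UniformSeries:
    """Nonlinear shaping of neural activation, a = (e^{Ap} - 1)/(e^A - 1).

    ``A = 0`` is handled as the linear limit a = p.  Values of p outside
    [0, 1] beyond ``tol`` raise a domain error.
    """
    if not (-3.0 <= A <= 0.0):
        raise ValueError(f"shape factor A must lie in [-3, 0], got {A}")
    vals = p.values
    if vals.min() < -tol or vals.max() > 1 + tol:
        raise ValueError(
            f"neural activation outside [0, 1]: range [{vals.min()}, {vals.max()}]"
        )
    vals = np.clip(vals, 0.0, 1.0)
    if A == 0.0:
        return p.with_values(vals)
    out = np.expm1(A * vals) / np.expm1(A)
    return p.with_values(out)
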