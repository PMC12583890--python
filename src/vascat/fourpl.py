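"""Four-parameter logistic (4PL) psychometric function and trial-noise profile.

The 4PL maps continuum step x (1..7) to an expected VAS rating (0-100):

    mu(x) = L + (U - L) / (1 + exp(-(4 s / (U - L)) (x - c)))

with lower/upper asymptotes L and U (VAS units), crossover c (step units) and
s the derivative of mu at x = c (VAS units per step).  Parameterizing the
slope directly as the midpoint derivative makes the quantity of scientific
interest (category gradiency) a native parameter instead of a post-hoc
transform of a rate constant.

Trial-to-trial response variance is log-linear in a quadratic of the centered
step:

    sigma^2(x) = exp(a + w1 (x - m) + w2 (x - m)^2)

where ``a`` is a (possibly subject-specific) log-variance intercept and m is
the fixed mid-continuum step.  With w2 < 0 the variance peaks mid-continuum,
where stimuli are most ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "FourPLParams",
    "fourpl_mean",
    "fourpl_mean_grad",
    "trial_sigma2",
    "ParameterError",
]


@dataclass(frozen=True)
class FourPLParams:
    """4PL parameters: asymptotes L < U (VAS), crossover c (steps), midpoint
    slope s (VAS/step)."""

    L: float
    U: float
    c: float
    s: float

    def __post_init__(self) -> None:
        if not self.U > self.L:
            raise ParameterError(
                f"upper asymptote must exceed lower (got L={self.L}, U={self.U})"
            )
        if not np.isfinite(self.s):
            raise ParameterError("slope must be finite")


class ParameterError(ValueError):
    """Raised for invalid psychometric-function parameters."""


def fourpl_mean(x, L, U, c, s):
    """Expected VAS rating at continuum step ``x``.

    All arguments broadcast.  Requires U > L elementwise.
    """
    x = np.asarray(x, dtype=float)
    L, U, c, s = (np.asarray(v, dtype=float) for v in (L, U, c, s))
    r = U - L
    if np.any(r <= 0):
        raise ParameterError("upper asymptote must exceed lower asymptote")
    k = 4.0 * s / r
    z = _sigmoid(k * (x - c))
    return L + r * z


def fourpl_mean_grad(x, L, U, c, s):
    """Value and partial derivatives of :func:`fourpl_mean`.

    Returns ``(mu, dL, dU, dc, ds)`` — each the same shape as the broadcast
    inputs.  Used by the hierarchical model's analytic log-posterior gradient.
    """
    x, L, U, c, s = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x, L, U, c, s))
    )
    r = U - L
    k = 4.0 * s / r
    z = _sigmoid(k * (x - c))
    zz = z * (1.0 - z)
    mu = L + r * z
    xc = x - c
    # k depends on L and U through r = U - L
    dL = 1.0 - z + zz * xc * (4.0 * s / r)
    dU = z - zz * xc * (4.0 * s / r)
    dc = -4.0 * s * zz
    ds = 4.0 * zz * xc
    return mu, dL, dU, dc, ds


def trial_sigma2(step, log_intercept, w1, w2, mid):
    """Trial-level response variance at ``step`` (squared VAS units).

    ``log_intercept`` is the summed log-scale intercept (population w0 plus
    any subject offset); ``mid`` is the fixed continuum center.
    Always positive by construction.
    """
    d = np.asarray(step, dtype=float) - mid
    return np.exp(np.asarray(log_intercept, dtype=float) + w1 * d + w2 * d * d)
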