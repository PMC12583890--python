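"""Per-subject indices from a fitted year: Slope and Response Variability.

Slope is the posterior mean of the subject's midpoint derivative (population
slope plus the subject's random intercept), in VAS units per continuum step.
Response Variability is the posterior mean of the subject's step-averaged
trial variance, in squared VAS units: 0 means no trial-to-trial dispersion,
and with trial SDs around 23 VAS points values of 500-600 arise.  Averaging
the quadratic variance profile over the steps (rather than reading it at the
center step only) is the documented convention here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fourpl import FourPLParams, fourpl_mean
from .model import HierarchicalPosterior


class SubjectLookupError(KeyError):
    """Raised when a subject is absent from a fitted year."""


class OracleFitError(RuntimeError):
    """Raised when the per-subject least-squares oracle fails to converge."""


def extract_subject_indices(post: HierarchicalPosterior) -> pd.DataFrame:
    """One row per kept subject: slope_hat and rv_hat point estimates.

    slope_hat = E_post[s0 + subject slope intercept];
    rv_hat    = E_post[mean over steps of sigma^2_j(step)].
    """
    data = post.data
    pop = post.flat(post.layout["pop"])
    slope_draws = post.subject_slope_draws()            # (ndraw, J)
    a_draws = post.subject_logvar_intercept_draws()     # (ndraw, J)
    grid = np.arange(1, data.steps + 1, dtype=float) - data.mid
    # step-average factor per draw: mean_d exp(w1 d + w2 d^2)
    w1 = pop[:, 5][:, None]
    w2 = pop[:, 6][:, None]
    A = np.mean(np.exp(w1 * grid[None, :] + w2 * grid[None, :] ** 2), axis=1)
    rv_draws = np.exp(a_draws) * A[:, None]
    return pd.DataFrame(
        {
            "subject_id": data.subject_ids,
            "testing_year": post.testing_year,
            "start_grade": data.start_grade,
            "slope_hat": slope_draws.mean(axis=0),
            "rv_hat": rv_draws.mean(axis=0),
        }
    )


def subject_index_row(indices: pd.DataFrame, subject_id) -> pd.Series:
    """Row for one subject; raises :class:`SubjectLookupError` if absent."""
    hit = indices[indices["subject_id"] == subject_id]
    if hit.empty:
        raise SubjectLookupError(f"subject {subject_id!r} not in fitted year")
    return hit.iloc[0]


def oracle_subject_fit(
    trials: pd.DataFrame, *, steps: int | None = None
) -> tuple[FourPLParams, float]:
    """Unpenalized nonlinear least-squares 4PL fit to one subject-year.

    A deliberately independent cross-check of the hierarchical estimates on
    data-rich synthetic subjects: plain least squares on that subject's own
    pooled trials, no pooling, no priors.  Returns the fitted parameters and
    the residual variance.
    """
    x = trials["step"].to_numpy(dtype=float)
    y = trials["vas_score"].to_numpy(dtype=float)
    if len(y) < 8 or len(np.unique(x)) < 4:
        raise OracleFitError("need >= 8 trials spanning the continuum")
    n_steps = int(steps if steps is not None else x.max())
    mid = (1 + n_steps) / 2.0

    lo = np.array([-50.0, 50.0, 0.0, 0.1])
    hi = np.array([50.0, 150.0, n_steps + 1.0, 200.0])

    def resid(theta):
        L, U, c, s = theta
        return fourpl_mean(x, L, max(U, L + 1e-3), c, s) - y

    step_means = pd.Series(y).groupby(x).mean()
    guess = np.array(
        [
            float(step_means.min()),
            float(step_means.max()),
            mid,
            max(0.5, float((step_means.max() - step_means.min()) / n_steps)),
        ]
    )
    guess = np.clip(guess, lo + 1e-6, hi - 1e-6)
    try:
        res = least_squares(resid, guess, bounds=(lo, hi), max_nfev=2000)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise OracleFitError(str(exc)) from exc
    if not res.success:
        raise OracleFitError(f"least squares did not converge: {res.status}")
    L, U, c, s = res.x
    dof = max(1, len(y) - 4)
    resid_var = float(np.sum(res.fun**2) / dof)
    return FourPLParams(L=float(L), U=float(U), c=float(c), s=float(s)), resid_var
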