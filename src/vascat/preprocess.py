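"""VAS preprocessing: orientation normalization, validity screening, assembly.

Raw ratings from blocks where the endpoint pictures were swapped are reversed
(100 - rating) so that high values always correspond to the last continuum
step.  Participant-years whose mean response profile never reaches the scale
extremes (lowest step-mean above 25 or highest below 75) are excluded: such
data cannot distinguish a genuinely flat category structure from a
misunderstood task.  Exclusion is year-specific — a participant dropped for
one year re-enters other years unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOWER_CRITERION = 25.0
UPPER_CRITERION = 75.0


class DataError(ValueError):
    """Raised for malformed trial data."""


class ScreeningError(ValueError):
    """Raised when the screen cannot be evaluated."""


class PipelineError(RuntimeError):
    """Raised when a stage is left with nothing to process."""


def normalize_orientation(trials: pd.DataFrame, *, validate: bool = True) -> pd.DataFrame:
    """Add ``vas_score``: the orientation-normalized rating.

    ``vas_score = raw_rating`` on upright blocks and ``100 - raw_rating`` on
    flipped blocks.  The transform is an involution: applying it to an
    already-flipped recording restores the original.  ``validate=False``
    skips the physical-range check (for unbounded estimator-validation
    draws).
    """
    raw = trials["raw_rating"].to_numpy(dtype=float)
    if validate and (np.any(raw < 0) or np.any(raw > 100) or np.any(~np.isfinite(raw))):
        bad = np.flatnonzero((raw < 0) | (raw > 100) | ~np.isfinite(raw))[:5]
        raise DataError(f"raw ratings outside [0, 100] at rows {bad.tolist()}")
    out = trials.copy()
    flipped = trials["flipped"].to_numpy(dtype=bool)
    out["vas_score"] = np.where(flipped, 100.0 - raw, raw)
    return out


@dataclass(frozen=True)
class ScreenReport:
    """Validity-screen outcome for one participant-year."""

    subject_id: str
    testing_year: int
    step_means: dict[int, float]
    lower: float
    upper: float
    kept: bool
    reason: str


def screen_subject_year(
    trials: pd.DataFrame,
    *,
    steps: int | None = None,
    per_continuum: bool = False,
) -> ScreenReport:
    """Apply the asymptote screen to one participant-year's clean trials.

    Mean ``vas_score`` is computed per continuum step (pooled over continua by
    default); the participant-year is kept iff the lowest step-mean is <= 25
    and the highest is >= 75 (inclusive).  With ``per_continuum=True`` every
    continuum must individually satisfy both criteria.
    """
    if trials.empty:
        raise ScreeningError("no trials for this participant-year")
    if "vas_score" not in trials.columns:
        raise ScreeningError("trials must be orientation-normalized first")
    sid = str(trials["subject_id"].iloc[0])
    year = int(trials["testing_year"].iloc[0])
    observed = set(trials["step"].astype(int))
    if steps is not None and not {1, steps} <= observed:
        raise ScreeningError(
            f"participant {sid} year {year} is missing endpoint steps"
        )

    step_means = trials.groupby("step")["vas_score"].mean()
    if per_continuum:
        by_cont = trials.groupby(["continuum_id", "step"])["vas_score"].mean()
        lows = by_cont.groupby("continuum_id").min()
        highs = by_cont.groupby("continuum_id").max()
        lower, upper = float(lows.max()), float(highs.min())
    else:
        lower = float(step_means.min())
        upper = float(step_means.max())

    low_ok = lower <= LOWER_CRITERION
    high_ok = upper >= UPPER_CRITERION
    kept = low_ok and high_ok
    if kept:
        reason = "ok"
    elif not low_ok and not high_ok:
        reason = "flat"
    elif not low_ok:
        reason = "lower asymptote above 25"
    else:
        reason = "upper asymptote below 75"
    return ScreenReport(
        subject_id=sid,
        testing_year=year,
        step_means={int(k): float(v) for k, v in step_means.items()},
        lower=lower,
        upper=upper,
        kept=kept,
        reason=reason,
    )


def screen_all(
    clean: pd.DataFrame, *, steps: int | None = None, per_continuum: bool = False
) -> pd.DataFrame:
    """Screen every participant-year; one report row each.

    Decisions depend only on that participant-year's own trials.
    """
    rows = []
    for (sid, year), grp in clean.groupby(["subject_id", "testing_year"], sort=True):
        rep = screen_subject_year(grp, steps=steps, per_continuum=per_continuum)
        rows.append(
            {
                "subject_id": sid,
                "testing_year": year,
                "lower": rep.lower,
                "upper": rep.upper,
                "kept": rep.kept,
                "reason": rep.reason,
            }
        )
    return pd.DataFrame(rows)


def assemble_year_dataset(
    clean: pd.DataFrame, reports: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Model-ready table for one testing year: kept participant-years only.

    Adds contiguous 0-based integer codes ``subject_idx`` and ``item_idx``
    (sorted by id, so re-assembly after adding a participant leaves existing
    rows' scores unchanged).
    """
    kept_ids = set(
        reports.loc[(reports["testing_year"] == year) & reports["kept"], "subject_id"]
    )
    data = clean[
        (clean["testing_year"] == year) & clean["subject_id"].isin(kept_ids)
    ].copy()
    if data.empty:
        raise PipelineError(f"no participant-years survive screening for year {year}")
    subjects = sorted(data["subject_id"].unique())
    items = sorted(data["continuum_id"].unique())
    data["subject_idx"] = data["subject_id"].map({s: i for i, s in enumerate(subjects)})
    data["item_idx"] = data["continuum_id"].map({c: i for i, c in enumerate(items)})
    return data.reset_index(drop=True)
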