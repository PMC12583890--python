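"""Trial-level simulation of the accelerated-longitudinal VAS study.

Produces the raw, un-normalized recordings a real session would yield: on
blocks where the endpoint pictures are swapped, the stored rating is
100 - intended rating, so the preprocessing stage has real work to do.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign, build_design
from .fourpl import fourpl_mean, trial_sigma2
from .population import (
    PopulationTruth,
    PsychometricParams,
    draw_subject_effects,
    draw_subject_params,
)

TRIAL_COLUMNS = [
    "subject_id", "start_grade", "testing_year", "day",
    "continuum_id", "step", "raw_rating", "flipped",
]


def simulate_trial(
    params: PsychometricParams,
    step,
    rng: np.random.Generator | int,
    *,
    w1: float = 0.0,
    w2: float = -0.15,
    mid: float = 4.0,
    flipped=False,
    clip: bool = True,
):
    """Simulate raw VAS rating(s) at ``step`` for one subject-year.

    rating = 4PL mean + Gaussian noise with step-dependent variance from the
    quadratic log-variance profile, clipped to [0, 100] (the physical scale;
    ``clip=False`` draws from the unbounded Gaussian, for estimator-validation
    runs where the fitted model should be exactly well-specified).  On flipped
    blocks the stored value is 100 - rating (un-normalized orientation).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    step = np.asarray(step, dtype=float)
    mu = fourpl_mean(step, params.L, params.U, params.c, params.s)
    sigma2 = trial_sigma2(step, params.log_var_intercept, w1, w2, mid)
    rating = mu + rng.standard_normal(step.shape) * np.sqrt(sigma2)
    if clip:
        rating = np.clip(rating, 0.0, 100.0)
    return np.where(np.asarray(flipped, dtype=bool), 100.0 - rating, rating)


def simulate_study(
    design: StudyDesign,
    truth: PopulationTruth,
    seed: int,
    attrition_rate: float = 0.065,
    clip: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full study: all cohorts, subjects and testing years.

    Returns ``(trials, ground_truth)``: one tidy table of realized raw trials
    and one table of the latent per-subject-year parameters (including the
    step-averaged trial variance ``rv``).  Participant-years are dropped
    completely at random at ``attrition_rate``, mimicking year-specific
    exclusions.  Fully reproducible from ``seed``.
    """
    if not 0.0 <= attrition_rate < 1.0:
        raise ValueError("attrition_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mid = design.mid_step

    # item (continuum) intercepts, fixed for the whole study
    item_fx = {
        cont: {
            "dL": rng.normal(0.0, truth.item_L_sd),
            "dU": rng.normal(0.0, truth.item_U_sd),
            "dc": rng.normal(0.0, truth.item_c_sd),
            "ds": rng.normal(0.0, truth.item_s_sd),
        }
        for cont in design.continua
    }

    trial_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for grade in design.cohorts:
        for i in range(design.subjects_per_cohort):
            sid = f"S{grade}{i:03d}"
            effects = draw_subject_effects(truth, rng)
            for year in range(1, design.years + 1):
                missing = rng.random() < attrition_rate
                params = draw_subject_params(
                    truth, grade, year, rng, effects=effects, steps=design.steps
                )
                if missing:
                    continue
                grid = build_design(design, seed=int(rng.integers(2**31)))
                steps = grid["step"].to_numpy(dtype=float)
                conts = grid["continuum_id"].to_numpy()
                mu = np.empty(len(grid))
                for cont in design.continua:
                    m = conts == cont
                    fx = item_fx[cont]
                    mu[m] = fourpl_mean(
                        steps[m],
                        params.L + fx["dL"],
                        params.U + fx["dU"],
                        params.c + fx["dc"],
                        params.s + fx["ds"],
                    )
                sigma2 = trial_sigma2(
                    steps, params.log_var_intercept, truth.w1, truth.w2, mid
                )
                rating = mu + rng.standard_normal(len(grid)) * np.sqrt(sigma2)
                if clip:
                    rating = np.clip(rating, 0.0, 100.0)
                flipped = grid["flipped"].to_numpy(dtype=bool)
                raw = np.where(flipped, 100.0 - rating, rating)
                trial_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "start_grade": grade,
                            "testing_year": year,
                            "day": grid["day"].to_numpy(),
                            "continuum_id": conts,
                            "step": grid["step"].to_numpy(),
                            "raw_rating": raw,
                            "flipped": flipped,
                        }
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "start_grade": grade,
                        "testing_year": year,
                        "L": params.L,
                        "U": params.U,
                        "c": params.c,
                        "s": params.s,
                        "rv": params.rv,
                        "log_var_intercept": params.log_var_intercept,
                    }
                )
    if not trial_frames:
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
    else:
        trials = pd.concat(trial_frames, ignore_index=True)[TRIAL_COLUMNS]
    ground_truth = pd.DataFrame(truth_rows)
    return trials, ground_truth


def save_study(
    outdir: str | Path,
    trials: pd.DataFrame,
    ground_truth: pd.DataFrame,
    design: StudyDesign,
    truth: PopulationTruth,
    seed: int,
) -> dict[str, Path]:
    """Write trials + ground truth as CSV with a JSON sidecar of the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "sidecar": outdir / "study.json",
    }
    # %.17g keeps float round-trips exact, so ingesting a written study
    # reproduces simulate-mode results bit for bit
    trials.to_csv(paths["trials"], index=False, float_format="%.17g")
    ground_truth.to_csv(paths["ground_truth"], index=False, float_format="%.17g")
    sidecar = {
        "design": {
            "cohorts": list(design.cohorts),
            "years": design.years,
            "continua": list(design.continua),
            "steps": design.steps,
            "days": design.days,
            "reps": design.reps,
            "subjects_per_cohort": design.subjects_per_cohort,
        },
        "truth": truth.to_dict(),
        "seed": seed,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`save_study` (or real-format CSV)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["flipped"] = df["flipped"].astype(bool)
    return df
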