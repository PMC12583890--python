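"""Accelerated-longitudinal study design and trial-grid construction.

The study follows three cohorts of children (starting grades 1-3) over four
annual testing waves.  Each year a participant rates five 7-step minimal-pair
continua on a 0-100 visual analogue scale (VAS), twice per step on each of two
days, for 7 x 2 x 2 x 5 = 140 experimental trials.  Endpoint pictures swap
sides between the two days of a year, so half of all blocks are recorded with
the scale reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CONTINUA = ["beach-peach", "time-dime", "net-nut", "hat-hot", "sip-ship"]


class DesignError(ValueError):
    """Raised for an invalid study-design configuration."""


@dataclass(frozen=True)
class StudyDesign:
    """Structural parameters of the accelerated longitudinal VAS study.

    Defaults reproduce the reference design: 3 cohorts x 4 years,
    5 continua x 7 steps x 2 days x 2 repetitions = 140 trials per
    participant-year.
    """

    cohorts: tuple[int, ...] = (1, 2, 3)
    years: int = 4
    continua: tuple[str, ...] = tuple(DEFAULT_CONTINUA)
    steps: int = 7
    days: int = 2
    reps: int = 2
    subjects_per_cohort: int = 75

    def __post_init__(self) -> None:
        if self.steps < 2:
            raise DesignError(f"steps must be >= 2, got {self.steps}")
        for name, value in [
            ("years", self.years),
            ("days", self.days),
            ("reps", self.reps),
            ("subjects_per_cohort", self.subjects_per_cohort),
        ]:
            if value < 1:
                raise DesignError(f"{name} must be positive, got {value}")
        if not self.cohorts:
            raise DesignError("at least one cohort is required")
        if not self.continua:
            raise DesignError("at least one continuum is required")

    @property
    def n_continua(self) -> int:
        return len(self.continua)

    @property
    def trials_per_continuum(self) -> int:
        """Trials per continuum per participant-year (28 with defaults)."""
        return self.steps * self.days * self.reps

    @property
    def trials_per_year(self) -> int:
        """Trials per participant-year (140 with defaults)."""
        return self.trials_per_continuum * self.n_continua

    @property
    def mid_step(self) -> float:
        """Center of the continuum (step 4 for 7 steps)."""
        return (1 + self.steps) / 2.0

    @property
    def n_subjects(self) -> int:
        return self.subjects_per_cohort * len(self.cohorts)


def build_design(design: StudyDesign, *, seed: int = 0) -> pd.DataFrame:
    """Lay out the unrealized trial grid for one participant-year.

    Returns one row per trial with columns ``day``, ``continuum_id``, ``step``,
    ``rep``, ``flipped`` and ``trial_in_block``.  Trials are blocked by
    continuum within a day; step order within each block is a seeded random
    permutation of ``reps`` copies of every step.  The picture orientation
    (``flipped``) alternates between days within each continuum, mimicking the
    endpoint images swapping sides on the second day.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    # day-1 flip assignment per continuum: half the continua start flipped so
    # that overall half of all blocks are reversed
    base_flip = {
        cont: bool((i + rng.integers(0, 2)) % 2)
        for i, cont in enumerate(design.continua)
    }
    for day in range(1, design.days + 1):
        for cont in design.continua:
            flipped = base_flip[cont] ^ ((day - 1) % 2 == 1)
            block = np.repeat(np.arange(1, design.steps + 1), design.reps)
            order = rng.permutation(len(block))
            for pos, idx in enumerate(order):
                rows.append(
                    {
                        "day": day,
                        "continuum_id": cont,
                        "step": int(block[idx]),
                        "rep": int(idx % design.reps),
                        "flipped": flipped,
                        "trial_in_block": pos,
                    }
                )
    grid = pd.DataFrame(rows)
    expected = design.trials_per_year
    assert len(grid) == expected
    return grid
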