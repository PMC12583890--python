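"""Shared fixtures: small synthetic studies and (expensive) fitted posteriors.

Heavy hierarchical fits are session-scoped so several tests can interrogate
one posterior.  All randomness is seeded; fixture problem sizes are kept
small (tens of subjects, two continua) so the full suite runs on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vascat.design import StudyDesign
from vascat.model import HierarchicalSpec, fit_year
from vascat.population import PopulationTruth
from vascat.preprocess import assemble_year_dataset, normalize_orientation, screen_all
from vascat.simulate import simulate_study


def no_trend_truth(**overrides) -> PopulationTruth:
    """Population truth with all developmental trends switched off."""
    base = dict(
        s_year=0.0, s_grade=0.0, s_year_grade=0.0,
        rv_year=0.0, rv_grade=0.0, rv_year_grade=0.0,
    )
    base.update(overrides)
    return PopulationTruth(**base)


def assemble_unscreened(trials: pd.DataFrame, year: int) -> pd.DataFrame:
    """Model-ready year table keeping every participant (no validity screen)."""
    clean = normalize_orientation(trials, validate=False)
    reports = screen_all(clean).assign(kept=True)
    return assemble_year_dataset(clean, reports, year)


@pytest.fixture(scope="session")
def small_study():
    """3 cohorts x 10 subjects, 2 continua, 4 years, default trends."""
    design = StudyDesign(
        cohorts=(1, 2, 3), subjects_per_cohort=10,
        continua=("beach-peach", "sip-ship"),
    )
    truth = PopulationTruth()
    trials, ground_truth = simulate_study(design, truth, seed=42, attrition_rate=0.0)
    return design, truth, trials, ground_truth


@pytest.fixture(scope="session")
def small_clean(small_study):
    _, _, trials, _ = small_study
    clean = normalize_orientation(trials)
    reports = screen_all(clean, steps=7)
    return clean, reports


@pytest.fixture(scope="session")
def fitted_year1(small_study, small_clean):
    """Reduced-sampler hierarchical fit of year 1 of the small study."""
    _, _, _, ground_truth = small_study
    clean, reports = small_clean
    data = assemble_year_dataset(clean, reports, 1)
    spec = HierarchicalSpec(chains=2, warmup=400, draws=400, seed=7, max_leapfrog=48)
    post = fit_year(data, spec, testing_year=1, steps=7)
    return post, ground_truth


@pytest.fixture(scope="session")
def oracle_comparison_fit():
    """40 subjects x 112 trials (4 continua), one year, moderate noise.

    Rich enough per subject that the unpooled least-squares oracle is stable,
    so hierarchical and oracle estimates can be correlated.
    """
    design = StudyDesign(
        cohorts=(2,), subjects_per_cohort=40, years=1,
        continua=("a", "b", "c", "d"),
    )
    truth = no_trend_truth(rv_base=100.0)  # moderate noise keeps the oracle stable
    trials, ground_truth = simulate_study(
        design, truth, seed=77, attrition_rate=0.0, clip=False
    )
    data = assemble_unscreened(trials, 1)
    spec = HierarchicalSpec(chains=2, warmup=300, draws=300, seed=9, max_leapfrog=32)
    post = fit_year(data, spec, testing_year=1, steps=7)
    return post, data, ground_truth
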