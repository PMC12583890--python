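"""Hierarchical fits: recovery, diagnostics, subject indices, oracle checks."""

import numpy as np
import pandas as pd
import pytest

from vascat.design import StudyDesign
from vascat.indices import (
    OracleFitError,
    SubjectLookupError,
    extract_subject_indices,
    oracle_subject_fit,
    subject_index_row,
)
from vascat.model import (
    HierarchicalPosterior,
    HierarchicalSpec,
    fit_year,
    param_layout,
    year_data_from_frame,
)
from vascat.fourpl import fourpl_mean
from vascat.population import step_average_profile
from vascat.simulate import simulate_study

from conftest import assemble_unscreened, no_trend_truth


def test_requires_two_subjects_and_items(small_clean):
    clean, reports = small_clean
    from vascat.preprocess import assemble_year_dataset

    data = assemble_year_dataset(clean, reports, 1)
    one_subj = data[data["subject_idx"] == 0]
    with pytest.raises(ValueError):
        fit_year(one_subj.assign(subject_idx=0), HierarchicalSpec())


def test_near_degenerate_recovery():
    """Tiny noise, zero heterogeneity: population 4PL recovered sharply."""
    design = StudyDesign(cohorts=(2,), subjects_per_cohort=8, years=1)
    truth = no_trend_truth(
        L_sd=0, U_sd=0, c_sd=0, s_sd=0, s_year_slope_sd=0,
        item_L_sd=0, item_U_sd=0, item_c_sd=0, item_s_sd=0,
        rv_base=1.0, rv_floor=0.5, rv_subject_sd_log=0, rv_year_slope_sd_log=0,
    )
    trials, _ = simulate_study(design, truth, seed=1, attrition_rate=0.0, clip=False)
    data = assemble_unscreened(trials, 1)
    spec = HierarchicalSpec(chains=2, warmup=400, draws=400, seed=3, max_leapfrog=48)
    post = fit_year(data, spec, testing_year=1, steps=7)
    est = post.summary().set_index("parameter")["mean"]
    assert abs(est["L0"] - truth.L_mean) < 0.5
    assert abs(est["U0"] - truth.U_mean) < 0.5
    assert abs(est["s0"] - truth.s_mean) < 0.5
    assert abs(est["c0"] - truth.c_mean) < 0.05


def test_population_diagnostics_clean_at_default_settings(small_clean):
    """Split R-hat < 1.01 for all population parameters, default sampler."""
    from vascat.preprocess import assemble_year_dataset

    clean, reports = small_clean
    data = assemble_year_dataset(clean, reports, 1)
    # small fixture: trim to 12 subjects to keep the default-settings run fast
    keep = sorted(data["subject_id"].unique())[:12]
    data = data[data["subject_id"].isin(keep)].copy()
    data["subject_idx"] = data["subject_id"].map({s: i for i, s in enumerate(keep)})
    post = fit_year(data, HierarchicalSpec(seed=5), testing_year=1, steps=7)
    pop = post.diagnostics.set_index("parameter")
    rhat = pop.loc[["L0", "U0", "c0", "s0", "w0", "w1", "w2"], "rhat"]
    assert rhat.max() < 1.01
    assert post.convergence_ok
    assert (pop["ess_bulk"] > 100).all()


def test_fit_recovers_population_means_within_interval(fitted_year1):
    """Posterior intervals bracket the (selection-adjusted) sample truth."""
    post, ground_truth = fitted_year1
    gt1 = ground_truth[ground_truth["testing_year"] == 1]
    kept = set(post.data.subject_ids)
    gt1 = gt1[gt1["subject_id"].isin(kept)]
    s = post.summary().set_index("parameter")
    # wide sanity intervals: the realized kept-sample means must be plausible
    assert s.loc["s0", "q2.5"] - 3 < gt1["s"].mean() < s.loc["s0", "q97.5"] + 3
    assert s.loc["c0", "q2.5"] - 0.5 < gt1["c"].mean() < s.loc["c0", "q97.5"] + 0.5


class TestSubjectIndices:
    def _artificial_posterior(self, n_subj=3, n_item=2, w0=np.log(400.0)):
        """Posterior with known constant draws: no subject deviations."""
        lay = param_layout(n_subj, n_item)
        draws = np.zeros((2, 10, lay["dim"]))
        draws[:, :, 0:7] = [5.0, 95.0, 4.0, 18.0, w0, 0.0, 0.0]
        draws[:, :, lay["log_subj_scale"]] = np.log(1e-8)
        draws[:, :, lay["log_item_scale"]] = np.log(1e-8)
        from vascat.model import YearData

        data = YearData(
            y=np.zeros(1), step=np.array([4.0]),
            subj_idx=np.array([0]), item_idx=np.array([0]),
            n_subj=n_subj, n_item=n_item, steps=7,
            subject_ids=[f"s{i}" for i in range(n_subj)],
            item_ids=[f"i{i}" for i in range(n_item)],
            start_grade=np.array([1, 2, 3][:n_subj]),
        )
        return HierarchicalPosterior(
            draws=draws, data=data, spec=HierarchicalSpec(), testing_year=2,
            diagnostics=pd.DataFrame({"parameter": [], "rhat": [], "ess_bulk": []}),
            divergences=0, accept_rate=1.0, convergence_ok=True,
        )

    def test_zero_intercept_subject_gets_population_slope(self):
        post = self._artificial_posterior()
        idx = extract_subject_indices(post)
        assert np.allclose(idx["slope_hat"], 18.0, atol=1e-6)

    def test_rv_is_step_averaged_variance(self):
        """With a flat profile, rv equals exp(intercept) exactly."""
        post = self._artificial_posterior(w0=np.log(400.0))
        idx = extract_subject_indices(post)
        assert np.allclose(idx["rv_hat"], 400.0, rtol=1e-6)

    def test_lookup_error_for_unknown_subject(self):
        idx = extract_subject_indices(self._artificial_posterior())
        with pytest.raises(SubjectLookupError):
            subject_index_row(idx, "nobody")

    def test_rv_scale_in_the_hundreds_for_realistic_noise(self, fitted_year1):
        """Trial SDs near 15-20 VAS points put the index in the hundreds."""
        post, _ = fitted_year1
        idx = extract_subject_indices(post)
        assert idx["rv_hat"].between(30, 1000).all()
        assert 100 < idx["rv_hat"].median() < 600

    def test_noisier_subjects_get_larger_rv(self, fitted_year1):
        post, ground_truth = fitted_year1
        idx = extract_subject_indices(post).merge(
            ground_truth, on=["subject_id", "testing_year"]
        )
        high = idx.nlargest(8, "rv")["rv_hat"].mean()
        low = idx.nsmallest(8, "rv")["rv_hat"].mean()
        assert high > low
        assert np.corrcoef(idx["rv_hat"], idx["rv"])[0, 1] > 0.5


class TestOracle:
    def test_noiseless_curve_recovered_exactly(self):
        steps = np.tile(np.arange(1, 8, dtype=float), 2)
        y = fourpl_mean(steps, 5.0, 95.0, 4.2, 20.0)
        trials = pd.DataFrame({"step": steps, "vas_score": y})
        params, resid_var = oracle_subject_fit(trials)
        assert abs(params.L - 5.0) < 1e-6
        assert abs(params.U - 95.0) < 1e-6
        assert abs(params.c - 4.2) < 1e-6
        assert abs(params.s - 20.0) < 1e-6
        assert resid_var < 1e-10

    def test_too_few_trials_rejected(self):
        trials = pd.DataFrame({"step": [1.0, 7.0], "vas_score": [5.0, 95.0]})
        with pytest.raises(OracleFitError):
            oracle_subject_fit(trials)

    def test_hierarchical_and_oracle_slopes_correlate(self, oracle_comparison_fit):
        post, data, _ = oracle_comparison_fit
        idx = extract_subject_indices(post)
        oracle = {}
        for sid, grp in data.groupby("subject_id"):
            try:
                params, _ = oracle_subject_fit(grp)
                oracle[sid] = params.s
            except OracleFitError:
                continue
        merged = idx[idx["subject_id"].isin(oracle)].copy()
        merged["oracle_s"] = merged["subject_id"].map(oracle)
        assert len(merged) >= 35
        assert np.corrcoef(merged["slope_hat"], merged["oracle_s"])[0, 1] > 0.9

    def test_partial_pooling_shrinks_subject_slopes(self):
        """On sparse, noisy subjects the hierarchical estimates vary less
        across subjects than unpooled least-squares estimates."""
        design = StudyDesign(
            cohorts=(2,), subjects_per_cohort=20, years=1,
            continua=("a", "b"), days=1, reps=1,  # 14 trials per subject
        )
        truth = no_trend_truth(rv_base=600.0)
        trials, _ = simulate_study(design, truth, seed=13, attrition_rate=0.0,
                                   clip=False)
        data = assemble_unscreened(trials, 1)
        spec = HierarchicalSpec(chains=2, warmup=300, draws=300, seed=4,
                                max_leapfrog=32)
        post = fit_year(data, spec, testing_year=1, steps=7)
        idx = extract_subject_indices(post)
        oracle_s = []
        for sid, grp in data.groupby("subject_id"):
            try:
                oracle_s.append(oracle_subject_fit(grp)[0].s)
            except OracleFitError:
                continue
        assert len(oracle_s) >= 15
        assert idx["slope_hat"].var(ddof=1) < np.var(oracle_s, ddof=1)


def test_population_posterior_invariant_to_subject_relabeling(small_clean):
    """Permuting subject identities leaves population estimates unchanged
    (up to Monte Carlo error with a fixed seed order)."""
    from vascat.preprocess import assemble_year_dataset

    clean, reports = small_clean
    data = assemble_year_dataset(clean, reports, 2)
    spec = HierarchicalSpec(chains=2, warmup=300, draws=300, seed=21, max_leapfrog=32)
    base = fit_year(data, spec, testing_year=2, steps=7).summary().set_index("parameter")

    ids = sorted(data["subject_id"].unique())
    rng = np.random.default_rng(0)
    relabel = dict(zip(ids, rng.permutation(ids)))
    permuted = clean.copy()
    permuted["subject_id"] = permuted["subject_id"].map(relabel).fillna(permuted["subject_id"])
    data_p = assemble_year_dataset(permuted, reports.assign(
        subject_id=reports["subject_id"].map(relabel).fillna(reports["subject_id"])
    ), 2)
    perm = fit_year(data_p, spec, testing_year=2, steps=7).summary().set_index("parameter")
    for p in ["L0", "U0", "c0", "s0", "w0", "w1", "w2"]:
        pooled_sd = np.sqrt(0.5 * (base.loc[p, "sd"] ** 2 + perm.loc[p, "sd"] ** 2))
        assert abs(base.loc[p, "mean"] - perm.loc[p, "mean"]) < 0.5 * pooled_sd
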