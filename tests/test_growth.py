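"""Growth-curve models: centering, recovery, standardization, predictions,
practice contrast, and an independent R (lme4) cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from vascat.growth import (
    ModelingError,
    build_growth_dataset,
    first_session_contrast,
    fit_growth_model,
    marginal_predictions,
    simulate_growth_dataset,
)


def _dataset(**kwargs):
    defaults = dict(b0=10.0, sd_intercept=2.0, sd_year_slope=0.5, sd_resid=1.0)
    defaults.update(kwargs)
    n = defaults.pop("n_subjects", 60)
    seed = defaults.pop("seed", 0)
    d = simulate_growth_dataset(n, seed=seed, **defaults)
    return build_growth_dataset(d.rename(columns={"value": "y"}), "y")


class TestBuild:
    def test_balanced_centering_values(self):
        g = _dataset()
        assert sorted(g["year_c"].unique()) == [-1.5, -0.5, 0.5, 1.5]
        assert sorted(g["grade_c"].unique()) == [-1.0, 0.0, 1.0]

    def test_centered_columns_have_zero_mean(self):
        g = _dataset(n_subjects=61, seed=3)  # unbalanced grades
        assert abs(g["year_c"].mean()) < 1e-12
        assert abs(g["grade_c"].mean()) < 1e-12
        assert np.allclose(g["year_x_grade"], g["year_c"] * g["grade_c"])

    def test_constant_predictor_rejected(self):
        d = simulate_growth_dataset(10, seed=0)
        d["start_grade"] = 2
        with pytest.raises(ModelingError):
            build_growth_dataset(d.rename(columns={"value": "y"}), "y")

    def test_missing_outcome_rejected(self):
        d = simulate_growth_dataset(10, seed=0)
        with pytest.raises(ModelingError):
            build_growth_dataset(d, "nope")


class TestFit:
    def test_noise_free_linear_data_recovered_exactly(self):
        g = _dataset(b_year=-1.39, b_grade=2.42, b_interaction=-0.81,
                     sd_intercept=0.0, sd_year_slope=0.0, sd_resid=0.0, seed=1)
        fit = fit_growth_model(g)
        coef = fit.coef
        assert coef["year_c"] == pytest.approx(-1.39, abs=1e-8)
        assert coef["grade_c"] == pytest.approx(2.42, abs=1e-8)
        assert coef["year_c:grade_c"] == pytest.approx(-0.81, abs=1e-8)
        assert coef["Intercept"] == pytest.approx(10.0, abs=1e-8)

    def test_degenerate_fit_flagged_not_silent(self):
        g = _dataset(sd_intercept=0.0, sd_year_slope=0.0, sd_resid=0.0,
                     b_year=-1.0, seed=2)
        fit = fit_growth_model(g)
        assert fit.meta["structure"] != "maximal" or fit.meta["notes"]

    def test_standardized_beta_equals_scaled_b_on_balanced_data(self):
        g = _dataset(b_year=-1.0, b_grade=2.0, sd_intercept=0.0,
                     sd_year_slope=0.0, sd_resid=2.0, seed=4)
        fit = fit_growth_model(g)
        t = fit.table.set_index("term")
        sd_y = g["outcome"].std(ddof=1)
        for term, col in [("year_c", "year_c"), ("grade_c", "grade_c")]:
            manual = t.loc[term, "B"] * g[col].std(ddof=1) / sd_y
            assert t.loc[term, "beta_std"] == pytest.approx(manual, abs=1e-6)

    def test_df_conventions(self):
        g = _dataset(seed=5)
        res = fit_growth_model(g, df_method="residual")
        bw = fit_growth_model(g, df_method="between_within")
        n = len(g)
        n_vc = {"maximal": 4, "uncorrelated": 3, "intercept": 2}[res.meta["structure"]]
        assert res.table["df"].iloc[0] == n - 4 - n_vc
        assert 0 < bw.table["df"].iloc[0] < res.table["df"].iloc[0] + 4
        assert (res.table["CI_low"] < res.table["CI_high"]).all()

    def test_variance_components_sane(self):
        g = _dataset(sd_intercept=3.0, sd_year_slope=1.0, sd_resid=1.0, seed=6,
                     n_subjects=150)
        fit = fit_growth_model(g)
        assert fit.vc["var_intercept"] > 0
        assert fit.vc["resid_var"] > 0
        assert abs(fit.vc["corr_intercept_slope"]) <= 1.0
        # recovered intercept SD within a factor of ~2 of the true 3.0
        assert 1.5 < np.sqrt(fit.vc["var_intercept"]) < 6.0


class TestPredictions:
    def test_prediction_at_grand_means_is_intercept(self):
        g = _dataset(b_year=-1.0, b_grade=1.0, seed=7)
        fit = fit_growth_model(g)
        preds = marginal_predictions(fit, years=[fit.year_mean], grades=[fit.grade_mean])
        assert preds["predicted"].iloc[0] == pytest.approx(fit.coef["Intercept"], abs=1e-9)

    def test_parallel_cohort_lines_without_interaction(self):
        g = _dataset(b_year=-2.0, b_grade=1.0, b_interaction=0.0,
                     sd_intercept=0.0, sd_year_slope=0.0, sd_resid=0.0, seed=8)
        fit = fit_growth_model(g)
        preds = marginal_predictions(fit, years=[1, 2, 3, 4], grades=[1, 2, 3])
        slopes = preds.groupby("start_grade").apply(
            lambda p: np.polyfit(p["testing_year"], p["predicted"], 1)[0],
            include_groups=False,
        )
        assert np.allclose(slopes, slopes.iloc[0], atol=1e-8)

    def test_positive_interaction_flattens_oldest_cohort(self):
        """Negative year trend + positive interaction: the oldest start grade
        shows the flattest (least negative) predicted change."""
        g = _dataset(b0=250, b_year=-26.08, b_grade=-36.78, b_interaction=26.52,
                     sd_intercept=0.0, sd_year_slope=0.0, sd_resid=0.0, seed=9)
        fit = fit_growth_model(g)
        preds = marginal_predictions(fit, years=[1, 2, 3, 4], grades=[1, 2, 3])
        trend = {
            int(gr): np.polyfit(p["testing_year"], p["predicted"], 1)[0]
            for gr, p in preds.groupby("start_grade")
        }
        assert trend[1] < trend[2] < trend[3]
        assert trend[3] > -26.08 + 20  # oldest cohort nearly plateaued

    def test_out_of_range_grid_warns(self):
        fit = fit_growth_model(_dataset(seed=10))
        with pytest.warns(UserWarning):
            marginal_predictions(fit, years=[0.0], grades=[2.0])


class TestContrast:
    def _panel(self, fn, n=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal(20, 3)
            for yr in range(1, 5):
                rows.append({
                    "subject_id": i, "testing_year": yr, "y": fn(base, yr, rng),
                })
        return pd.DataFrame(rows)

    def test_constant_outcome_gives_exactly_zero(self):
        d = self._panel(lambda b, yr, rng: 42.0)
        c = first_session_contrast(d, "y")
        assert c.estimate == 0.0
        assert c.p == 1.0

    def test_linear_decline_gives_near_zero(self):
        d = self._panel(lambda b, yr, rng: b - 1.39 * yr, n=100)
        c = first_session_contrast(d, "y")
        assert abs(c.estimate) < 1e-9

    def test_one_time_jump_detected(self):
        d = self._panel(
            lambda b, yr, rng: b - 1.39 * yr + (4.0 if yr >= 2 else 0.0)
            + rng.normal(0, 1), n=200, seed=3,
        )
        c = first_session_contrast(d, "y")
        assert c.estimate > 2.0
        assert c.p < 0.01

    def test_insufficient_years_rejected(self):
        d = self._panel(lambda b, yr, rng: b)
        with pytest.raises(ModelingError):
            first_session_contrast(d[d["testing_year"] <= 2], "y")


R_SCRIPT = r"""
suppressMessages({library(lme4); library(lmerTest)})
d <- read.csv(commandArgs(trailingOnly = TRUE)[1])
m <- lmer(outcome ~ year_c * grade_c + (1 + year_c | subject_id), data = d, REML = TRUE,
          control = lmerControl(check.conv.singular = "ignore"))
s <- summary(m)$coefficients
write.csv(data.frame(term = rownames(s), B = s[, "Estimate"], SE = s[, "Std. Error"],
                     df = s[, "df"]), commandArgs(trailingOnly = TRUE)[2], row.names = FALSE)
"""


def test_agrees_with_r_lme4_reference(tmp_path):
    """Independent oracle: the same REML model in lme4 gives the same fixed
    effects and standard errors."""
    assert shutil.which("Rscript"), "Rscript expected on PATH in this stack"
    g = _dataset(b_year=-1.39, b_grade=2.42, b_interaction=-0.81,
                 sd_intercept=2.0, sd_year_slope=0.7, sd_resid=1.0,
                 n_subjects=120, seed=11)
    csv = tmp_path / "growth.csv"
    out = tmp_path / "r_fit.csv"
    g[["subject_id", "outcome", "year_c", "grade_c"]].to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(R_SCRIPT)
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv), str(out)],
        check=True, capture_output=True, text=True,
    )
    rfit = pd.read_csv(out)
    rfit["term"] = rfit["term"].str.replace("(Intercept)", "Intercept", regex=False)
    ours = fit_growth_model(g, standardize=False).table.set_index("term")
    for _, row in rfit.iterrows():
        assert ours.loc[row["term"], "B"] == pytest.approx(row["B"], rel=2e-3, abs=1e-4)
        assert ours.loc[row["term"], "SE"] == pytest.approx(row["SE"], rel=2e-2, abs=1e-3)
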