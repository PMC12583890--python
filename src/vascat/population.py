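"""Population ground truth for the synthetic accelerated-longitudinal study.

The generator draws, for every subject and testing year, the latent
four-parameter-logistic (4PL) parameters and a trial-noise level, applying
developmental trends to the midpoint slope and to the expected trial variance.
Default trend magnitudes mirror the reference growth-model estimates
(slope: -1.39 VAS/step per testing year, +2.42 per start grade, -0.81
interaction; response variability: -26.08 squared-VAS units per year,
-36.78 per grade, +26.52 interaction); everything is configurable.

Subject heterogeneity in trial variance is mean-corrected lognormal, so the
configured additive trends hold exactly in expectation; slope heterogeneity is
additive Gaussian with a subject-level intercept and year-slope, giving the
longitudinal growth models a well-specified target.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .fourpl import trial_sigma2


class GenerationError(RuntimeError):
    """Raised when valid latent parameters cannot be drawn."""


@dataclass(frozen=True)
class PopulationTruth:
    """Latent population parameters of the synthetic study."""

    # 4PL population means and between-subject SDs (VAS / step units)
    L_mean: float = 5.0
    L_sd: float = 4.0
    U_mean: float = 95.0
    U_sd: float = 4.0
    c_mean: float = 4.0
    c_sd: float = 0.5
    s_mean: float = 18.0
    s_sd: float = 6.0
    s_year_slope_sd: float = 1.0  # SD of per-subject year-slope on s

    # item (continuum) intercept SDs on L, U, c, s
    item_L_sd: float = 2.0
    item_U_sd: float = 2.0
    item_c_sd: float = 0.3
    item_s_sd: float = 2.0

    # quadratic log-variance profile over centered steps
    w1: float = 0.0
    w2: float = -0.15

    # expected step-averaged trial variance (squared VAS units) and its
    # lognormal subject heterogeneity (log-scale SDs, mean-corrected)
    rv_base: float = 250.0
    rv_subject_sd_log: float = 0.3
    rv_year_slope_sd_log: float = 0.06
    rv_floor: float = 30.0

    # developmental trends on centered testing year / start grade
    s_year: float = -1.39
    s_grade: float = 2.42
    s_year_grade: float = -0.81
    rv_year: float = -26.08
    rv_grade: float = -36.78
    rv_year_grade: float = 26.52

    # centering constants (grand means of the default balanced design)
    year_center: float = 2.5
    grade_center: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "L_sd", "U_sd", "c_sd", "s_sd", "s_year_slope_sd",
            "item_L_sd", "item_U_sd", "item_c_sd", "item_s_sd",
            "rv_subject_sd_log", "rv_year_slope_sd_log",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rv_base <= 0:
            raise ValueError("rv_base must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject latent deviations, constant across testing years."""

    dL: float
    dU: float
    dc: float
    s_intercept: float
    s_year_slope: float
    rv_log_intercept: float
    rv_log_year_slope: float


@dataclass(frozen=True)
class PsychometricParams:
    """Latent 4PL parameters plus noise level for one subject-year."""

    L: float
    U: float
    c: float
    s: float
    rv: float                 # step-averaged trial variance, squared VAS units
    log_var_intercept: float  # a in sigma^2(x) = exp(a + w1 d + w2 d^2)


def step_average_profile(steps: int, w1: float, w2: float) -> float:
    """Mean over steps of exp(w1 d + w2 d^2), d = step - mid.

    Converts between a log-variance intercept and the step-averaged variance.
    """
    grid = np.arange(1, steps + 1, dtype=float)
    mid = (1 + steps) / 2.0
    return float(np.mean(trial_sigma2(grid, 0.0, w1, w2, mid)))


def draw_subject_effects(truth: PopulationTruth, rng: np.random.Generator) -> SubjectEffects:
    return SubjectEffects(
        dL=rng.normal(0.0, truth.L_sd),
        dU=rng.normal(0.0, truth.U_sd),
        dc=rng.normal(0.0, truth.c_sd),
        s_intercept=rng.normal(0.0, truth.s_sd),
        s_year_slope=rng.normal(0.0, truth.s_year_slope_sd),
        rv_log_intercept=rng.normal(0.0, truth.rv_subject_sd_log),
        rv_log_year_slope=rng.normal(0.0, truth.rv_year_slope_sd_log),
    )


def draw_subject_params(
    truth: PopulationTruth,
    start_grade: int,
    testing_year: int,
    rng: np.random.Generator | int,
    *,
    effects: SubjectEffects | None = None,
    steps: int = 7,
    max_resample: int = 100,
) -> PsychometricParams:
    """Draw latent 4PL + noise parameters for one subject-year.

    ``effects`` carries the subject-level deviations shared across that
    subject's years; if omitted, fresh ones are drawn (useful for
    cross-sectional draws).  Deterministic given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    yc = testing_year - truth.year_center
    gc = start_grade - truth.grade_center
    if effects is None:
        effects = draw_subject_effects(truth, rng)

    for _ in range(max_resample):
        L = truth.L_mean + effects.dL
        U = truth.U_mean + effects.dU
        if U > L:
            break
        effects = draw_subject_effects(truth, rng)
    else:
        raise GenerationError("could not draw U > L within resampling budget")

    c = truth.c_mean + effects.dc
    s = (
        truth.s_mean
        + truth.s_year * yc
        + truth.s_grade * gc
        + truth.s_year_grade * yc * gc
        + effects.s_intercept
        + effects.s_year_slope * yc
    )

    rv_target = (
        truth.rv_base
        + truth.rv_year * yc
        + truth.rv_grade * gc
        + truth.rv_year_grade * yc * gc
    )
    eta = effects.rv_log_intercept + effects.rv_log_year_slope * yc
    # mean-one lognormal multiplier: E[exp(eta - var/2)] = 1
    eta_var = truth.rv_subject_sd_log**2 + (truth.rv_year_slope_sd_log * yc) ** 2
    rv = max(truth.rv_floor, rv_target * np.exp(eta - eta_var / 2.0))
    a = float(np.log(rv / step_average_profile(steps, truth.w1, truth.w2)))
    return PsychometricParams(L=float(L), U=float(U), c=float(c), s=float(s),
                              rv=float(rv), log_var_intercept=a)
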