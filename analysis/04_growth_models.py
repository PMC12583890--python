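"""Longitudinal growth-curve models on Slope and Response Variability.

For each outcome, fits a linear mixed model with centered testing year,
centered start grade and their interaction as fixed effects, and a by-subject
random intercept + random year slope.  Prints the coefficient tables
(B, 95% CI, t, df, p, standardized beta) and writes them with marginal
predictions under results/study/.  Also runs the first-session practice
contrast on the Slope index.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vascat.growth import (
    build_growth_dataset,
    first_session_contrast,
    fit_growth_model,
    marginal_predictions,
)

OUT = Path("results/study")


def main() -> None:
    indices = pd.read_csv(OUT / "subject_indices.csv")
    for outcome, label in [("slope_hat", "slope"), ("rv_hat", "rv")]:
        data = build_growth_dataset(indices, outcome)
        fit = fit_growth_model(data)
        fit.table.to_csv(OUT / f"growth_{label}.csv", index=False)
        preds = marginal_predictions(fit, years=[1, 2, 3, 4], grades=[1, 2, 3])
        preds.to_csv(OUT / f"predictions_{label}.csv", index=False)
        print(f"\n=== {outcome} ===  (random-effects structure: {fit.meta['structure']})")
        cols = ["term", "B", "CI_low", "CI_high", "t", "df", "p", "beta_std"]
        print(fit.table[cols].round(4).to_string(index=False))
        year_b = fit.coef["year_c"]
        print(f"-> year effect {year_b:+.2f}: "
              + ("developmental decrease" if year_b < 0 else "increase"))

    contrast = first_session_contrast(indices, "slope_hat")
    print(
        f"\npractice contrast (slope): {contrast.estimate:+.3f} "
        f"[{contrast.ci_low:.3f}, {contrast.ci_high:.3f}], p = {contrast.p:.3f} "
        f"({'no one-time jump' if contrast.p > 0.05 else 'jump detected'})"
    )


if __name__ == "__main__":
    main()
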