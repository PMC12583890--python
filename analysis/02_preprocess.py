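"""Normalize VAS orientation and apply the validity screen.

Raw ratings from picture-swapped blocks are reversed (100 - rating) so high
values always mean "sounds like the step-7 endpoint", then each
participant-year is screened: the mean response profile must reach 25 on its
low end and 75 on its high end, pooled over continua.  Exclusions are
year-specific.  Writes results/study/clean_trials.csv and screen_report.csv.
"""

from pathlib import Path

from vascat.preprocess import normalize_orientation, screen_all
from vascat.simulate import load_trials

OUT = Path("results/study")


def main() -> None:
    trials = load_trials(OUT / "trials.csv")
    clean = normalize_orientation(trials)
    reports = screen_all(clean, steps=7)
    clean.to_csv(OUT / "clean_trials.csv", index=False, float_format="%.17g")
    reports.to_csv(OUT / "screen_report.csv", index=False)
    kept = int(reports["kept"].sum())
    print(f"validity screen kept {kept}/{len(reports)} participant-years")
    for reason, n in reports.loc[~reports["kept"], "reason"].value_counts().items():
        print(f"  excluded ({reason}): {n}")


if __name__ == "__main__":
    main()
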