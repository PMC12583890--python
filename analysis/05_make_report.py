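"""Assemble figures and the plain-text report for the completed run.

Produces the mean categorization functions by grade, predicted Slope and
Response Variability trajectories per start-grade cohort, the coefficient
tables, and a summary of whether recovered effect signs agree with the
generating trends.  Everything lands in results/study/.
"""

from pathlib import Path

from vascat.pipeline import make_report

OUT = Path("results/study")


def main() -> None:
    report = make_report(OUT)
    print(f"wrote {report}")
    for fig in sorted(OUT.glob("fig_*.png")):
        print(f"  figure: {fig.name}")


if __name__ == "__main__":
    main()
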