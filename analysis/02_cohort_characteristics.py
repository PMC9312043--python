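#!/usr/bin/env python
"""Characterise the cohort by subtype (descriptives, tests, residual flags).

Reads results/cohort.csv (run 01 first), keeps complete cases, and writes the
characteristics table — counts (%) or mean ± SD per subtype, Kruskal-Wallis
or chi-square p-values, and adjusted-residual flags — to
results/cohort_characteristics.csv.
"""

from pathlib import Path

from msadx.registry import Cohort, exclude_incomplete
from msadx.report import summarize_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = Cohort.read_csv(RESULTS / "cohort.csv")
    kept, _ = exclude_incomplete(cohort)
    summary = summarize_cohort(kept)
    summary.to_csv(RESULTS / "cohort_characteristics.csv", index=False)
    n_sig = (summary["p"].isin(["<0.001"])
             | (summary["p"].str.match(r"^0\.0[0-4]"))).sum()
    print(f"{len(summary)} table rows; {n_sig} with p < 0.05")
    flagged = summary[(summary[[f"flag_{s}" for s in ("SND", "SDS", "OPCA")]]
                       != "").any(axis=1)]
    print(f"{len(flagged)} rows carry residual flags; examples:")
    print(flagged.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
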