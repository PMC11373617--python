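"""Engineer all feature blocks and assemble the 203-column design matrix.

Runs the scoring chains (pathway disruption / TMB / CNV burden from the
variant and CNV tables; H-scores from IHC cores; SUV metrics from the
phantoms) and joins them with the clinical block and biopsy ISUP, then
reports the whole-dataset missingness exclusion at the 30% threshold.
"""

import sys
from collections import Counter
from pathlib import Path

import psma_multiomics as pm

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cohort = pm.generate_cohort(pm.CohortConfig(seed=SEED))
    table = pm.cohort_design_matrix(cohort)
    widths = Counter(table.categories.values())
    print(f"design matrix: {table.data.shape[0]} patients x {table.data.shape[1]} features")
    print(f"per category: {dict(widths)}")

    filtered, report = pm.missingness_filter(table, threshold=0.30)
    dropped = report[report["dropped"]]
    print(f"whole-dataset >30% missingness exclusion drops {len(dropped)} features:")
    for name, row in dropped.iterrows():
        print(f"  {name}: {row['missing_fraction']:.0%} missing")

    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "design_matrix.csv")
    report.to_csv(OUT / "missingness_report.csv")
    print(f"written to {OUT / 'design_matrix.csv'}")


if __name__ == "__main__":
    main()
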