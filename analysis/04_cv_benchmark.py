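"""Benchmark the five classifier families under Monte Carlo CV and compare
the best model with the biopsy-grade-alone baseline.

Runs a planted-signal cohort (three 1.5-SD features, informative biopsy
grade) through the full leakage-free pipeline.  Fold count and search
budget are scaled for a desk-side run; pass folds/budget as arguments for
larger runs.
"""

import sys
from pathlib import Path

import pandas as pd

import psma_multiomics as pm

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
FOLDS = int(sys.argv[2]) if len(sys.argv) > 2 else 25
BUDGET = int(sys.argv[3]) if len(sys.argv) > 3 else 3

PLANTED = {
    "rad::glcm::JointEnergy": -1.5,
    "rad::firstorder::Maximum": 1.5,
    "ihc::PSA::max": -1.5,
}


def main() -> None:
    cohort = pm.generate_cohort(pm.CohortConfig(seed=SEED, effect_map=dict(PLANTED)))
    table = pm.cohort_design_matrix(cohort)
    rows = {}
    for algo in ("knn", "rf", "xgb", "svm", "lgr"):
        cfg = pm.PipelineConfig(algorithm=algo, n_folds=FOLDS, search_budget=BUDGET, seed=SEED)
        summ, _ = pm.run_experiment(table, cfg)
        rows[algo] = summ.metrics_mean
        ci = summ.metrics_ci["AUC"]
        print(f"{algo}: AUC {summ.metrics_mean['AUC']:.3f} (95% CI {ci[0]:.2f}-{ci[1]:.2f})")

    # baseline: biopsy ISUP as the only input feature
    bx_only = pm.subset_categories(table, ["bxISUP"])
    cfg = pm.PipelineConfig(algorithm="lgr", n_folds=FOLDS, search_budget=1,
                            mrmr_k_grid=(1,), seed=SEED)
    summ, _ = pm.run_experiment(bx_only, cfg)
    rows["bxISUP alone"] = summ.metrics_mean
    print(f"bxISUP alone: AUC {summ.metrics_mean['AUC']:.3f}")

    metrics = pd.DataFrame(rows).T
    OUT.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(OUT / "model_metrics.csv")
    best = metrics["AUC"].idxmax()
    print(f"\nbest by AUC: {best}; full table written to {OUT / 'model_metrics.csv'}")


if __name__ == "__main__":
    main()
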