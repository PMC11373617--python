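"""Explain the final whole-dataset random-forest model: permutation
importance (per feature and per category), Monte Carlo Shapley values, and
the surrogate decision-tree workflow with its fidelity."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import psma_multiomics as pm
from psma_multiomics.explain import (
    category_importance,
    fit_surrogate,
    permutation_importance,
    shapley_estimate,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "explain"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

PLANTED = {
    "rad::glcm::JointEnergy": -1.5,
    "rad::firstorder::Maximum": 1.5,
    "ihc::PSA::max": -1.5,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = pm.generate_cohort(pm.CohortConfig(seed=SEED, effect_map=dict(PLANTED)))
    table = pm.cohort_design_matrix(cohort)
    final = pm.fit_final_model(table, pm.PipelineConfig("rf", search_budget=5, seed=SEED),
                               n_features=8)
    print(f"final RF model on 8 mRMR features: {final.features}")

    perm = permutation_importance(final.score, final.X, final.y, n_repeats=10, seed=SEED)
    perm["rank"] = perm["mean"].rank(ascending=False).astype(int)
    perm["category"] = [table.categories.get(f, "?") for f in perm.index]
    perm.sort_values("mean", ascending=False).to_csv(OUT / "permutation_importance.csv")
    print("\ntop 10 by permutation importance (mean AUC drop):")
    print(perm["mean"].nlargest(10).round(4).to_string())

    cat = category_importance(perm["mean"], table.categories)
    cat.to_csv(OUT / "category_importance.csv")
    print("\nmean importance per feature category:")
    print(cat.round(5).to_string())

    rng = np.random.default_rng(SEED)
    audit = rng.choice(len(final.X), size=20, replace=False)
    shap_rows = {}
    for i in audit:
        pid = final.X.index[i]
        shap_rows[pid] = shapley_estimate(
            final.score, final.X[final.features], final.X.iloc[i][final.features],
            n_coalitions=160, seed=int(i),
        )
    shap = pd.DataFrame(shap_rows).T
    shap.to_csv(OUT / "shapley_values.csv")
    print("\nmean |Shapley| over 20 audited patients:")
    print(shap.abs().mean().sort_values(ascending=False).round(4).to_string())

    sur = fit_surrogate(final.score, final.X[final.features], max_depth=3, seed=SEED)
    (OUT / "surrogate_flowchart.txt").write_text(sur.flowchart() + "\n")
    import json

    (OUT / "surrogate.json").write_text(json.dumps(sur.to_json_dict(), indent=2))
    print(f"\nsurrogate tree fidelity AUC vs RF predictions: {sur.fidelity_auc:.3f}")
    print("simplified diagnostic workflow:")
    print(sur.flowchart())


if __name__ == "__main__":
    main()
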