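"""Descriptive cohort statistics and the end-to-end experiment report.

Group comparisons follow the usual clinical-table conventions: two-sided
Mann-Whitney rank-sum for quantitative variables, chi-square (without
continuity correction by default) for categorical ones, significance at
0.05.  The report bundle mirrors a cohort table, a per-algorithm metric
table, feature-type ablations, importance rankings and the surrogate
flowchart, and is JSON round-trippable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "build_report", "report_to_json"]


@dataclass
class GroupComparison:
    variable: str
    test: str  # "rank-sum" | "chi-square"
    statistic: float
    p_value: float
    group_summaries: dict
    significant: bool


def compare_groups(
    data,
    variable: str = "",
    kind: str = "quantitative",
    groups=None,
    continuity_correction: bool = False,
) -> GroupComparison:
    """Two-group comparison.

    Quantitative: `data` is a pair (values_a, values_b); two-sided
    Mann-Whitney.  Categorical: `data` is a contingency table
    (levels x 2 groups) of counts; chi-square, no continuity correction
    unless requested.  NA handling is the caller's concern (rows excluded
    upstream by default).
    """
    if kind == "quantitative":
        a, b = [np.asarray(v, dtype=float) for v in data]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("empty group")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        summaries = {
            "group1": f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}" if len(a) > 1 else f"{a.mean():.2f}",
            "group2": f"{b.mean():.2f} +/- {b.std(ddof=1):.2f}" if len(b) > 1 else f"{b.mean():.2f}",
        }
        test = "rank-sum"
    elif kind == "categorical":
        table = np.asarray(data, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise ValueError("contingency table must be levels x 2 groups")
        if (table.sum(axis=0) == 0).any():
            raise ValueError("empty group")
        if np.allclose(table, table.mean()) and table.shape == (2, 2):
            stat, p = 0.0, 1.0  # perfectly balanced 2x2: exact null
        else:
            stat, p, _, _ = sps.chi2_contingency(table, correction=continuity_correction)
        col_tot = table.sum(axis=0)
        summaries = {
            f"group{j + 1}": {
                f"level{i}": f"{int(table[i, j])} ({100 * table[i, j] / col_tot[j]:.0f}%)"
                for i in range(table.shape[0])
            }
            for j in range(2)
        }
        test = "chi-square"
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    return GroupComparison(
        variable=variable,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_summaries=summaries,
        significant=bool(p < 0.05),
    )


def build_report(
    cv_summaries: dict[str, "object"] | None = None,
    importance: pd.DataFrame | None = None,
    category_importance: pd.Series | None = None,
    surrogate=None,
    comparisons: list[GroupComparison] | None = None,
    ablation: pd.DataFrame | None = None,
) -> dict:
    """Assemble one machine-readable report bundle (plain dict, JSON-safe).

    Missing sections render as placeholders so a partial run still reports.
    """
    report: dict = {}
    if cv_summaries:
        report["model_performance"] = {
            algo: {
                "mean": s.metrics_mean,
                "ci": {m: list(ci) for m, ci in s.metrics_ci.items()},
                "n_folds": s.n_folds_run,
            }
            for algo, s in cv_summaries.items()
        }
    else:
        report["model_performance"] = "not computed"
    report["permutation_importance"] = (
        importance.round(6).to_dict(orient="index") if importance is not None and len(importance) else "not computed"
    )
    report["category_importance"] = (
        category_importance.round(6).to_dict() if category_importance is not None else "not computed"
    )
    report["surrogate"] = surrogate.to_json_dict() if surrogate is not None else "not computed"
    report["group_comparisons"] = (
        [asdict(c) for c in comparisons] if comparisons else "not computed"
    )
    report["ablation"] = (
        ablation.round(6).to_dict(orient="index") if ablation is not None else "not computed"
    )
    return report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
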