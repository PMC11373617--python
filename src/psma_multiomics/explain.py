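"""Model explainability: permutation importance, Monte Carlo Shapley
values, category-level aggregation, and surrogate decision-tree extraction.

The surrogate workflow fits a shallow decision tree to the reference
model's *predicted labels* and reports a fidelity AUC — how well the tree
reproduces the black box on held-out rows — plus a human-readable rule
list in the style of a clinical decision flowchart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "permutation_importance",
    "category_importance",
    "shapley_estimate",
    "SurrogateTree",
    "fit_surrogate",
]


def permutation_importance(
    score_fn,
    X: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature AUC drop under within-column permutation.

    ``score_fn(X) -> scores``; importance of a feature is the baseline AUC
    minus the mean AUC over `n_repeats` independent permutations of that
    column.  A feature the model ignores scores exactly 0.  Returns a frame
    with columns mean / sd indexed by feature.
    """
    yv = y.to_numpy()
    if len(np.unique(yv)) < 2:
        raise ValueError("single-class data: permutation importance undefined")
    rng = np.random.default_rng(seed)
    baseline = roc_auc_score(yv, score_fn(X))
    rows = {}
    for col in X.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(baseline - roc_auc_score(yv, score_fn(Xp)))
        rows[col] = {"mean": float(np.mean(drops)), "sd": float(np.std(drops))}
    return pd.DataFrame(rows).T


def category_importance(
    importances: pd.Series, categories: dict[str, str]
) -> pd.Series:
    """Unweighted mean importance over the features of each category;
    categories with no features present are simply absent."""
    missing = [f for f in importances.index if f not in categories]
    if missing:
        raise ValueError(f"untagged features: {missing[:5]}")
    tags = pd.Series({f: categories[f] for f in importances.index})
    return importances.groupby(tags).mean().sort_values(ascending=False)


def shapley_estimate(
    score_fn,
    background: pd.DataFrame,
    x: pd.Series,
    n_coalitions: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Monte Carlo Shapley values for one patient against a marginal
    background.

    Random feature permutations are swept; each feature's marginal
    contribution is the score change when it switches from a random
    background row's value to the patient's value, with earlier features
    already set to the patient and later ones to the background row.
    Additivity — values summing to score(x) minus the mean background
    score — holds within Monte Carlo error.
    """
    p = len(x)
    if n_coalitions < 2 * p:
        raise ValueError(f"n_coalitions={n_coalitions} < 2 x n_features={2 * p}")
    rng = np.random.default_rng(seed)
    cols = list(background.columns)
    bg = background.to_numpy(dtype=float)
    xv = x.reindex(cols).to_numpy(dtype=float)
    contrib = np.zeros(p)
    n_perms = n_coalitions // p
    for _ in range(n_perms):
        order = rng.permutation(p)
        base = bg[rng.integers(0, len(bg))].copy()
        current = base.copy()
        prev = float(score_fn(pd.DataFrame([current], columns=cols))[0])
        for j in order:
            current[j] = xv[j]
            new = float(score_fn(pd.DataFrame([current], columns=cols))[0])
            contrib[j] += new - prev
            prev = new
    return pd.Series(contrib / n_perms, index=cols)


@dataclass
class SurrogateTree:
    """Shallow decision tree approximating a reference model."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    fidelity_auc: float
    rules: list[str] = field(default_factory=list)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.tree.predict_proba(X[self.feature_names].to_numpy())[:, 1]

    def used_features(self) -> set[str]:
        t = self.tree.tree_
        return {
            self.feature_names[f] for f in t.feature[t.feature >= 0]
        }

    def flowchart(self) -> str:
        """Plain-text decision flowchart of the surrogate workflow."""
        t = self.tree.tree_
        lines: list[str] = []

        def walk(node: int, depth: int) -> None:
            pad = "  " * depth
            if t.feature[node] < 0:
                frac = t.value[node][0]
                call = "HIGH risk" if frac[-1] >= frac[0] else "LOW risk"
                lines.append(f"{pad}-> predict {call}")
                return
            name = self.feature_names[t.feature[node]]
            thr = t.threshold[node]
            lines.append(f"{pad}{name} <= {thr:.3f}?")
            lines.append(f"{pad}yes:")
            walk(t.children_left[node], depth + 1)
            lines.append(f"{pad}no:")
            walk(t.children_right[node], depth + 1)

        walk(0, 0)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        t = self.tree.tree_

        def node(i: int) -> dict:
            if t.feature[i] < 0:
                frac = t.value[i][0]
                return {"leaf": True, "p_high": float(frac[-1] / frac.sum())}
            return {
                "leaf": False,
                "feature": self.feature_names[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i]),
            }

        return {"fidelity_auc": self.fidelity_auc, "root": node(0)}


def fit_surrogate(
    score_fn,
    X: pd.DataFrame,
    max_depth: int = 3,
    threshold: float = 0.5,
    seed: int = 0,
) -> SurrogateTree:
    """Distill a reference model into a depth-limited decision tree.

    The tree is trained on the reference model's predicted labels
    (score >= threshold) over a 70% split of `X`; fidelity is the AUC of
    the tree's probability against the reference predicted label on the
    held-out 30%.
    """
    ref_scores = np.asarray(score_fn(X), dtype=float)
    ref_labels = (ref_scores >= threshold).astype(int)
    if len(np.unique(ref_labels)) < 2:
        raise ValueError("reference predictions are constant; surrogate undefined")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(X))
    n_fit = int(round(0.7 * len(X)))
    fit_idx, hold_idx = idx[:n_fit], idx[n_fit:]
    # guard: both reference classes must appear in both partitions
    if len(np.unique(ref_labels[fit_idx])) < 2 or len(np.unique(ref_labels[hold_idx])) < 2:
        order = np.argsort(ref_labels)
        interleaved = np.empty(len(X), dtype=int)
        interleaved[0::2] = order[: (len(X) + 1) // 2]
        interleaved[1::2] = order[(len(X) + 1) // 2:]
        fit_idx = interleaved[0::2]
        hold_idx = interleaved[1::2]
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X.iloc[fit_idx].to_numpy(), ref_labels[fit_idx])
    hold_prob = tree.predict_proba(X.iloc[hold_idx].to_numpy())[:, 1]
    fidelity = float(roc_auc_score(ref_labels[hold_idx], hold_prob))
    surrogate = SurrogateTree(tree=tree, feature_names=list(X.columns), fidelity_auc=fidelity)
    surrogate.rules = surrogate.flowchart().splitlines()
    return surrogate
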