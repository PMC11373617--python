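"""Leakage-free Monte Carlo cross-validation engine.

Evaluation protocol: repeated independent stratified 70/30 train/test
splits (default 100 folds).  Inside every fold, fitted strictly on the
training partition: the >30% missingness filter, distance-weighted kNN
imputation, z-scoring, mRMR feature selection (MID criterion, mutual
information on equal-frequency bins), random-search hyperparameter tuning
of one of five classifier families (kNN, random forest, gradient-boosted
trees, SVM, logistic regression) and isotonic probability calibration.
The test partition is only ever transformed with train-fitted parameters
and scored.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "FoldSpec",
    "PipelineConfig",
    "CvFoldResult",
    "CvSummary",
    "make_folds",
    "knn_impute",
    "zscore",
    "mrmr_select",
    "tune_and_train",
    "calibrate",
    "evaluate",
    "run_experiment",
]

ALGORITHMS = ("knn", "rf", "xgb", "svm", "lgr")
METRICS = ("AUC", "ACC", "SNS", "SPC", "PPV", "NPV")


# ---------------------------------------------------------------- folds


@dataclass(frozen=True)
class FoldSpec:
    index: int
    train_ids: tuple
    test_ids: tuple
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_folds(
    labels: pd.Series, n_folds: int = 100, train_frac: float = 0.70, seed: int = 0
) -> list[FoldSpec]:
    """Independent stratified random splits (Monte Carlo cross-validation).

    Per-class training counts are the nearest integer to train_frac * class
    size; if their sum misses the rounded total training size, the larger
    class is adjusted by +/-1.
    """
    y = labels.astype(int)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    by_class = {c: y.index[y == c].to_numpy() for c in classes}
    if any(len(v) < 2 for v in by_class.values()):
        raise ValueError("each class needs >= 2 members for stratified splitting")
    total_train = _round_half_up(train_frac * len(y))
    n_train = {c: _round_half_up(train_frac * len(v)) for c, v in by_class.items()}
    larger = max(classes, key=lambda c: len(by_class[c]))
    n_train[larger] += total_train - sum(n_train.values())
    for c in classes:
        if not (1 <= n_train[c] < len(by_class[c])):
            raise ValueError(f"class {c} too small to stratify at train_frac={train_frac}")

    rng = np.random.default_rng(seed)
    folds = []
    for i in range(n_folds):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        frng = np.random.default_rng(fold_seed)
        train: list = []
        for c in classes:
            ids = by_class[c].copy()
            frng.shuffle(ids)
            train.extend(ids[: n_train[c]])
        train_set = set(train)
        test = [pid for pid in y.index if pid not in train_set]
        folds.append(FoldSpec(i, tuple(sorted(train)), tuple(test), fold_seed))
    return folds


# ---------------------------------------------------------------- transforms


def knn_impute(
    train: pd.DataFrame, test: pd.DataFrame, k: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Distance-weighted kNN imputation, donors drawn from the training
    block only.  Distances are computed on train-min-max-scaled features
    (imputation precedes z-scoring, so an internal scaling keeps the
    Euclidean metric commensurable); observed values pass through.
    """
    if len(train) < k:
        raise ValueError(f"training block has {len(train)} rows < k={k}")
    fully_missing = train.columns[train.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(
            f"columns fully missing in train (filter them first): {list(fully_missing)[:5]}"
        )
    lo = train.min(axis=0)
    span = (train.max(axis=0) - lo).replace(0.0, 1.0)
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    tr_scaled = (train - lo) / span
    te_scaled = (test - lo) / span
    tr_imp = imputer.fit_transform(tr_scaled)
    te_imp = imputer.transform(te_scaled) if len(test) else np.empty((0, train.shape[1]))
    params = {"minmax_lo": lo, "minmax_span": span, "k": k}
    out_tr = pd.DataFrame(tr_imp, index=train.index, columns=train.columns) * span + lo
    out_te = pd.DataFrame(te_imp, index=test.index, columns=test.columns) * span + lo
    return out_tr, out_te, params


def zscore(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Standardize with train means and population SDs; constant train
    columns map to all-zeros (with a warning)."""
    if len(train) < 2:
        raise ValueError("z-scoring needs >= 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        log.warning("%d constant training columns mapped to zeros", int(zero.sum()))
    sd_safe = sd.replace(0.0, 1.0)
    out_tr = (train - mean) / sd_safe
    out_te = (test - mean) / sd_safe
    out_tr.loc[:, zero] = 0.0
    if len(test):
        out_te.loc[:, zero] = 0.0
    return out_tr, out_te, {"mean": mean, "sd": sd}


# ---------------------------------------------------------------- mRMR


def _equal_frequency_codes(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-column equal-frequency discretization into integer codes."""
    n, p = X.shape
    codes = np.empty((n, p), dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(p):
        col = X[:, j]
        edges = np.unique(np.quantile(col, qs))
        codes[:, j] = np.searchsorted(edges, col, side="right")
    return codes


def _mi_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two integer-coded vectors."""
    n = len(a)
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_select(X: pd.DataFrame, y: pd.Series, k: int) -> list[str]:
    """Greedy mRMR forward selection, MID criterion.

    Relevance is the mutual information between feature and label;
    redundancy the mean MI with already-selected features; at each step the
    feature maximizing (relevance - redundancy) is added.  MI is estimated
    after equal-frequency discretization into min(5, n // 5) bins.
    Deterministic: ties resolve to the earliest column.
    """
    cols = list(X.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds {len(cols)} candidate features")
    n = len(X)
    n_bins = max(2, min(5, n // 5))
    codes = _equal_frequency_codes(X.to_numpy(dtype=float), n_bins)
    ycodes = y.to_numpy(dtype=np.int64)
    relevance = np.array([_mi_from_codes(codes[:, j], ycodes) for j in range(len(cols))])

    selected: list[int] = []
    redundancy_sum = np.zeros(len(cols))
    for _ in range(k):
        remaining = [j for j in range(len(cols)) if j not in selected]
        if selected:
            scores = [
                relevance[j] - redundancy_sum[j] / len(selected) for j in remaining
            ]
        else:
            scores = [relevance[j] for j in remaining]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        for j in range(len(cols)):
            if j not in selected:
                redundancy_sum[j] += _mi_from_codes(codes[:, j], codes[:, best])
    return [cols[j] for j in selected]


# ---------------------------------------------------------------- models


_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 7, 9, 11], "weights": ["uniform", "distance"]},
    "rf": {
        "n_estimators": [100, 200],
        "max_depth": [None, 3, 5, 8],
        "max_features": ["sqrt", 0.5],
        "min_samples_leaf": [1, 2, 4],
    },
    "xgb": {
        "n_estimators": [50, 100],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1, 0.3],
        "subsample": [0.7, 1.0],
    },
    "svm": {"C": [0.1, 1.0, 10.0, 100.0], "kernel": ["rbf", "linear"], "gamma": ["scale", "auto"]},
    "lgr": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
}


def _build_model(algorithm: str, params: dict, seed: int):
    if algorithm == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(**params)
    if algorithm == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **params
        )
    if algorithm == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed, **params)  # scores via decision_function
    if algorithm == "lgr":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _raw_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score: probability where available,
    otherwise a logistic squash of the decision function (keeps [0, 1])."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    z = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class PipelineConfig:
    algorithm: str = "rf"
    impute_k: int = 5
    mrmr_k_grid: tuple[int, ...] = (4, 8, 16)
    search_budget: int = 10
    inner_splits: int = 3
    calibration: bool = True
    threshold: float = 0.5
    n_folds: int = 100
    train_frac: float = 0.70
    missing_threshold: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.search_budget < 1 or self.inner_splits < 1 or self.n_folds < 1:
            raise ValueError("budgets must be >= 1")


def _sample_params(rng: np.random.Generator, algorithm: str, mrmr_k_grid) -> dict:
    space = _SEARCH_SPACES[algorithm]
    params = {name: opts[rng.integers(0, len(opts))] for name, opts in space.items()}
    params["n_features"] = int(mrmr_k_grid[rng.integers(0, len(mrmr_k_grid))])
    return params


def tune_and_train(
    config: PipelineConfig,
    X: pd.DataFrame,
    y: pd.Series,
    ranked_features: list[str],
    seed: int,
):
    """Random-search tuning on inner stratified splits of the training fold,
    then refit of the winning configuration.

    The mRMR-selected feature count is itself tuned: each draw uses the
    first `n_features` of the (nested) greedy ranking.  Returns
    (fitted model, chosen params, used feature names).
    """
    if y.nunique() < 2:
        raise ValueError("degenerate training labels")
    rng = np.random.default_rng(seed)
    draws = [
        _sample_params(rng, config.algorithm, config.mrmr_k_grid)
        for _ in range(config.search_budget)
    ]
    best_score, best_params = -np.inf, None
    if config.search_budget > 1:
        inner = make_folds(
            y, n_folds=config.inner_splits, train_frac=0.7,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for params in draws:
            feats = ranked_features[: min(params["n_features"], len(ranked_features))]
            aucs = []
            for f in inner:
                ytr, yva = y.loc[list(f.train_ids)], y.loc[list(f.test_ids)]
                if yva.nunique() < 2:
                    continue
                m = _build_model(
                    config.algorithm,
                    {k: v for k, v in params.items() if k != "n_features"},
                    seed=int(f.seed),
                )
                m.fit(X.loc[list(f.train_ids), feats].to_numpy(), ytr.to_numpy())
                aucs.append(
                    roc_auc_score(yva.to_numpy(), _raw_scores(m, X.loc[list(f.test_ids), feats].to_numpy()))
                )
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best_score:
                best_score, best_params = score, params
    if best_params is None:
        best_params = draws[0]
    feats = ranked_features[: min(best_params["n_features"], len(ranked_features))]
    model = _build_model(
        config.algorithm,
        {k: v for k, v in best_params.items() if k != "n_features"},
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    model.fit(X[feats].to_numpy(), y.to_numpy())
    return model, best_params, feats


def _cross_predicted_scores(
    config: "PipelineConfig", X: pd.DataFrame, y: pd.Series, params: dict, seed: int,
    n_parts: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold raw scores within the training fold, for calibration.

    Stratified partition into `n_parts`; each part is scored by a model of
    the chosen configuration fitted on the other parts.
    """
    rng = np.random.default_rng(seed)
    parts: list[list] = [[] for _ in range(n_parts)]
    for c in sorted(y.unique()):
        ids = y.index[y == c].to_numpy()
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            parts[i % n_parts].append(pid)
    scores, labels = [], []
    model_params = {k: v for k, v in params.items() if k != "n_features"}
    for i, part in enumerate(parts):
        rest = [pid for j, p_ in enumerate(parts) if j != i for pid in p_]
        if y.loc[rest].nunique() < 2 or not part:
            continue
        m = _build_model(config.algorithm, model_params, seed=seed + i)
        m.fit(X.loc[rest].to_numpy(), y.loc[rest].to_numpy())
        scores.append(_raw_scores(m, X.loc[part].to_numpy()))
        labels.append(y.loc[part].to_numpy())
    return np.concatenate(scores), np.concatenate(labels)


def calibrate(raw_scores: np.ndarray, labels: np.ndarray):
    """Fit an isotonic (monotone nondecreasing) map raw score -> [0, 1].

    Returns a callable; with fewer than two distinct raw scores the map is
    the identity (warning).  Monotonicity preserves the rank order, hence
    the AUC, of any score vector it is applied to.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    if len(np.unique(raw_scores)) < 2:
        log.warning("constant raw scores: isotonic calibration degenerates to identity")
        return lambda s: np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(raw_scores, np.asarray(labels, dtype=float))

    def mapper(s):
        s = np.asarray(s, dtype=float)
        # tiny raw-score admixture keeps the map *strictly* increasing, so
        # isotonic plateaus do not collapse distinct ranks into ties
        return (1.0 - 1e-6) * iso.predict(s) + 1e-6 * np.clip(s, 0.0, 1.0)

    return mapper


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """AUC (midrank tie convention) plus confusion metrics at `threshold`.
    Positive class = high risk (label 1)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class test set: metrics undefined")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "AUC": float(roc_auc_score(y, s)),
            "ACC": (tp + tn) / len(y),
            "SNS": tp / (tp + fn) if tp + fn else float("nan"),
            "SPC": tn / (tn + fp) if tn + fp else float("nan"),
            "PPV": tp / (tp + fp) if tp + fp else float("nan"),
            "NPV": tn / (tn + fn) if tn + fn else float("nan"),
        }


# ---------------------------------------------------------------- engine


@dataclass
class CvFoldResult:
    index: int
    selected_features: list[str]
    params: dict
    test_scores: pd.Series  # calibrated probabilities per test patient
    metrics: dict[str, float]
    model: object = field(repr=False, default=None)
    preprocessing: dict = field(repr=False, default_factory=dict)


@dataclass
class CvSummary:
    metrics_mean: dict[str, float]
    metrics_ci: dict[str, tuple[float, float]]
    selection_frequency: pd.Series
    n_folds_run: int
    n_folds_failed: int
    per_fold: pd.DataFrame

    def table(self) -> pd.DataFrame:
        rows = {
            m: {
                "mean": self.metrics_mean[m],
                "ci_low": self.metrics_ci[m][0],
                "ci_high": self.metrics_ci[m][1],
            }
            for m in METRICS
        }
        return pd.DataFrame(rows).T


def _run_fold(table, fold: FoldSpec, config: PipelineConfig) -> CvFoldResult:
    X, y = table.data, table.labels
    tr_ids, te_ids = list(fold.train_ids), list(fold.test_ids)
    Xtr, Xte = X.loc[tr_ids], X.loc[te_ids]
    ytr, yte = y.loc[tr_ids], y.loc[te_ids]

    # train-fitted missingness filter
    frac = Xtr.isna().mean(axis=0)
    keep = frac.index[frac <= config.missing_threshold]
    Xtr, Xte = Xtr[keep], Xte[keep]

    Xtr, Xte, imp_params = knn_impute(Xtr, Xte, k=config.impute_k)
    Xtr, Xte, z_params = zscore(Xtr, Xte)

    max_k = min(max(config.mrmr_k_grid), Xtr.shape[1])
    ranked = mrmr_select(Xtr, ytr, max_k)

    model, params, feats = tune_and_train(config, Xtr, ytr, ranked, seed=fold.seed)
    raw_te = _raw_scores(model, Xte[feats].to_numpy())
    if config.calibration:
        # isotonic map fitted on out-of-fold cross-predicted training
        # scores: every calibration score comes from a model that did not
        # see that row, while the final model keeps the full training fold
        raw_cal, y_cal = _cross_predicted_scores(config, Xtr[feats], ytr, params, fold.seed)
        mapper = calibrate(raw_cal, y_cal)
        scores = np.clip(mapper(raw_te), 0.0, 1.0)
    else:
        scores = np.clip(raw_te, 0.0, 1.0)

    metrics = evaluate(scores, yte.to_numpy(), threshold=config.threshold)
    return CvFoldResult(
        index=fold.index,
        selected_features=feats,
        params=params,
        test_scores=pd.Series(scores, index=te_ids),
        metrics=metrics,
        model=model,
        preprocessing={
            "missing_kept": list(keep),
            "impute": imp_params,
            "zscore": z_params,
        },
    )


@dataclass
class FinalModel:
    """Whole-dataset model: preprocessed design matrix, selected features,
    fitted classifier.  `score` accepts a frame in preprocessed feature
    space (any superset of the selected columns)."""

    model: object
    features: list[str]
    X: pd.DataFrame  # imputed + z-scored full design matrix
    y: pd.Series
    params: dict

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return _raw_scores(self.model, X[self.features].to_numpy())


def fit_final_model(table, config: PipelineConfig, n_features: int = 8) -> FinalModel:
    """Fit one model on the entire dataset for explainability work.

    Whole-cohort preprocessing (missingness filter, kNN imputation,
    z-scoring), mRMR selection of exactly `n_features` features, and a
    random-search-tuned classifier refit on everything.
    """
    X, y = table.data, table.labels
    frac = X.isna().mean(axis=0)
    X = X[frac.index[frac <= config.missing_threshold]]
    X, _, _ = knn_impute(X, X.iloc[:0], k=config.impute_k)
    X, _, _ = zscore(X, X.iloc[:0])
    feats = mrmr_select(X, y, min(n_features, X.shape[1]))
    cfg = PipelineConfig(
        **{**vars(config), "mrmr_k_grid": (len(feats),)}
    )
    model, params, feats = tune_and_train(cfg, X, y, feats, seed=config.seed)
    return FinalModel(model=model, features=feats, X=X, y=y, params=params)


def run_experiment(table, config: PipelineConfig) -> tuple[CvSummary, list[CvFoldResult]]:
    """Full Monte Carlo cross-validation of one classifier family.

    Every transform is fitted on the training partition of each fold; the
    run fails if more than 10% of folds are unusable (e.g. single-class
    test sets).
    """
    folds = make_folds(
        table.labels, n_folds=config.n_folds, train_frac=config.train_frac, seed=config.seed
    )
    results: list[CvFoldResult] = []
    failures = 0
    for fold in folds:
        try:
            results.append(_run_fold(table, fold, config))
        except ValueError as exc:
            failures += 1
            log.warning("fold %d failed: %s", fold.index, exc)
    if failures > 0.10 * config.n_folds:
        raise RuntimeError(f"{failures}/{config.n_folds} folds failed; run aborted")

    per_fold = pd.DataFrame([r.metrics for r in results], index=[r.index for r in results])
    mean = {m: float(np.nanmean(per_fold[m])) for m in METRICS}
    ci = {
        m: tuple(np.nanpercentile(per_fold[m], [2.5, 97.5]).tolist()) for m in METRICS
    }
    counts: dict[str, int] = {}
    for r in results:
        for f in r.selected_features:
            counts[f] = counts.get(f, 0) + 1
    freq = (pd.Series(counts, dtype=float) / len(results)).sort_values(ascending=False)
    summary = CvSummary(
        metrics_mean=mean,
        metrics_ci=ci,
        selection_frequency=freq,
        n_folds_run=len(results),
        n_folds_failed=failures,
        per_fold=per_fold,
    )
    return summary, results
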