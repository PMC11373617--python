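"""Monte Carlo CV engine: folds, imputation, scaling, mRMR, tuning,
calibration, metrics, and the leakage contract."""

import numpy as np
import pandas as pd
import pytest

import psma_multiomics as pm
from psma_multiomics.cv import (
    PipelineConfig,
    calibrate,
    evaluate,
    knn_impute,
    make_folds,
    mrmr_select,
    tune_and_train,
    zscore,
)


def _labels(n_low=28, n_high=37):
    idx = [f"P{i:03d}" for i in range(n_low + n_high)]
    return pd.Series([0] * n_low + [1] * n_high, index=idx)


class TestMakeFolds:
    def test_stratified_sizes_at_study_scale(self):
        folds = make_folds(_labels(), n_folds=100, train_frac=0.70, seed=1)
        assert len(folds) == 100
        y = _labels()
        for f in folds[:10]:
            train = y.loc[list(f.train_ids)]
            assert len(train) == 46
            assert (train == 0).sum() == 20 and (train == 1).sum() == 26
            assert set(f.train_ids).isdisjoint(f.test_ids)
            assert set(f.train_ids) | set(f.test_ids) == set(y.index)

    def test_same_seed_identical_folds(self):
        a = make_folds(_labels(), 20, seed=9)
        b = make_folds(_labels(), 20, seed=9)
        assert a == b

    def test_folds_are_independent_draws(self):
        folds = make_folds(_labels(), 50, seed=2)
        assert len({f.train_ids for f in folds}) > 45  # essentially all distinct

    def test_degenerate_class_errors(self):
        with pytest.raises(ValueError):
            make_folds(pd.Series([0, 1, 1, 1], index=list("abcd")), 5, seed=0)


class TestKnnImpute:
    def test_complete_data_unchanged(self, rng):
        tr = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        te = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        out_tr, out_te, _ = knn_impute(tr, te)
        pd.testing.assert_frame_equal(out_tr, tr, check_exact=False, atol=1e-12)
        pd.testing.assert_frame_equal(out_te, te, check_exact=False, atol=1e-12)

    def test_k1_equals_nearest_neighbor_oracle(self, rng):
        tr = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        te = tr.copy().iloc[:6].reset_index(drop=True) + rng.normal(0, 0.01, size=(6, 5))
        te.iloc[0, 2] = np.nan
        out_tr, out_te, params = knn_impute(tr, te, k=1)
        # oracle: scale with train min-max, find nearest train row on
        # observed dims, copy its value
        lo, span = params["minmax_lo"], params["minmax_span"]
        tr_s, te_s = (tr - lo) / span, (te - lo) / span
        obs = [c for c in "abde"]
        d = ((tr_s[obs] - te_s.loc[0, obs]) ** 2).sum(axis=1)
        assert out_te.loc[0, "c"] == pytest.approx(tr.loc[d.idxmin(), "c"])

    def test_constant_column_holes_filled_with_constant(self, rng):
        tr = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        tr["c"] = 7.0
        tr.loc[3:5, "c"] = np.nan
        out_tr, _, _ = knn_impute(tr, tr.iloc[:0])
        assert (out_tr["c"] == 7.0).all()

    def test_observed_values_untouched(self, rng):
        tr = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        holes = tr.mask(rng.random(tr.shape) < 0.2)
        out_tr, _, _ = knn_impute(holes, holes.iloc[:0])
        observed = ~holes.isna()
        assert np.allclose(out_tr.values[observed.values], holes.values[observed.values])

    def test_fully_missing_train_column_errors(self, rng):
        tr = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        tr["b"] = np.nan
        with pytest.raises(ValueError):
            knn_impute(tr, tr.iloc[:0])


class TestZscore:
    def test_closed_form_population_sd(self):
        tr = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        te = pd.DataFrame({"x": [2.0]})
        out_tr, out_te, params = zscore(tr, te)
        assert out_tr["x"].tolist() == pytest.approx([-1.224744871, 0.0, 1.224744871])
        assert out_te["x"].iloc[0] == 0.0  # test value at the train mean

    def test_train_standardized_and_constant_column_zeroed(self, rng):
        tr = pd.DataFrame(rng.normal(3, 2, size=(30, 4)), columns=list("abcd"))
        tr["d"] = 5.0
        out_tr, _, _ = zscore(tr, tr.iloc[:0])
        assert np.allclose(out_tr[list("abc")].mean(), 0, atol=1e-12)
        assert np.allclose(out_tr[list("abc")].std(ddof=0), 1, atol=1e-12)
        assert (out_tr["d"] == 0).all()


def _oracle_mrmr(X, y, k, n_bins):
    """Exhaustive greedy mRMR: every relevance/redundancy term evaluated
    directly from contingency tables."""
    def codes(v, bins):
        qs = np.linspace(0, 1, bins + 1)[1:-1]
        edges = np.unique(np.quantile(v, qs))
        return np.searchsorted(edges, v, side="right")

    def mi(a, b):
        ka, kb = a.max() + 1, b.max() + 1
        j = np.zeros((ka, kb))
        for x_, y_ in zip(a, b):
            j[x_, y_] += 1
        j /= j.sum()
        pa, pb = j.sum(1, keepdims=True), j.sum(0, keepdims=True)
        nz = j > 0
        return (j[nz] * np.log(j[nz] / (pa @ pb)[nz])).sum()

    cols = list(X.columns)
    C = {c: codes(X[c].to_numpy(), n_bins) for c in cols}
    yc = y.to_numpy().astype(int)
    chosen = []
    while len(chosen) < k:
        best, best_score = None, -np.inf
        for c in cols:
            if c in chosen:
                continue
            rel = mi(C[c], yc)
            red = np.mean([mi(C[c], C[s]) for s in chosen]) if chosen else 0.0
            if rel - red > best_score + 1e-15:
                best, best_score = c, rel - red
        chosen.append(best)
    return chosen


class TestMrmr:
    def test_k1_is_max_relevance_feature(self, toy_table):
        sel = mrmr_select(toy_table.data, toy_table.labels, 1)
        assert sel == ["signal"]

    @pytest.mark.parametrize("p, k", [(6, 3), (10, 5)])
    def test_equals_exhaustive_greedy_oracle(self, rng, p, k):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)])
        y = pd.Series(rng.integers(0, 2, size=n), index=X.index)
        n_bins = max(2, min(5, n // 5))
        assert mrmr_select(X, y, k) == _oracle_mrmr(X, y, k, n_bins)

    def test_planted_feature_ranked_first_in_replicates(self):
        hits = 0
        reps = 20
        for s in range(reps):
            r = np.random.default_rng(s)
            n = 200
            y = pd.Series(r.integers(0, 2, n))
            X = pd.DataFrame(r.normal(size=(n, 20)), columns=[f"n{j}" for j in range(20)])
            X["planted"] = r.normal(size=n) + 2.0 * y
            assert X.shape[1] == 21
            sel = mrmr_select(X, y, 1)
            hits += sel[0] == "planted"
        assert hits >= 19  # >= 95% of replicate draws

    def test_k_exceeding_candidates_errors(self, toy_table):
        with pytest.raises(ValueError):
            mrmr_select(toy_table.data, toy_table.labels, 99)


class TestTuneAndTrain:
    def test_budget_one_returns_single_sampled_config(self, toy_table):
        cfg = PipelineConfig(algorithm="lgr", search_budget=1, seed=0)
        m1, p1, f1 = tune_and_train(cfg, toy_table.data, toy_table.labels,
                                    list(toy_table.data.columns), seed=3)
        m2, p2, f2 = tune_and_train(cfg, toy_table.data, toy_table.labels,
                                    list(toy_table.data.columns), seed=3)
        assert p1 == p2 and f1 == f2

    @pytest.mark.parametrize("algo", ["knn", "rf", "xgb", "svm", "lgr"])
    def test_separable_data_training_auc_one(self, algo):
        r = np.random.default_rng(0)
        n = 40
        y = pd.Series([0] * 20 + [1] * 20, index=[f"P{i}" for i in range(n)])
        X = pd.DataFrame(
            {"f1": np.concatenate([r.normal(-4, 0.3, 20), r.normal(4, 0.3, 20)]),
             "f2": np.concatenate([r.normal(4, 0.3, 20), r.normal(-4, 0.3, 20)])},
            index=y.index,
        )
        cfg = PipelineConfig(algorithm=algo, search_budget=2, mrmr_k_grid=(2,), seed=1)
        model, params, feats = tune_and_train(cfg, X, y, ["f1", "f2"], seed=1)
        from psma_multiomics.cv import _raw_scores

        auc = evaluate(_raw_scores(model, X[feats].to_numpy()), y.to_numpy())["AUC"]
        assert auc == 1.0

    def test_degenerate_labels_error(self, toy_table):
        cfg = PipelineConfig(algorithm="lgr", search_budget=1)
        with pytest.raises(ValueError):
            tune_and_train(cfg, toy_table.data, toy_table.labels * 0,
                           list(toy_table.data.columns), seed=0)


class TestCalibrate:
    def test_well_calibrated_scores_map_near_identity(self, rng):
        p = rng.uniform(0.05, 0.95, size=4000)
        y = (rng.random(4000) < p).astype(int)
        mapper = calibrate(p, y)
        grid = np.linspace(0.1, 0.9, 9)
        assert np.allclose(mapper(grid), grid, atol=0.05)

    def test_auc_preserved_by_calibration(self, rng):
        raw = rng.random(300)
        y = (rng.random(300) < raw).astype(int)
        mapper = calibrate(raw, y)
        assert evaluate(mapper(raw), y)["AUC"] == pytest.approx(
            evaluate(raw, y)["AUC"], abs=1e-12
        )

    def test_anticalibrated_scores_stay_below_half(self, rng):
        p = rng.uniform(0, 1, size=2000)
        y = (rng.random(2000) < p).astype(int)
        flipped = 1 - p
        mapper = calibrate(flipped, y)
        assert evaluate(mapper(flipped), y)["AUC"] < 0.5

    def test_constant_scores_identity_with_warning(self):
        mapper = calibrate(np.full(10, 0.4), np.arange(10) % 2)
        assert np.allclose(mapper(np.array([0.2, 0.8])), [0.2, 0.8])


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert all(v == 1.0 for v in m.values())

    def test_confusion_arithmetic(self):
        # TP=3, FN=1, TN=6, FP=2
        y = np.array([1] * 4 + [0] * 8)
        s = np.array([0.9, 0.8, 0.7, 0.2] + [0.1] * 6 + [0.6, 0.6])
        m = evaluate(s, y, threshold=0.5)
        assert m["SNS"] == pytest.approx(0.75)
        assert m["SPC"] == pytest.approx(0.75)
        assert m["PPV"] == pytest.approx(0.6)
        assert m["NPV"] == pytest.approx(6 / 7)
        assert m["ACC"] == pytest.approx(0.75)

    def test_random_scores_auc_near_half(self, rng):
        n = 10_000
        y = rng.integers(0, 2, n)
        m = evaluate(rng.random(n), y)
        assert abs(m["AUC"] - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestRunExperiment:
    def test_bxisup_alone_reproduces_single_feature_pathway(self, default_table):
        """Using the biopsy grade as the only feature gives a meaningful
        comparator AUC well above chance (the grade is informative by
        construction)."""
        sub = pm.subset_categories(default_table, ["bxISUP"])
        cfg = PipelineConfig(algorithm="lgr", n_folds=20, search_budget=1,
                             mrmr_k_grid=(1,), seed=4)
        summ, res = pm.run_experiment(sub, cfg)
        assert summ.metrics_mean["AUC"] > 0.65
        assert all(r.selected_features == ["bxISUP"] for r in res)

    def test_leakage_sentinel_test_perturbation_changes_no_fit_params(self, default_table):
        """Perturbing a test-row value must leave every fold's fitted
        imputation and normalization parameters bit-identical."""
        cfg = PipelineConfig(algorithm="lgr", n_folds=3, search_budget=1,
                             mrmr_k_grid=(4,), seed=11)
        _, res1 = pm.run_experiment(default_table, cfg)
        perturbed = pm.OmicsFeatureTable(
            default_table.data.copy(), dict(default_table.categories), default_table.labels
        )
        test_pid = res1[0].test_scores.index[0]
        col = "rad::glcm::JointEnergy"
        perturbed.data.loc[test_pid, col] = 1e9  # extreme outlier in a test row
        _, res2 = pm.run_experiment(perturbed, cfg)
        f1, f2 = res1[0], res2[0]
        pd.testing.assert_series_equal(
            f1.preprocessing["zscore"]["mean"], f2.preprocessing["zscore"]["mean"]
        )
        pd.testing.assert_series_equal(
            f1.preprocessing["zscore"]["sd"], f2.preprocessing["zscore"]["sd"]
        )
        pd.testing.assert_series_equal(
            f1.preprocessing["impute"]["minmax_lo"], f2.preprocessing["impute"]["minmax_lo"]
        )
        assert f1.selected_features == f2.selected_features

    def test_summary_aggregation_bounds(self, toy_table):
        cfg = PipelineConfig(algorithm="lgr", n_folds=12, search_budget=1,
                             mrmr_k_grid=(3,), seed=2)
        summ, res = pm.run_experiment(toy_table, cfg)
        for m in ("AUC", "ACC", "SNS", "SPC"):
            lo, hi = summ.metrics_ci[m]
            assert lo <= summ.metrics_mean[m] <= hi
        # removing one fold moves the mean by at most max deviation / (n-1)
        aucs = summ.per_fold["AUC"].to_numpy()
        for i in range(len(aucs)):
            rest = np.delete(aucs, i)
            assert abs(rest.mean() - aucs.mean()) <= (
                np.abs(aucs - aucs.mean()).max() / (len(aucs) - 1) + 1e-12
            )

    def test_scores_in_unit_interval(self, toy_table):
        cfg = PipelineConfig(algorithm="rf", n_folds=5, search_budget=1,
                             mrmr_k_grid=(3,), seed=8)
        _, res = pm.run_experiment(toy_table, cfg)
        for r in res:
            assert ((r.test_scores >= 0) & (r.test_scores <= 1)).all()
            assert set(r.selected_features) <= set(toy_table.data.columns)
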