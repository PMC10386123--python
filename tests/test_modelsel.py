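"""Selection and nested-LOSO tests, including frozen reference metric rows.

``REFERENCE_ROWS`` holds the published per-subject confusion counts and the
metric values printed alongside them; ``compute_metrics`` must reproduce every
row to two decimals, which pins down the macro-averaging convention.
"""

import numpy as np
import pandas as pd
import pytest

from cogload import modelsel

from cogload.modelsel import (HyperGrid, SubjectEvaluation, anova_filter,
                              compute_metrics, nested_loso, rfecv_select,
                              summarise)

# (tp, fn, fp, tn, precision, f1, recall, accuracy)
REFERENCE_ROWS = [
    (35, 22, 1, 46, 82.43, 77.63, 79.64, 77.88),
    (61, 8, 0, 48, 92.86, 93.08, 94.20, 93.16),
    (39, 12, 6, 41, 82.01, 81.62, 81.85, 81.63),
    (38, 8, 0, 47, 92.73, 91.32, 91.30, 91.40),
    (31, 0, 20, 27, 80.39, 74.29, 78.72, 74.36),
    (42, 16, 2, 45, 84.61, 82.84, 84.08, 82.86),
    (31, 1, 4, 49, 93.29, 93.84, 94.66, 94.12),
    (47, 1, 25, 22, 80.46, 70.60, 72.36, 72.63),
    (44, 2, 3, 44, 94.63, 94.62, 94.63, 94.62),
    (37, 7, 0, 48, 93.64, 92.28, 92.05, 92.39),
    (31, 3, 0, 47, 97.00, 96.15, 95.59, 96.30),
    (37, 3, 23, 24, 75.28, 69.43, 71.78, 70.11),
]
REFERENCE_MEANS = {"precision": 87.44, "f1": 84.81, "recall": 85.90,
                   "accuracy": 85.12}


def _table(X, y, subjects, features=None):
    features = features or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=features)
    df["load_class"] = np.where(y == 1, "HL", "LL")
    df["subject_id"] = subjects
    df["session_type"] = df["load_class"]
    df["task"] = "t"
    df["start_s"] = 0.0
    return df


def _brute_force_f(x, y):
    """One-way ANOVA F statistic computed from first principles."""
    groups = [x[y == g] for g in np.unique(y)]
    grand = np.mean(np.concatenate(groups))
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestComputeMetrics:
    @pytest.mark.parametrize("tp,fn,fp,tn,p,f1,r,a", REFERENCE_ROWS)
    def test_reference_rows_reproduced_to_2dp(self, tp, fn, fp, tn, p, f1, r, a):
        precision, recall, f1_, accuracy = compute_metrics(tp, fn, fp, tn)
        assert round(precision, 2) == p
        assert round(recall, 2) == r
        assert round(f1_, 2) == f1
        assert round(accuracy, 2) == a

    def test_perfect_classifier_scores_100(self):
        assert compute_metrics(7, 0, 0, 11) == (100.0, 100.0, 100.0, 100.0)

    def test_undefined_ratio_warns_and_uses_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            precision, recall, f1, accuracy = compute_metrics(0, 5, 0, 5)
        assert precision == pytest.approx(25.0)   # HL precision 0/0 -> 0
        assert recall == pytest.approx(50.0)
        assert accuracy == pytest.approx(50.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 5)

    def test_matches_brute_force_confusion_evaluation(self, rng):
        y = rng.integers(0, 2, 200)
        yhat = rng.integers(0, 2, 200)
        tp = int(np.sum((y == 1) & (yhat == 1)))
        fn = int(np.sum((y == 1) & (yhat == 0)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        tn = int(np.sum((y == 0) & (yhat == 0)))
        from sklearn.metrics import (precision_score, recall_score, f1_score,
                                     accuracy_score)
        precision, recall, f1, accuracy = compute_metrics(tp, fn, fp, tn)
        assert precision == pytest.approx(
            100 * precision_score(y, yhat, average="macro", zero_division=0))
        assert recall == pytest.approx(
            100 * recall_score(y, yhat, average="macro", zero_division=0))
        assert f1 == pytest.approx(
            100 * f1_score(y, yhat, average="macro", zero_division=0))
        assert accuracy == pytest.approx(100 * accuracy_score(y, yhat))


class TestSummarise:
    def _evals(self):
        out = []
        for i, (tp, fn, fp, tn, *_rest) in enumerate(REFERENCE_ROWS):
            p, r, f1, a = compute_metrics(tp, fn, fp, tn)
            out.append(SubjectEvaluation(
                subject_id=str(i + 1), tp=tp, fn=fn, fp=fp, tn=tn,
                precision=p, recall=r, f1=f1, accuracy=a))
        return out

    def test_reference_means(self):
        s = summarise(self._evals())
        assert round(s["accuracy"], 2) == REFERENCE_MEANS["accuracy"]
        assert round(s["precision"], 2) == REFERENCE_MEANS["precision"]
        assert round(s["f1"], 2) == REFERENCE_MEANS["f1"]
        assert abs(s["recall"] - REFERENCE_MEANS["recall"]) < 0.011

    def test_single_subject_mean_is_that_subject(self):
        e = self._evals()[0]
        s = summarise([e])
        assert s["accuracy"] == e.accuracy

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarise([])


class TestHyperGrid:
    def test_svm_grid_matches_published_values(self):
        grid = HyperGrid()
        assert grid.svm["C"] == [0.1, 1, 10, 100]
        assert grid.svm["gamma"] == [1, 0.1, 0.01, 0.001]
        assert grid.svm["kernel"] == ["linear"]
        assert len(grid.points("svm")) == 16
        assert grid.points("svm")[0] == {"C": 0.1, "gamma": 1, "kernel": "linear"}

    def test_gnb_grid_spans_1_to_1e_minus_9(self):
        vs = HyperGrid().gnb["var_smoothing"]
        assert vs[0] == pytest.approx(1.0)
        assert vs[-1] == pytest.approx(1e-9)

    def test_rf_literal_auto_translated(self):
        est = modelsel.build_estimator("rf", {"max_features": "auto",
                                              "n_estimators": 5})
        assert est.max_features == "sqrt"


class TestAnovaFilter:
    def test_scores_match_brute_force(self, rng):
        X = rng.normal(size=(60, 6))
        y = rng.integers(0, 2, 60)
        X[:, 2] += 2.0 * y
        table = _table(X, y, [f"S{i % 4}" for i in range(60)])
        res = anova_filter(table, k=3)
        for i in range(6):
            assert res.anova_scores[f"f{i}"] == pytest.approx(
                _brute_force_f(X[:, i], y), rel=1e-9)

    def test_label_like_feature_ranked_first(self, rng):
        y = rng.integers(0, 2, 80)
        X = rng.normal(size=(80, 5))
        X[:, 3] = y + rng.normal(0, 1e-3, 80)
        table = _table(X, y, ["S0"] * 80)
        res = anova_filter(table, k=1)
        assert res.kept40 == ["f3"]

    def test_k_equal_to_total_keeps_all(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, 40)
        table = _table(X, y, ["S0"] * 40)
        assert set(anova_filter(table, k=4).kept40) == {"f0", "f1", "f2", "f3"}

    def test_constant_feature_ranked_last_with_warning(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 1] = 5.0
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        X[:, 0] += y
        table = _table(X, y, ["S0"] * 40)
        with pytest.warns(UserWarning, match="undefined F"):
            res = anova_filter(table, k=2)
        assert "f1" not in res.kept40

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        table = _table(X, np.ones(20, int), ["S0"] * 20)
        with pytest.raises(ValueError):
            anova_filter(table)


class TestRfecv:
    def _informative_table(self, seed=0, n=240):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 40))
        X[:, 0] += 3.0 * y
        X[:, 1] -= 3.0 * y
        subjects = [f"S{i % 12}" for i in range(n)]
        return _table(X, y, subjects), y

    def test_informative_pair_recovered(self):
        table, _ = self._informative_table()
        sel = anova_filter(table, k=40)
        res = rfecv_select(table, sel, seed=0, n_estimators=30)
        assert {"f0", "f1"} <= set(res.selected)
        assert len(res.selected) <= 4
        assert [n for n, _ in res.rfecv_curve] == list(range(1, 41))

    def test_deterministic_given_seed(self):
        table, _ = self._informative_table(seed=3)
        sel = anova_filter(table, k=40)
        r1 = rfecv_select(table, sel, seed=5, n_estimators=20)
        r2 = rfecv_select(table, sel, seed=5, n_estimators=20)
        assert r1.selected == r2.selected
        assert r1.rfecv_curve == r2.rfecv_curve

    def test_all_noise_curve_is_flat_near_chance(self, rng):
        n = 240
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 10))
        table = _table(X, y, [f"S{i % 12}" for i in range(n)])
        sel = anova_filter(table, k=10)
        res = rfecv_select(table, sel, seed=1, n_estimators=20)
        scores = [s for _, s in res.rfecv_curve]
        assert 0.3 < np.mean(scores) < 0.65


class TestNestedLoso:
    def _separable_table(self, n_subjects=4, per=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for _ in range(per):
                y = rng.integers(0, 2)
                rows.append((y + rng.normal(0, 0.05), rng.normal(), y,
                             f"S{s}"))
        X = np.array([[r[0], r[1]] for r in rows])
        y = np.array([r[2] for r in rows])
        subjects = [r[3] for r in rows]
        return _table(X, y, subjects)

    def test_perfectly_separable_gives_100pc_everywhere(self):
        table = self._separable_table()
        evals, prov = nested_loso(table, ["f0", "f1"], model_family="svm",
                                  seed=0, reproduction_mode=True)
        assert all(e.accuracy == 100.0 for e in evals)

    def test_no_leakage_in_provenance(self):
        table = self._separable_table()
        evals, prov = nested_loso(table, ["f0", "f1"], model_family="svm",
                                  seed=0, reproduction_mode=True)
        assert prov, "provenance must record every fit"
        for test_subject, train_subjects in prov:
            assert test_subject not in train_subjects

    def test_metrics_consistent_with_compute_metrics(self):
        table = self._separable_table(seed=2)
        evals, _ = nested_loso(table, ["f0", "f1"], model_family="gnb", seed=0,
                               grid=HyperGrid(gnb={"var_smoothing": [1e-9]}),
                               reproduction_mode=True)
        for e in evals:
            p, r, f1, a = compute_metrics(e.tp, e.fn, e.fp, e.tn)
            assert (e.precision, e.recall, e.f1, e.accuracy) == (p, r, f1, a)

    def test_grid_determinism(self):
        table = self._separable_table(seed=4)
        e1, _ = nested_loso(table, ["f0", "f1"], model_family="svm", seed=7,
                            reproduction_mode=True)
        e2, _ = nested_loso(table, ["f0", "f1"], model_family="svm", seed=7,
                            reproduction_mode=True)
        assert [e.best_params for e in e1] == [e.best_params for e in e2]

    def test_fewer_than_3_subjects_rejected(self):
        table = self._separable_table(n_subjects=2)
        with pytest.raises(ValueError):
            nested_loso(table, ["f0", "f1"], reproduction_mode=True)

    def test_reselect_incompatible_with_reproduction_mode(self):
        table = self._separable_table()
        with pytest.raises(ValueError):
            nested_loso(table, ["f0"], reproduction_mode=True,
                        reselect=lambda t: ["f0"])
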