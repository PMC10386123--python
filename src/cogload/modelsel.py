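"""Hybrid feature selection and nested leave-one-subject-out evaluation.

Selection is a two-stage hybrid: a one-way-ANOVA filter keeps the 40 features
with the largest F-statistic against the HL/LL label, then recursive feature
elimination with cross-validation (random-forest importance, macro-F1
scoring) picks the cardinality with the best mean score.

Classification is a nested leave-one-subject-out (LOSO) protocol: for each
held-out subject, hyperparameters are chosen by an inner LOSO over the
remaining subjects scored by mean macro F1, the winning configuration is
refit on all non-held-out data (scaler fit on training data only), and the
held-out subject yields one confusion matrix.  HL is the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV, f_classif
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, METADATA_COLUMNS

log = logging.getLogger(__name__)

POSITIVE = "HL"
NEGATIVE = "LL"


# ---------------------------------------------------------------------------
# Hyperparameter grids
# ---------------------------------------------------------------------------

@dataclass
class HyperGrid:
    """Published grid-search value lists per model family.

    ``max_features`` keeps the literal value ``'auto'`` for fidelity; it is
    translated to ``'sqrt'`` (its meaning for classifiers) when estimators are
    built, since newer scikit-learn releases removed the alias.
    """

    rf: dict = field(default_factory=lambda: {
        "bootstrap": [True, False],
        "max_depth": [5, 15, 26, 36, 47, 57, 68, 78, 89, 99, 110],
        "max_features": ["auto", "sqrt"],
        "min_samples_split": [2, 5, 10, 15, 20, 25],
        "min_samples_leaf": [1, 2, 4, 6, 8, 10, 12],
        "n_estimators": [5, 12, 19, 26, 33, 41, 48, 55, 62, 70],
    })
    svm: dict = field(default_factory=lambda: {
        "C": [0.1, 1, 10, 100],
        "gamma": [1, 0.1, 0.01, 0.001],  # inert for the linear kernel; kept for fidelity
        "kernel": ["linear"],
    })
    gnb: dict = field(default_factory=lambda: {
        # "1 to 1e-9, step 0.099" read as a log10 grid with exponent step 0.099
        "var_smoothing": list(np.logspace(0, -9, 92)),
    })

    def points(self, family):
        """Grid points in listed order (first-listed wins ties)."""
        grid = getattr(self, family)
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def build_estimator(family, params, seed=0):
    params = dict(params)
    if family == "rf":
        if params.get("max_features") == "auto":
            params["max_features"] = "sqrt"
        return RandomForestClassifier(random_state=seed, **params)
    if family == "svm":
        # bounded iterations: libsvm can fail to terminate on inseparable
        # data with large C (e.g. permutation controls)
        params.setdefault("max_iter", 50_000)
        return SVC(**params)
    if family == "gnb":
        return GaussianNB(**params)
    raise ValueError(f"unknown model family {family!r}")


def build_scaler(kind="zscore"):
    if kind == "zscore":
        return StandardScaler()
    if kind == "minmax":
        return MinMaxScaler()
    raise ValueError(f"unknown scaler {kind!r}")


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    anova_scores: dict            # feature -> F statistic
    kept40: list
    rfecv_curve: list = field(default_factory=list)   # [(n_features, mean F1)]
    selected: list = field(default_factory=list)
    selector_seed: int = 0


def _feature_matrix(table, features=None):
    features = list(features or FEATURE_NAMES)
    X = table[features].to_numpy(dtype=float)
    y = (table["load_class"] == POSITIVE).astype(int).to_numpy()
    groups = table["subject_id"].to_numpy()
    return X, y, groups, features


def anova_filter(table, k=40):
    """Rank features by one-way F-statistic against the class label.

    Constant features have an undefined F and are ranked last with a warning.
    """
    feats = [c for c in table.columns if c not in METADATA_COLUMNS]
    X, y, _, feats = _feature_matrix(table, feats)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for the ANOVA filter")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X, y)
    scores = {}
    for name, f in zip(feats, F):
        if not np.isfinite(f):
            warnings.warn(f"feature {name!r} has undefined F (constant?); ranked last")
            f = -np.inf
        scores[name] = float(f)
    order = sorted(feats, key=lambda n: scores[n], reverse=True)
    kept = order[:min(k, len(feats))]
    return SelectionResult(anova_scores=scores, kept40=kept)


def rfecv_select(table, selection: SelectionResult, folds=12, seed=0,
                 n_estimators=100, min_subjects_for_groups=12):
    """Recursive feature elimination over the ANOVA-kept features.

    Scoring is cross-validated macro F1 with one feature removed per step;
    folds are grouped by subject when enough subjects are available, else
    stratified.  The cardinality with the best mean score wins (smallest on
    ties).
    """
    X, y, groups, feats = _feature_matrix(table, selection.kept40)
    n_subjects = len(np.unique(groups))
    if n_subjects >= min_subjects_for_groups and n_subjects >= folds:
        cv = list(GroupKFold(n_splits=folds).split(X, y, groups))
    else:
        cv = list(StratifiedKFold(n_splits=min(folds, np.bincount(y).min()),
                                  shuffle=True, random_state=seed).split(X, y))
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rfecv = RFECV(est, step=1, cv=cv, scoring="f1_macro",
                  min_features_to_select=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rfecv.fit(X, y)
    curve = list(zip(rfecv.cv_results_["n_features"].tolist(),
                     rfecv.cv_results_["mean_test_score"].tolist()))
    selected = [f for f, keep in zip(feats, rfecv.support_) if keep]
    return SelectionResult(
        anova_scores=selection.anova_scores, kept40=selection.kept40,
        rfecv_curve=curve, selected=selected, selector_seed=seed)


def select_features(table, k=40, folds=12, seed=0, n_estimators=100):
    """ANOVA filter to ``k`` then RFECV to the winning cardinality."""
    return rfecv_select(table, anova_filter(table, k=k), folds=folds, seed=seed,
                        n_estimators=n_estimators)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class SubjectEvaluation:
    subject_id: str
    tp: int
    fn: int
    fp: int
    tn: int
    precision: float      # macro-averaged, %
    recall: float
    f1: float
    accuracy: float
    best_params: dict = field(default_factory=dict)
    inner_f1: float = np.nan


def _safe_ratio(num, den, label):
    if den == 0:
        warnings.warn(f"{label} undefined (0/0); set to 0")
        return 0.0
    return num / den


def compute_metrics(tp, fn, fp, tn):
    """Macro-averaged precision/recall/F1 and accuracy, in percent.

    Per-class values are computed for the positive (HL) and negative (LL)
    classes and averaged with equal weight; accuracy is the fraction of
    correct windows.  Undefined per-class ratios (0/0) contribute 0.
    """
    if min(tp, fn, fp, tn) < 0 or tp + fn + fp + tn == 0:
        raise ValueError("counts must be nonnegative with a positive sum")
    p_pos = _safe_ratio(tp, tp + fp, "positive precision")
    p_neg = _safe_ratio(tn, tn + fn, "negative precision")
    r_pos = _safe_ratio(tp, tp + fn, "positive recall")
    r_neg = _safe_ratio(tn, tn + fp, "negative recall")
    f_pos = _safe_ratio(2 * p_pos * r_pos, p_pos + r_pos, "positive F1")
    f_neg = _safe_ratio(2 * p_neg * r_neg, p_neg + r_neg, "negative F1")
    precision = 100.0 * (p_pos + p_neg) / 2
    recall = 100.0 * (r_pos + r_neg) / 2
    f1 = 100.0 * (f_pos + f_neg) / 2
    accuracy = 100.0 * (tp + tn) / (tp + fn + fp + tn)
    return precision, recall, f1, accuracy


def summarise(evals):
    """Unweighted mean of the per-subject metrics."""
    if not evals:
        raise ValueError("no evaluations to summarise")
    return {
        "accuracy": float(np.mean([e.accuracy for e in evals])),
        "precision": float(np.mean([e.precision for e in evals])),
        "recall": float(np.mean([e.recall for e in evals])),
        "f1": float(np.mean([e.f1 for e in evals])),
        "n_subjects": len(evals),
    }


# ---------------------------------------------------------------------------
# Nested LOSO
# ---------------------------------------------------------------------------

def _fit_and_score(family, params, scaler_kind, seed, X_tr, y_tr, X_te, y_te,
                   provenance=None, test_subject=None, train_groups=None):
    if provenance is not None:
        # no-leakage assertion: the held-out subject's rows never reach a fit
        assert test_subject is not None
        assert not np.any(train_groups == test_subject), "leakage detected"
        provenance.append((test_subject, sorted(set(train_groups.tolist()))))
    pipe = Pipeline([
        ("scale", build_scaler(scaler_kind)),
        ("clf", build_estimator(family, params, seed=seed)),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X_tr, y_tr)
    y_hat = pipe.predict(X_te)
    return y_hat, f1_score(y_te, y_hat, average="macro", zero_division=0)


def nested_loso(table, features, model_family="svm", grid: HyperGrid = None,
                scaler="zscore", seed=0, reproduction_mode=False,
                reselect=None):
    """Nested leave-one-subject-out evaluation.

    Parameters
    ----------
    table : feature table (windows x features + metadata columns).
    features : selected feature names used in *reproduction mode* (selection
        performed once beforehand).  In leakage-safe mode pass
        ``reselect=callable(train_table) -> feature names`` and ``features``
        is ignored per fold.
    reproduction_mode : when True, mirrors the published order of operations
        (selection before the outer loop); the default keeps whatever
        ``features``/``reselect`` combination the caller provides.

    Returns
    -------
    (evaluations, provenance) where provenance records, for every fit, the
    held-out subject and the subjects the model was fitted on.
    """
    grid = grid or HyperGrid()
    subjects = list(pd.unique(table["subject_id"]))
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for nested LOSO")
    if reselect is not None and reproduction_mode:
        raise ValueError("reselect is a leakage-safe-mode option")
    points = grid.points(model_family)
    evals, provenance = [], []
    for s in subjects:
        outer_train = table[table["subject_id"] != s]
        outer_test = table[table["subject_id"] == s]
        feats = list(features) if reselect is None else list(reselect(outer_train))
        if set(outer_test["load_class"]) != {POSITIVE, NEGATIVE}:
            warnings.warn(f"subject {s} has windows of only one class")

        inner_subjects = [v for v in subjects if v != s]
        best_point, best_score = None, -np.inf
        for point in points:
            scores = []
            for v in inner_subjects:
                tr = outer_train[outer_train["subject_id"] != v]
                va = outer_train[outer_train["subject_id"] == v]
                if va.empty or len(set(tr["load_class"])) < 2:
                    warnings.warn(f"degenerate inner fold {v}; skipped")
                    continue
                X_tr, y_tr, g_tr, _ = _feature_matrix(tr, feats)
                X_va, y_va, _, _ = _feature_matrix(va, feats)
                _, sc = _fit_and_score(
                    model_family, point, scaler, seed, X_tr, y_tr, X_va, y_va,
                    provenance=provenance, test_subject=s, train_groups=g_tr)
                scores.append(sc)
            mean_score = float(np.mean(scores)) if scores else -np.inf
            if mean_score > best_score:  # strict: first-listed point wins ties
                best_score, best_point = mean_score, point
        if best_point is None:
            warnings.warn(f"no scoreable inner fold for subject {s}; "
                          "using the first grid point")
            best_point = points[0]

        X_tr, y_tr, g_tr, _ = _feature_matrix(outer_train, feats)
        X_te, y_te, _, _ = _feature_matrix(outer_test, feats)
        y_hat, _ = _fit_and_score(
            model_family, best_point, scaler, seed, X_tr, y_tr, X_te, y_te,
            provenance=provenance, test_subject=s, train_groups=g_tr)
        tp = int(np.sum((y_te == 1) & (y_hat == 1)))
        fn = int(np.sum((y_te == 1) & (y_hat == 0)))
        fp = int(np.sum((y_te == 0) & (y_hat == 1)))
        tn = int(np.sum((y_te == 0) & (y_hat == 0)))
        precision, recall, f1, accuracy = compute_metrics(tp, fn, fp, tn)
        evals.append(SubjectEvaluation(
            subject_id=s, tp=tp, fn=fn, fp=fp, tn=tn,
            precision=precision, recall=recall, f1=f1, accuracy=accuracy,
            best_params=dict(best_point), inner_f1=best_score))
    return evals, provenance


def evaluations_frame(evals):
    """Per-subject metric table (one row per held-out subject)."""
    return pd.DataFrame([{
        "subject_id": e.subject_id, "tp": e.tp, "fn": e.fn, "fp": e.fp,
        "tn": e.tn, "precision": round(e.precision, 2), "f1": round(e.f1, 2),
        "recall": round(e.recall, 2), "accuracy": round(e.accuracy, 2),
        "best_params": str(e.best_params),
    } for e in evals])
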