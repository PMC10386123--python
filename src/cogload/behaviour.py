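"""Questionnaire scoring and normality-routed behavioural statistics.

Affect questionnaires (20 items, 1-5) are scored as two 10-item sums
(positive and negative affect, range 10-50).  Workload questionnaires carry
six 0-100 subscales; the unweighted workload is their mean, the weighted
variant uses 15 pairwise-comparison weights.

Statistical comparisons are routed by Shapiro-Wilk normality per condition:
paired two-condition designs use a paired t-test when every condition looks
normal (p > 0.05) and the Wilcoxon signed-rank test otherwise; repeated
three-condition designs use the Friedman test (with tie correction), with
the normality outcome recorded alongside the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import FOOD_ITEMS

SHAPIRO_ALPHA = 0.05


class ScoringError(ValueError):
    """Questionnaire items are missing or out of range."""


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class PanasScores:
    subject_id: str
    session_type: str
    timepoint: str
    positive: int
    negative: int

    def __post_init__(self):
        for v in (self.positive, self.negative):
            if not 10 <= v <= 50:
                raise ScoringError(f"subscale score {v} outside [10, 50]")


def score_panas(items, subject_id="unknown", session_type="HL",
                timepoint="before_load"):
    """Sum 10 positive and 10 negative items (each 1-5) into two subscales.

    ``items`` is a mapping or Series with keys ``pa_01..pa_10`` and
    ``na_01..na_10``.  Missing items raise; no imputation.
    """
    pos_keys = [f"pa_{i:02d}" for i in range(1, 11)]
    neg_keys = [f"na_{i:02d}" for i in range(1, 11)]
    vals = {}
    for k in pos_keys + neg_keys:
        if k not in items or pd.isna(items[k]):
            raise ScoringError(f"missing item {k}")
        v = int(items[k])
        if not 1 <= v <= 5:
            raise ScoringError(f"item {k}={v} outside 1-5")
        vals[k] = v
    return PanasScores(
        subject_id=subject_id, session_type=session_type, timepoint=timepoint,
        positive=sum(vals[k] for k in pos_keys),
        negative=sum(vals[k] for k in neg_keys),
    )


def score_panas_table(frame):
    """Score a wide per-row item table (as written by the generator)."""
    rows = []
    for _, r in frame.iterrows():
        s = score_panas(r, subject_id=str(r.get("subject_id", "unknown")),
                        session_type=str(r.get("session_type", "HL")),
                        timepoint=str(r.get("timepoint", "")))
        rows.append(asdict(s))
    return pd.DataFrame(rows)


@dataclass
class NasaTlxScore:
    subject_id: str
    task: str
    subscales: dict
    workload: float

    def __post_init__(self):
        lo, hi = min(self.subscales.values()), max(self.subscales.values())
        assert lo - 1e-9 <= self.workload <= hi + 1e-9


def score_nasatlx(subscales, weights=None, subject_id="unknown", task=""):
    """Workload from six 0-100 subscales.

    Unweighted (default): mean of the six.  Weighted: sum(w_i * s_i) / 15 with
    pairwise-comparison weights summing to 15.
    """
    subscales = dict(subscales)
    if len(subscales) != 6:
        raise ScoringError("expected six subscales")
    for k, v in subscales.items():
        if not 0 <= v <= 100:
            raise ScoringError(f"subscale {k}={v} outside 0-100")
    if weights is None:
        workload = float(np.mean(list(subscales.values())))
    else:
        if set(weights) != set(subscales):
            raise ScoringError("weights must cover the same six subscales")
        total = sum(weights.values())
        if total != 15:
            raise ScoringError(f"weights must sum to 15, got {total}")
        workload = float(sum(weights[k] * subscales[k] for k in subscales) / 15.0)
    return NasaTlxScore(subject_id=subject_id, task=task,
                        subscales=subscales, workload=workload)


# ---------------------------------------------------------------------------
# Routed tests
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    comparison: str
    test: str                     # paired_t | wilcoxon | friedman | posthoc_pairwise
    statistic: float
    p_value: float
    group_means: list = field(default_factory=list)
    group_sds: list = field(default_factory=list)
    direction_of_change: float = np.nan
    routing: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _shapiro_p(x):
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is treated as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def wilcoxon_paired(a, b, zero_method="wilcox", two_sided=True):
    """Wilcoxon signed-rank: zeros dropped, exact null for n <= 25 else
    normal approximation with tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    n_eff = int(np.sum(d != 0)) if zero_method == "wilcox" else len(d)
    if n_eff == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if n_eff <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method=zero_method, method=method,
                         alternative="two-sided" if two_sided else "greater")
    return float(res.statistic), float(res.pvalue)


def friedman(*conditions):
    """Tie-corrected Friedman test over repeated measures."""
    stat, p = stats.friedmanchisquare(*conditions)
    return float(stat), float(p)


def route_test(samples, design, comparison="", alpha=SHAPIRO_ALPHA):
    """Normality-routed comparison.

    ``samples`` is a list of equal-length condition arrays (complete cases).
    ``paired_2``: paired t-test when Shapiro-Wilk passes for every condition,
    otherwise Wilcoxon signed-rank.  ``repeated_3``: Friedman test (the
    Shapiro outcome is recorded in ``routing``).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError("conditions must have equal length (complete cases)")
    n = lengths.pop()
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sh = [_shapiro_p(a) for a in arrays]
    normal = all(p > alpha for p in sh)
    routing = {"shapiro_p": sh, "normal": normal}
    means = [float(np.mean(a)) for a in arrays]
    sds = [float(np.std(a, ddof=1)) for a in arrays]

    if design == "paired_2":
        if len(arrays) != 2:
            raise ValueError("paired_2 expects two conditions")
        a, b = arrays
        if normal:
            if np.ptp(a - b) == 0 and np.all(a == b):
                stat, p = 0.0, 1.0  # identical samples: no evidence of change
            else:
                t = stats.ttest_rel(a, b)
                stat, p = float(t.statistic), float(t.pvalue)
            test = "paired_t"
        else:
            stat, p = wilcoxon_paired(a, b)
            test = "wilcoxon"
        direction = means[0] / means[1] if means[1] != 0 else np.nan
    elif design == "repeated_3":
        if len(arrays) != 3:
            raise ValueError("repeated_3 expects three conditions")
        stat, p = friedman(*arrays)
        test = "friedman"
        direction = np.nan
    else:
        raise ValueError(f"unknown design {design!r}")
    return StatResult(comparison=comparison, test=test, statistic=stat,
                      p_value=p, group_means=means, group_sds=sds,
                      direction_of_change=float(direction) if np.isfinite(direction) else np.nan,
                      routing=routing)


def posthoc_pairwise(samples, labels=None, method="wilcoxon",
                     zero_method="wilcox", require_omnibus=True,
                     alpha=0.05):
    """Pairwise follow-up tests after a significant Friedman omnibus.

    The omnibus follow-up procedure is an interpretation: pairwise Wilcoxon
    signed-rank tests (uncorrected, zeros dropped) by default;
    ``method='wilcoxon_approx'`` forces the tie-corrected normal
    approximation with zeros ranked (Pratt).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) != 3:
        raise ValueError("expected three conditions")
    labels = labels or [f"cond{i}" for i in range(3)]
    if require_omnibus:
        _, p_omni = friedman(*arrays)
        if p_omni > alpha:
            warnings.warn("omnibus Friedman not significant; post-hoc anyway")
    out = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        a, b = arrays[i], arrays[j]
        warns = []
        if np.all(a == b):
            stat, p = 0.0, 1.0
            warns.append("all-zero differences")
        elif method == "wilcoxon":
            stat, p = wilcoxon_paired(a, b, zero_method=zero_method)
        elif method == "wilcoxon_approx":
            res = stats.wilcoxon(a, b, zero_method="pratt", method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        out.append(StatResult(
            comparison=f"{labels[i]} vs {labels[j]}", test="posthoc_pairwise",
            statistic=stat, p_value=p,
            group_means=[float(np.mean(a)), float(np.mean(b))],
            group_sds=[float(np.std(a, ddof=1)), float(np.std(b, ddof=1))],
            warnings=warns))
    return out


def flag_higher_negative_affect(scores):
    """Per subject: negative affect strictly peaks just after the load.

    ``scores`` is a DataFrame with columns subject_id, timepoint
    (before_load/after_load/after_eating), negative (HL session rows).
    Subjects with a missing timepoint are excluded.
    Returns ``{subject_id: bool}``.
    """
    out = {}
    for sid, grp in scores.groupby("subject_id", sort=False):
        tps = grp.set_index("timepoint")["negative"]
        if not {"before_load", "after_load", "after_eating"} <= set(tps.index):
            warnings.warn(f"subject {sid} missing a timepoint; excluded")
            continue
        out[sid] = bool(tps["after_load"] > tps["before_load"]
                        and tps["after_load"] > tps["after_eating"])
    return out


# ---------------------------------------------------------------------------
# Food consumption
# ---------------------------------------------------------------------------

@dataclass
class FoodRecord:
    subject_id: str
    session_type: str
    item: str
    grams: float
    kcal: float
    sugar_g: float

    def __post_init__(self):
        if self.grams < -1e-9:
            raise ValueError("consumed amount cannot be negative")


def food_records(frame, energy_table=None):
    """Turn a before/after weight table into consumption records.

    ``energy_table`` maps item -> (kcal per g, sugar g per g); defaults to the
    built-in snack table.  Consumed = weight_before - weight_after.
    """
    energy = energy_table or {k: (v[1], v[2]) for k, v in FOOD_ITEMS.items()}
    out = []
    for _, r in frame.iterrows():
        item = str(r["item"])
        if item not in energy:
            raise KeyError(f"no energy density for item {item!r}")
        grams = float(r["weight_before_g"]) - float(r["weight_after_g"])
        grams = max(grams, 0.0)
        kcal_per_g, sugar_per_g = energy[item]
        out.append(FoodRecord(
            subject_id=str(r["subject_id"]), session_type=str(r["session_type"]),
            item=item, grams=grams, kcal=grams * kcal_per_g,
            sugar_g=grams * sugar_per_g))
    return out


def direction_of_change(mean_hl, mean_ll, decimals=1):
    """Ratio of HL mean to LL mean, rounded (>1 means an increase under load)."""
    if mean_ll == 0:
        return np.nan
    return round(mean_hl / mean_ll, decimals)


def food_summary(records, subjects=None):
    """Per-item HL-vs-LL comparison plus sugar and total-calorie rows.

    ``subjects`` restricts the analysis subgroup (e.g. the higher-negative-
    affect flag).  Items missing a session for the subgroup are excluded with
    a warning.  Returns ``{label: StatResult}``.
    """
    df = pd.DataFrame([asdict(r) for r in records])
    if subjects is not None:
        df = df[df["subject_id"].isin(list(subjects))]
    if df.empty:
        raise ValueError("no records in the analysis subgroup")
    out = {}

    def paired(label, series_by_session):
        wide = series_by_session.unstack("session_type")
        if "HL" not in wide or "LL" not in wide or wide[["HL", "LL"]].isna().any().any():
            warnings.warn(f"{label}: a session is missing; excluded")
            return
        hl, ll = wide["HL"].to_numpy(), wide["LL"].to_numpy()
        res = route_test([hl, ll], "paired_2", comparison=label)
        res.direction_of_change = direction_of_change(res.group_means[0],
                                                      res.group_means[1])
        out[label] = res

    for item, grp in df.groupby("item", sort=False):
        paired(item, grp.set_index(["subject_id", "session_type"])["grams"])
    totals = df.groupby(["subject_id", "session_type"])[["kcal", "sugar_g"]].sum()
    paired("sugar", totals["sugar_g"])
    paired("total_kcal", totals["kcal"])
    return out
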