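"""Per-subject aggregation and food-item clustering.

Fuses per-subject classification accuracy, the higher-negative-affect flag,
and min-max-normalised food consumption into one table, then clusters food
items (items as objects, subject-session consumption as dimensions) with
agglomerative hierarchical clustering for a heat-map-style export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

ACCURACY_CUTOFF = 80.0   # strictly above -> label 1

EXCLUDED_ITEMS = ("water",)  # calories excluded from clustering (water = 0 kcal)


def normalize_food(food_wide):
    """Min-max normalise each item column to [0, 1].

    Normalisation is computed per item across all subjects and both sessions
    jointly, so HL and LL stay on one scale.  Constant columns map to all 0
    with a warning.  Idempotent on already-normalised non-constant columns.
    """
    out = food_wide.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy()
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"column {col!r} is constant; normalised to 0")
            out[col] = 0.0
        else:
            out[col] = (x - lo) / (hi - lo)
    return out


def food_wide_table(records_df, exclude=EXCLUDED_ITEMS, value="grams"):
    """Pivot long consumption records to (subject x item-session) amounts."""
    df = records_df[~records_df["item"].isin(exclude)]
    wide = df.pivot_table(index="subject_id", columns=["item", "session_type"],
                         values=value, aggfunc="sum")
    wide.columns = [f"{item}_{session}" for item, session in wide.columns]
    return wide


@dataclass
class AggregateRow:
    subject_id: str
    normalized: dict             # "item_session" -> [0, 1]
    accuracy_label: int
    neg_affect_label: int

    def __post_init__(self):
        assert self.accuracy_label in (0, 1)
        assert self.neg_affect_label in (0, 1)


def binarize_labels(evals, affect_flags, cutoff=ACCURACY_CUTOFF):
    """accuracy_label = 1 iff subject accuracy strictly above the cutoff;
    neg_affect_label from the higher-negative-affect flag."""
    acc = {e.subject_id: int(e.accuracy > cutoff) for e in evals}
    aff = {s: int(bool(v)) for s, v in affect_flags.items()}
    return acc, aff


def build_aggregate(evals, affect_flags, records_df):
    """AggregateRow per subject present in all three inputs."""
    acc, aff = binarize_labels(evals, affect_flags)
    wide = normalize_food(food_wide_table(records_df))
    rows = []
    for sid in wide.index:
        if sid not in acc or sid not in aff:
            warnings.warn(f"subject {sid} missing labels; excluded")
            continue
        rows.append(AggregateRow(
            subject_id=sid,
            normalized=wide.loc[sid].to_dict(),
            accuracy_label=acc[sid],
            neg_affect_label=aff[sid]))
    return rows


def aggregate_frame(rows):
    df = pd.DataFrame([
        {"subject_id": r.subject_id, **r.normalized,
         "accuracy_label": r.accuracy_label,
         "neg_affect_label": r.neg_affect_label}
        for r in rows]).set_index("subject_id")
    return df


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: dict            # item -> cluster id (1..k)
    linkage: np.ndarray          # scipy linkage matrix
    item_order: list             # leaf order for heat-map export
    items: list = field(default_factory=list)

    def newick(self):
        """Linkage tree in Newick text form (merge heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster_items(normalized, k=3, linkage_method="ward", metric="euclidean"):
    """Agglomerative clustering of item columns.

    ``normalized`` is a (subjects x item-session columns) frame; object =
    item-session column, dimensions = subjects.  Deterministic given the
    linkage/metric configuration.
    """
    items = list(normalized.columns)
    if k > len(items):
        raise ValueError(f"k={k} exceeds {len(items)} items")
    X = normalized.to_numpy(dtype=float).T
    Z = hierarchy.linkage(X, method=linkage_method, metric=metric)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    assert len(set(labels)) == k
    return ClusterResult(
        assignments={it: int(c) for it, c in zip(items, labels)},
        linkage=Z,
        item_order=[items[i] for i in order],
        items=items)


def cross_tabulate(rows):
    """Label cross-table: accuracy_label composition within affect groups."""
    df = aggregate_frame(rows)
    out = {"groups": {}}
    for aff, grp in df.groupby("neg_affect_label"):
        n = len(grp)
        n_high = int((grp["accuracy_label"] == 1).sum())
        out["groups"][int(aff)] = {
            "n": n,
            "n_high_accuracy": n_high,
            "fraction_high_accuracy": n_high / n if n else None,
        }
    for aff in (0, 1):
        out["groups"].setdefault(aff, {"n": 0, "n_high_accuracy": 0,
                                       "fraction_high_accuracy": None})
    return out


def heatmap_matrix(rows, cluster: ClusterResult):
    """Aggregate matrix with columns in cluster leaf order (for CSV export)."""
    df = aggregate_frame(rows)
    cols = cluster.item_order + ["accuracy_label", "neg_affect_label"]
    return df[cols]
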