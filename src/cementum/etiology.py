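"""Etiology classification of hypercementotic teeth.

Three classifiers over the five groups IMP (impacted), INF (infected),
HYPO (hypofunctional), HYPER (hyperfunctional), MIX (mixed condition):

* the fixed published decision tree — PREF at the root; on the preferential
  branch ANT, then MAX THI at 1295 µm, then wear degree; on the
  non-preferential branch wear degree, then MAX VE at 190 µm;
* a criteria rule set (one decisive-criteria list per group) with rule traces;
* a from-scratch CART learner (greedy binary splits maximizing Gini-impurity
  decrease) for refitting on new samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ToothRecord

LABELS = ("HYPER", "HYPO", "IMP", "INF", "MIX")


@dataclass(frozen=True)
class FeatureVector:
    """Predictors consumed by the published tree (and optionally Table-3 rules)."""

    pref: bool
    ant: int                      # 0 impacted, 1 present, 2 lost ante-mortem, 3 NA
    max_thi_um: float
    wear_deg: int
    max_ve_um: float | None = None
    pulp_exp: str = "none"
    caries: bool = False
    hc_stage: int | None = None

    def __post_init__(self):
        if self.max_thi_um <= 0:
            raise ValueError("max_thi_um must be positive")

    @classmethod
    def from_record(cls, r: ToothRecord) -> "FeatureVector":
        return cls(
            pref=r.pref, ant=r.ant, max_thi_um=r.max_thi_um, wear_deg=r.wear_deg,
            max_ve_um=r.max_ve_um, pulp_exp=r.pulp_exp, caries=r.caries_present,
            hc_stage=r.hc_stage,
        )


# ---------------------------------------------------------------------------
# generic tree structure


@dataclass
class TreeNode:
    """A split node (numeric threshold or categorical level subset) or a leaf."""

    variable: str | None = None
    threshold: float | None = None          # numeric: go left iff value < threshold
    left_levels: frozenset | None = None    # categorical: go left iff value in set
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    counts: dict[str, int] = field(default_factory=dict)
    leaf_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def label(self) -> str | None:
        if not self.counts:
            return None
        # majority label; alphabetical tie-break for determinism
        return max(sorted(self.counts), key=lambda k: self.counts[k])

    def describe(self) -> str:
        if self.is_leaf:
            return f"leaf {self.leaf_id or ''} {self.counts}"
        if self.threshold is not None:
            return f"{self.variable} < {self.threshold:g}"
        return f"{self.variable} in {sorted(self.left_levels)}"


@dataclass(frozen=True)
class RoutingResult:
    leaf_id: str | None
    label: str | None
    trace: tuple[str, ...]

    @property
    def routable(self) -> bool:
        return self.leaf_id is not None


class DecisionTree:
    """A binary classification tree over mixed predictors."""

    def __init__(self, root: TreeNode):
        self.root = root

    def route(self, values: dict) -> RoutingResult:
        node = self.root
        trace: list[str] = []
        while not node.is_leaf:
            v = values.get(node.variable)
            if v is None:
                trace.append(f"{node.variable}: missing -> unroutable")
                return RoutingResult(None, None, tuple(trace))
            if node.threshold is not None:
                go_left = float(v) < node.threshold
                trace.append(f"{node.variable}={v:g} {'<' if go_left else '>='} {node.threshold:g}")
            else:
                go_left = v in node.left_levels
                rel = "in" if go_left else "not in"
                trace.append(f"{node.variable}={v} {rel} {sorted(node.left_levels)}")
            node = node.left if go_left else node.right
        trace.append(node.describe())
        return RoutingResult(node.leaf_id, node.label, tuple(trace))

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend([n.right, n.left])
        return out

    def to_text(self, node: TreeNode | None = None, depth: int = 0) -> str:
        node = node or self.root
        pad = "  " * depth
        if node.is_leaf:
            return f"{pad}* {node.describe()}\n"
        out = f"{pad}{node.describe()}?\n"
        out += self.to_text(node.left, depth + 1)
        out += self.to_text(node.right, depth + 1)
        return out


# ---------------------------------------------------------------------------
# the fixed published tree

MAX_THI_CUT_UM = 1295.0
MAX_VE_CUT_UM = 190.0
WEAR_CUT_IMP = 2      # impacted side: wear degree 0, 1 or 2
WEAR_CUT_INF = 1      # infected side: wear degree 0 or 1


def build_published_tree() -> DecisionTree:
    """The seven-leaf classification tree, with the study's leaf counts.

    Leaf counts are those of the 33-tooth study sample routed through the
    tree; majority labels follow from them.
    """
    hyper_pure = TreeNode(counts={"HYPER": 8}, leaf_id="HYPER_pure")
    mix_thick = TreeNode(counts={"MIX": 5}, leaf_id="MIX_thick")
    imp_pure = TreeNode(counts={"IMP": 2}, leaf_id="IMP_pure")
    hyper_mix = TreeNode(counts={"HYPER": 4, "MIX": 1}, leaf_id="HYPER_worn")
    inf_pure = TreeNode(counts={"INF": 4}, leaf_id="INF_pure")
    hypo_pure = TreeNode(counts={"HYPO": 5}, leaf_id="HYPO_pure")
    mix_rough = TreeNode(counts={"MIX": 4}, leaf_id="MIX_rough")

    wear_pref = TreeNode(variable="wear_deg", threshold=WEAR_CUT_IMP + 0.5,
                         left=imp_pure, right=hyper_mix)
    thick = TreeNode(variable="max_thi_um", threshold=MAX_THI_CUT_UM,
                     left=wear_pref, right=mix_thick)
    ant = TreeNode(variable="ant", left_levels=frozenset({1}),
                   left=hyper_pure, right=thick)
    ve = TreeNode(variable="max_ve_um", threshold=MAX_VE_CUT_UM,
                  left=hypo_pure, right=mix_rough)
    wear_nonpref = TreeNode(variable="wear_deg", threshold=WEAR_CUT_INF + 0.5,
                            left=inf_pure, right=ve)
    root = TreeNode(variable="pref", left_levels=frozenset({True, 1}),
                    left=ant, right=wear_nonpref)
    return DecisionTree(root)


def apply_published_tree(v: FeatureVector) -> RoutingResult:
    """Route one feature vector through the published tree.

    A missing field needed on the traversed path (max_ve_um on the
    non-preferential worn branch) yields an explicit unroutable result.
    """
    values = {
        "pref": v.pref,
        "ant": v.ant,
        "max_thi_um": v.max_thi_um,
        "wear_deg": v.wear_deg,
        "max_ve_um": v.max_ve_um,
    }
    return build_published_tree().route(values)


# ---------------------------------------------------------------------------
# Table-3 criteria rule set

_TABLE3: dict[str, list[tuple[str, "callable"]]] = {
    "IMP": [
        ("preferential apposition", lambda v: v.pref),
        ("no antagonist scoreable (ANT=0)", lambda v: v.ant == 0),
        ("no wear", lambda v: v.wear_deg <= 1),
        ("no carious lesion", lambda v: not v.caries),
        ("no pulp exposure", lambda v: v.pulp_exp == "none"),
        ("stage 3 (whole root)", lambda v: v.hc_stage == 3),
        ("MAX THI < 1295 um", lambda v: v.max_thi_um < MAX_THI_CUT_UM),
    ],
    "INF": [
        ("non-preferential apposition", lambda v: not v.pref),
        ("pulp exposure or carious lesion", lambda v: v.pulp_exp != "none" or v.caries),
    ],
    "HYPO": [
        ("non-preferential apposition", lambda v: not v.pref),
        ("wear degree 2 or 3", lambda v: v.wear_deg in (2, 3)),
        ("stage 2 (apical + middle thirds)", lambda v: v.hc_stage == 2),
        ("MAX VE < 190 um", lambda v: v.max_ve_um is not None and v.max_ve_um < MAX_VE_CUT_UM),
    ],
    "HYPER": [
        ("preferential apposition", lambda v: v.pref),
        ("stage 1 (apical third)", lambda v: v.hc_stage == 1),
        ("wear degree >= 6", lambda v: v.wear_deg >= 6),
        ("no carious lesion", lambda v: not v.caries),
        ("no pulp exposure", lambda v: v.pulp_exp == "none"),
        ("MAX THI < 1295 um", lambda v: v.max_thi_um < MAX_THI_CUT_UM),
    ],
}


def classify_table3(v: FeatureVector | ToothRecord) -> tuple[str, dict[str, tuple[int, int]]]:
    """Evaluate the per-group decisive-criteria lists on one tooth.

    Returns ``(label, scores)`` where ``scores[group] = (matched, total)``.
    A unique fully matching group wins.  Teeth fully matching several groups
    are labeled MIX — the mixed condition is defined by overlapping profiles,
    not by criteria of its own — as are teeth partially matching at least two
    groups on half of their criteria.  Anything else is "indeterminate".
    """
    if isinstance(v, ToothRecord):
        v = FeatureVector.from_record(v)
    scores: dict[str, tuple[int, int]] = {}
    full: list[str] = []
    for group, rules in _TABLE3.items():
        matched = sum(bool(fn(v)) for _, fn in rules)
        scores[group] = (matched, len(rules))
        if matched == len(rules):
            full.append(group)
    if len(full) == 1:
        return full[0], scores
    if len(full) >= 2:
        return "MIX", scores
    near = [g for g, (m, n) in scores.items() if m >= n / 2]
    if len(near) >= 2:
        return "MIX", scores
    return "indeterminate", scores


# ---------------------------------------------------------------------------
# CART learner


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _class_counts(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes])


def _best_split(X: pd.DataFrame, y: np.ndarray, classes: np.ndarray):
    """Exhaustive best Gini split: (gain, variable, threshold, left_levels)."""
    n = len(y)
    parent = _gini(_class_counts(y, classes))
    best = (0.0, None, None, None)
    for col in X.columns:
        x = X[col]
        if pd.api.types.is_numeric_dtype(x) and not pd.api.types.is_bool_dtype(x):
            vals = np.sort(x.unique().astype(float))
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                mask = x.to_numpy(dtype=float) < thr
                gain = parent - (
                    mask.sum() / n * _gini(_class_counts(y[mask], classes))
                    + (~mask).sum() / n * _gini(_class_counts(y[~mask], classes))
                )
                if gain > best[0] + 1e-12:
                    best = (gain, col, thr, None)
        else:
            levels = sorted(map(str, x.unique()))
            if len(levels) > 8:
                raise ValueError(f"categorical variable {col!r} has more than 8 levels")
            xs = x.astype(str).to_numpy()
            for k in range(1, len(levels) // 2 + 1):
                for subset in itertools.combinations(levels, k):
                    if k == len(levels) - k and subset[0] != levels[0]:
                        continue  # avoid the mirrored duplicate of an even split
                    mask = np.isin(xs, subset)
                    if not mask.any() or mask.all():
                        continue
                    gain = parent - (
                        mask.sum() / n * _gini(_class_counts(y[mask], classes))
                        + (~mask).sum() / n * _gini(_class_counts(y[~mask], classes))
                    )
                    if gain > best[0] + 1e-12:
                        best = (gain, col, None, frozenset(subset))
    return best


def fit_cart(
    X: pd.DataFrame,
    y,
    min_leaf: int = 2,
    max_depth: int = 5,
) -> DecisionTree:
    """Greedy binary recursive partitioning maximizing Gini-impurity decrease.

    Numeric predictors split at midpoints between sorted distinct values;
    categorical predictors over exhaustive level subsets (≤ 8 levels).
    Growth stops at node purity, ``min_leaf`` or ``max_depth``.  No pruning.
    """
    y = np.asarray(y, dtype=object)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(X) < 2 * min_leaf and len(np.unique(y)) > 1:
        raise ValueError(f"need at least {2 * min_leaf} rows to split")
    classes = np.unique(y)
    counter = itertools.count(1)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        counts = {str(c): int((sub_y == c).sum()) for c in classes if (sub_y == c).sum()}
        if len(counts) == 1 or depth >= max_depth or len(idx) < 2 * min_leaf:
            return TreeNode(counts=counts, leaf_id=f"L{next(counter)}")
        gain, col, thr, levels = _best_split(X.iloc[idx], sub_y, classes)
        if col is None:
            return TreeNode(counts=counts, leaf_id=f"L{next(counter)}")
        x = X[col].iloc[idx]
        if thr is not None:
            mask = x.to_numpy(dtype=float) < thr
        else:
            mask = x.astype(str).isin(levels).to_numpy()
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return TreeNode(counts=counts, leaf_id=f"L{next(counter)}")
        return TreeNode(
            variable=col, threshold=thr, left_levels=levels,
            left=grow(idx[mask], depth + 1), right=grow(idx[~mask], depth + 1),
            counts=counts,
        )

    return DecisionTree(grow(np.arange(len(y)), 0))


def route_frame(tree: DecisionTree, X: pd.DataFrame) -> list[RoutingResult]:
    """Route every row of a feature table; categorical values pass as strings."""
    results = []
    for _, row in X.iterrows():
        values = {}
        for col, v in row.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                values[col] = None
            elif isinstance(v, (bool, np.bool_, int, float, np.integer, np.floating)):
                values[col] = v
            else:
                values[col] = str(v)
        results.append(tree.route(values))
    return results


def leaf_purity(tree: DecisionTree, X: pd.DataFrame, y, ids=None):
    """(n_pure_leaves, n_leaves, misclassified ids) of a tree on labeled data.

    A leaf is pure when all records routed to it share one label;
    misclassified records are those whose label differs from their leaf's
    majority (majority by routed records, leaf-count priors as tie-break).
    """
    y = list(y)
    ids = list(ids) if ids is not None else list(range(len(y)))
    results = route_frame(tree, X)
    routed: dict[str, list[int]] = {}
    for i, res in enumerate(results):
        if res.leaf_id is not None:
            routed.setdefault(res.leaf_id, []).append(i)
    n_leaves = len(tree.leaves())
    n_pure = 0
    mis: list = []
    for leaf in tree.leaves():
        idxs = routed.get(leaf.leaf_id, [])
        if not idxs:
            n_pure += 1  # nothing routed, vacuously pure
            continue
        labels = [y[i] for i in idxs]
        if len(set(labels)) == 1:
            n_pure += 1
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        majority = max(sorted(counts), key=lambda k: (counts[k], leaf.counts.get(k, 0)))
        mis.extend(ids[i] for i in idxs if y[i] != majority)
    return n_pure, n_leaves, mis
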