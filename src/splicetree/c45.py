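"""C4.5-style decision-tree induction over feature tables.

Continuous features only, binary ``value <= threshold`` tests ("yes"
routes left), split selection by gain ratio (information gain divided by
split information), thresholds placed at observed data values.  The
induction settings mirror the study design this pipeline reproduces:
a minimum of one record per branch, pessimistic-error pruning that is a
no-op at 100% confidence, and an iterative (windowing) mode that grows
trees on a seed subset and repeatedly folds misclassified records back
in, restarted from several random windows to dodge local optima.

Training tables are pandas DataFrames with a class column (default
``label``) and one numeric column per feature; missing values must be
filtered out beforehand with :func:`filter_complete`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

_EPS = 1e-12


class InductionError(ValueError):
    pass


@dataclass
class InductionConfig:
    pruning_confidence: float = 100.0
    min_leaf: int = 1
    iterative: bool = True
    n_restarts: int = 10
    initial_window_frac: float = 0.2
    seed: Optional[int] = None
    gain_guard: bool = False
    threshold_style: str = "data"  # "data" (C4.5 convention) or "midpoint"

    def __post_init__(self):
        if not 0 < self.pruning_confidence <= 100:
            raise InductionError("pruning_confidence must be in (0, 100]")
        if self.min_leaf < 1:
            raise InductionError("min_leaf must be >= 1")
        if self.threshold_style not in ("data", "midpoint"):
            raise InductionError(f"bad threshold_style {self.threshold_style!r}")


@dataclass
class TreeNode:
    """Internal test node (``feature``/``threshold`` set) or leaf
    (``klass`` set).  ``left`` is the "yes" branch (value <= threshold)."""

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    klass: Optional[str] = None
    group: Optional[str] = None
    n: int = 0
    members: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        if self.is_leaf:
            d = {"class": self.klass, "group": self.group, "n": self.n}
            if self.members:
                d["members"] = list(self.members)
            return d
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "yes": self.left.to_dict(),
            "no": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "class" in d:
            return cls(klass=d["class"], group=d.get("group"),
                       n=d.get("n", 0), members=tuple(d.get("members", ())))
        return cls(
            feature=d["feature"], threshold=float(d["threshold"]),
            left=cls.from_dict(d["yes"]), right=cls.from_dict(d["no"]),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "TreeNode":
        return cls.from_dict(json.loads(s))


def iter_nodes(tree: TreeNode):
    yield tree
    if not tree.is_leaf:
        yield from iter_nodes(tree.left)
        yield from iter_nodes(tree.right)


def count_nodes(tree: TreeNode) -> int:
    return sum(1 for _ in iter_nodes(tree))


def render_text(tree: TreeNode, indent: str = "") -> str:
    """Indented text rendering; the "yes" (<=) branch is printed first."""
    if tree.is_leaf:
        return f"{indent}{tree.klass} (group {tree.group}, n={tree.n})\n"
    out = ""
    for op, child in (("<=", tree.left), (">", tree.right)):
        test = f"{indent}{tree.feature} {op} {tree.threshold:g}:"
        if child.is_leaf:
            out += f"{test} {child.klass} (group {child.group}, n={child.n})\n"
        else:
            out += f"{test}\n" + render_text(child, indent + "|   ")
    return out


# ---------------------------------------------------------------------------
# split criteria
# ---------------------------------------------------------------------------

def class_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy (bits) of class proportions."""
    total = float(sum(counts))
    if total <= 0:
        raise InductionError("entropy of an empty node is undefined")
    h = 0.0
    for c in counts:
        if c < 0:
            raise InductionError("negative class count")
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def best_split(values, classes, min_leaf: int = 1,
               threshold_style: str = "data"):
    """Best binary threshold on one feature by gain ratio.

    Candidate thresholds are the observed values (each is the largest
    value not exceeding the midpoint of an adjacent distinct pair, the
    C4.5 convention; ``threshold_style='midpoint'`` uses midpoints
    instead).  Returns ``(threshold, gain_ratio, gain)`` or ``None``
    when no admissible split has positive information gain.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(classes)
    n = len(values)
    if n < 2:
        return None
    order = np.argsort(values, kind="stable")
    v, y = values[order], y[order]
    labels, y_codes = np.unique(y, return_inverse=True)
    k = len(labels)
    total = np.bincount(y_codes, minlength=k).astype(float)
    h_parent = class_entropy(total)

    best = None
    left = np.zeros(k)
    for i in range(n - 1):
        left[y_codes[i]] += 1
        if v[i] == v[i + 1]:
            continue
        nl, nr = i + 1, n - i - 1
        if nl < min_leaf or nr < min_leaf:
            continue
        right = total - left
        gain = h_parent - (nl * class_entropy(left) + nr * class_entropy(right)) / n
        if gain <= _EPS:
            continue
        split_info = class_entropy([nl, nr])
        gr = gain / split_info
        if best is None or gr > best[1] + _EPS:
            thr = v[i] if threshold_style == "data" else (v[i] + v[i + 1]) / 2.0
            best = (float(thr), float(gr), float(gain))
    return best


def _balanced_split(values, min_leaf: int):
    """Fallback threshold when no split has positive gain: the admissible
    observed value whose split is most size-balanced (ties to the lower
    threshold).  Returns None for a constant feature."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    best = None
    for i in range(n - 1):
        if v[i] == v[i + 1]:
            continue
        nl, nr = i + 1, n - i - 1
        if nl < min_leaf or nr < min_leaf:
            continue
        imbalance = abs(nl - nr)
        if best is None or imbalance < best[0]:
            best = (imbalance, float(v[i]))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def _majority(y) -> str:
    vals, counts = np.unique(y, return_counts=True)
    return str(vals[np.argmax(counts)])


def grow_tree(df: pd.DataFrame, config: Optional[InductionConfig] = None,
              features: Optional[Sequence[str]] = None,
              class_col: str = "label") -> TreeNode:
    """Grow a decision tree by recursive gain-ratio splitting.

    Recursion stops at class purity or when no admissible split exists.
    At an impure node of *distinct* vectors where every split has zero
    gain (XOR-like patterns), a forced size-balanced split on the first
    feature in canonical order keeps growth going, so any consistent
    table is fit exactly with ``min_leaf=1``.  Contradictory duplicate
    vectors collapse to a majority leaf with a warning.
    """
    config = config or InductionConfig()
    if features is None:
        features = [c for c in FEATURE_NAMES if c in df.columns]
        if not features:
            features = [c for c in df.columns
                        if c not in (class_col, "id", "group")]
    if df.empty:
        raise InductionError("empty training table")
    X = df[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InductionError(
            "training table contains missing values; run filter_complete first"
        )
    y = df[class_col].to_numpy(dtype=object)
    ids = (df["id"].to_numpy(dtype=object) if "id" in df.columns
           else np.arange(len(df)).astype(str))

    def build(idx: np.ndarray) -> TreeNode:
        sub_y = y[idx]
        if len(np.unique(sub_y)) == 1:
            return TreeNode(klass=str(sub_y[0]), n=len(idx),
                            members=tuple(ids[idx]))
        sub_X = X[idx]
        if (sub_X == sub_X[0]).all():
            warnings.warn(
                "contradictory duplicate vectors with differing classes; "
                "emitting a majority leaf"
            )
            return TreeNode(klass=_majority(sub_y), n=len(idx),
                            members=tuple(ids[idx]))
        candidates = []  # (gain_ratio, order, threshold, gain, feature)
        for fi, f in enumerate(features):
            res = best_split(sub_X[:, fi], sub_y, min_leaf=config.min_leaf,
                             threshold_style=config.threshold_style)
            if res is not None:
                thr, gr, gain = res
                candidates.append((gr, fi, thr, gain, f))
        if config.gain_guard and candidates:
            mean_gain = sum(c[3] for c in candidates) / len(candidates)
            guarded = [c for c in candidates if c[3] >= mean_gain - _EPS]
            candidates = guarded or candidates
        if candidates:
            best = candidates[0]
            for c in candidates[1:]:
                if c[0] > best[0] + _EPS:
                    best = c
            _, fi, thr, _, f = best
        else:
            # zero-gain impasse on distinct vectors: force a balanced split
            fi, thr, f = None, None, None
            for j, feat in enumerate(features):
                t = _balanced_split(sub_X[:, j], config.min_leaf)
                if t is not None:
                    fi, thr, f = j, t, feat
                    break
            if fi is None:
                return TreeNode(klass=_majority(sub_y), n=len(idx),
                                members=tuple(ids[idx]))
        mask = sub_X[:, fi] <= thr
        return TreeNode(feature=f, threshold=float(thr),
                        left=build(idx[mask]), right=build(idx[~mask]))

    tree = build(np.arange(len(df)))
    if config.pruning_confidence < 100.0:
        tree = _prune(tree, config.pruning_confidence)
    _assign_groups(tree)
    return tree


def _assign_groups(tree: TreeNode) -> None:
    """Label leaves left-to-right: authentic leaves A, B, C, ...;
    cryptic leaves a, b, c, ...; other classes ``<class>-1``, ..."""
    counters: dict = {}

    def visit(node: TreeNode):
        if node.is_leaf:
            i = counters.get(node.klass, 0)
            counters[node.klass] = i + 1
            if node.klass == "authentic":
                node.group = chr(ord("A") + i)
            elif node.klass == "cryptic":
                node.group = chr(ord("a") + i)
            else:
                node.group = f"{node.klass}-{i + 1}"
            return
        visit(node.left)
        visit(node.right)

    visit(tree)


# ---------------------------------------------------------------------------
# pruning (no-op at 100% confidence)
# ---------------------------------------------------------------------------

def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """Pessimistic error count of a leaf: n times the upper confidence
    bound U_cf(e, n), the error rate p at which observing <= e errors in
    n records has probability cf.  At cf = 100% the bound equals the
    observed error count (pruning becomes a no-op)."""
    if n == 0 or cf >= 100.0:
        return float(e)
    target = cf / 100.0

    def tail(p: float) -> float:  # P(X <= e) for X ~ Binomial(n, p)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
                   for k in range(e + 1))

    lo, hi = e / n, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if tail(mid) > target:
            lo = mid
        else:
            hi = mid
    return n * (lo + hi) / 2


def _prune(tree: TreeNode, cf: float) -> TreeNode:
    if tree.is_leaf:
        return tree
    tree.left = _prune(tree.left, cf)
    tree.right = _prune(tree.right, cf)
    counts: dict = {}
    for node in iter_nodes(tree):
        if node.is_leaf:
            counts[node.klass] = counts.get(node.klass, 0) + node.n
    n = sum(counts.values())
    majority = max(counts, key=counts.get)
    leaf_err = _pessimistic_errors(n, n - counts[majority], cf)
    subtree_err = sum(
        _pessimistic_errors(node.n, 0, cf)
        for node in iter_nodes(tree) if node.is_leaf
    )
    if leaf_err <= subtree_err + _EPS:
        members = tuple(
            m for node in iter_nodes(tree) if node.is_leaf for m in node.members
        )
        return TreeNode(klass=majority, n=n, members=members)
    return tree


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(tree: TreeNode, v) -> tuple:
    """Route one feature vector through a tree.

    ``v`` may be a mapping, a pandas Series, or a
    :class:`~splicetree.features.FeatureVector`.  Returns
    ``(class, group, path)`` where path lists ``(feature, threshold,
    "yes"|"no")`` per internal node visited.  A missing value on the
    realized path raises, naming the offending feature.
    """
    get = v.__getitem__
    node, path = tree, []
    while not node.is_leaf:
        try:
            x = get(node.feature)
        except KeyError:
            x = None
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise InductionError(
                f"feature {node.feature!r} needed at node "
                f"'{node.feature} <= {node.threshold}' is missing"
            )
        if float(x) <= node.threshold:
            path.append((node.feature, node.threshold, "yes"))
            node = node.left
        else:
            path.append((node.feature, node.threshold, "no"))
            node = node.right
    return node.klass, node.group, path


def resubstitution_accuracy(tree: TreeNode, df: pd.DataFrame,
                            class_col: str = "label") -> float:
    """Fraction of training rows the tree classifies correctly."""
    correct = 0
    for _, row in df.iterrows():
        klass, _, _ = classify(tree, row)
        correct += klass == row[class_col]
    return correct / len(df)


# ---------------------------------------------------------------------------
# iterative (windowing) mode
# ---------------------------------------------------------------------------

def iterative_grow(df: pd.DataFrame, config: Optional[InductionConfig] = None,
                   features: Optional[Sequence[str]] = None,
                   class_col: str = "label") -> TreeNode:
    """Windowed induction with restarts.

    Each restart seeds a random window of ``initial_window_frac`` of the
    table (topped up so every class is represented), grows a tree, adds
    every record the tree misclassifies, and repeats to a fixed point.
    Across restarts the tree with the fewest whole-table errors wins,
    ties broken by node count, then by restart order.  Fully
    deterministic for a given ``config.seed``.
    """
    config = config or InductionConfig()
    if config.seed is None:
        raise InductionError("iterative mode requires an explicit seed")
    n = len(df)
    if n == 0:
        raise InductionError("empty training table")
    df = df.reset_index(drop=True)
    y = df[class_col].to_numpy(dtype=object)
    classes = np.unique(y)

    best = None  # (errors, n_nodes, restart, tree)
    for r in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, r])
        size = max(2, int(round(config.initial_window_frac * n)))
        window = set(rng.choice(n, size=min(size, n), replace=False).tolist())
        for cls in classes:
            if not any(y[i] == cls for i in window):
                pool = np.flatnonzero(y == cls)
                window.add(int(rng.choice(pool)))
        while True:
            tree = grow_tree(df.iloc[sorted(window)], config,
                             features=features, class_col=class_col)
            mis = [
                i for i in range(n)
                if classify(tree, df.iloc[i])[0] != y[i]
            ]
            new = [i for i in mis if i not in window]
            if not new:
                errors = len(mis)
                break
            window.update(new)
        size_now = count_nodes(tree)
        if best is None or (errors, size_now, r) < best[:3]:
            best = (errors, size_now, r, tree)
    return best[3]


# ---------------------------------------------------------------------------
# completeness filter
# ---------------------------------------------------------------------------

def filter_complete(df: pd.DataFrame,
                    features: Optional[Sequence[str]] = None) -> tuple:
    """Split a feature table into complete records and dropped ones.

    Returns ``(kept_df, dropped)`` where ``dropped`` is a list of
    ``(id, missing_feature_names)``.  Raises if nothing survives.
    """
    if features is None:
        features = [c for c in FEATURE_NAMES if c in df.columns]
    sub = df[list(features)]
    complete = sub.notna().all(axis=1)
    dropped = []
    for i in df.index[~complete]:
        missing = tuple(f for f in features if pd.isna(df.at[i, f]))
        dropped.append((df.at[i, "id"] if "id" in df.columns else str(i), missing))
    kept = df[complete].reset_index(drop=True)
    if kept.empty:
        raise InductionError("no complete records remain after filtering")
    return kept, dropped
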