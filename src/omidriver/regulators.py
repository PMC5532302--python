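"""Regulator-module assignment via sample-partitioning regression trees.

Each module is summarized by its mean expression profile over tumor
samples.  A shallow regression tree recursively splits the samples by
thresholding that profile at the value maximizing the within-node
sum-of-squares reduction, yielding a small set of expression "states".
A candidate regulator is scored against the tree by how sharply its own
expression separates the two sides of every internal split: the score is
the sample-weighted sum of absolute Welch t-statistics over internal
nodes.  Associations are ranked, the top fraction kept, and modules with
too few passenger candidates (secondary-alteration accumulation) are
filtered out.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ValidationError


@dataclasses.dataclass
class TreeNode:
    """A node of the sample-partitioning tree.

    Leaves carry a sample set with the mean and standard deviation of the
    module profile; internal nodes carry the split threshold, the
    variance (SS) reduction it achieves, and two children that partition
    the node's samples.
    """

    samples: list[str]
    mean: float
    sd: float
    threshold: float | None = None
    variance_reduction: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclasses.dataclass
class RegressionTree:
    root: TreeNode
    profile: pd.Series  # the module mean profile the tree was grown on

    def internal_nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out


@dataclasses.dataclass
class Association:
    """A scored (regulator, module) pair."""

    regulator_id: str
    module_id: str
    score: float
    rank: int = 0
    passenger_count: int = 0
    module_size: int = 0

    @property
    def passenger_fraction(self) -> float:
        return self.passenger_count / self.module_size if self.module_size else 0.0


def _best_split(values: np.ndarray, min_leaf: int) -> tuple[float, float] | None:
    """Exhaustive scan over sorted midpoints; returns (threshold,
    SS reduction) of the best admissible split or None."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    total_ss = float(np.sum((v - v.mean()) ** 2))
    best = None
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    for i in range(min_leaf, n - min_leaf + 1):
        if v[i - 1] == v[i]:
            continue  # no threshold separates equal values
        left_ss = csq[i - 1] - csum[i - 1] ** 2 / i
        right_n = n - i
        right_sum = csum[-1] - csum[i - 1]
        right_ss = (csq[-1] - csq[i - 1]) - right_sum**2 / right_n
        red = total_ss - (left_ss + right_ss)
        if best is None or red > best[1]:
            best = ((v[i - 1] + v[i]) / 2.0, float(red))
    return best


def build_tree(
    module_profile: pd.Series,
    min_leaf: int = 5,
    max_depth: int = 3,
) -> RegressionTree:
    """Grow a regression tree on a module's per-sample mean profile.

    Samples are split by thresholding the profile itself; recursion stops
    at ``min_leaf`` samples per side, ``max_depth``, or when no split
    reduces the sum of squares.  A constant profile yields a single-leaf
    tree.
    """
    if len(module_profile) < 2 * min_leaf:
        raise ValidationError(f"need >= {2 * min_leaf} samples to grow a tree")

    def grow(samples: list[str], depth: int) -> TreeNode:
        vals = module_profile.loc[samples].to_numpy(float)
        node = TreeNode(samples=list(samples), mean=float(vals.mean()),
                        sd=float(vals.std(ddof=0)))
        if depth >= max_depth or len(samples) < 2 * min_leaf or node.sd == 0:
            return node
        found = _best_split(vals, min_leaf)
        if found is None or found[1] <= 0:
            return node
        thr, red = found
        left = [s for s in samples if module_profile[s] <= thr]
        right = [s for s in samples if module_profile[s] > thr]
        node.threshold, node.variance_reduction = thr, red
        node.left = grow(left, depth + 1)
        node.right = grow(right, depth + 1)
        return node

    return RegressionTree(root=grow(list(module_profile.index), 0), profile=module_profile)


def score_association(tree: RegressionTree, regulator_expr: pd.Series) -> float:
    """Score how well a regulator's expression tracks a module's states.

    For every internal node the Welch t-statistic of the regulator
    between the left and right sample sets is computed; the score is
    sum of w_n * |t_n| with w_n = (samples under node) / (total samples).
    A depth-0 tree, or a regulator constant across samples, scores 0.
    Perfectly separated constant sides (zero pooled variance, distinct
    means) are capped at |t| = 1e6 to keep scores finite.
    """
    missing = set(tree.root.samples) - set(regulator_expr.index)
    if missing:
        raise ValidationError(f"regulator expression missing samples: {sorted(missing)[:5]}")
    total = len(tree.root.samples)
    score = 0.0
    for node in tree.internal_nodes():
        a = regulator_expr.loc[node.left.samples].to_numpy(float)
        b = regulator_expr.loc[node.right.samples].to_numpy(float)
        se = np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b))
        diff = a.mean() - b.mean()
        if se == 0:
            t = 0.0 if diff == 0 else 1e6
        else:
            t = min(abs(diff) / se, 1e6)
        score += (len(node.samples) / total) * float(t)
    return score


def score_all(
    module_profiles: Mapping[str, pd.Series],
    regulator_pool: Mapping[str, pd.Series],
    min_leaf: int = 5,
    max_depth: int = 3,
) -> list[Association]:
    """Score every (regulator, module) pair."""
    trees = {mid: build_tree(prof, min_leaf, max_depth) for mid, prof in module_profiles.items()}
    out = []
    for mid, tree in trees.items():
        for rid, expr in regulator_pool.items():
            out.append(Association(rid, mid, score_association(tree, expr)))
    return out


def rank_top(associations: Sequence[Association], top_percent: float = 1.0,
             top_k: int | None = None) -> list[Association]:
    """Keep the top-scoring associations.

    Sorts by score descending (ties by regulator id then module id,
    ascending) and keeps ``ceil(top_percent/100 * N)`` associations, or
    exactly ``top_k`` if given.  Ranks are assigned 1..k.
    """
    if not associations:
        raise ValidationError("rank_top: empty association list")
    if top_k is None and not (0 < top_percent <= 100):
        raise ValidationError("top_percent must be in (0, 100]")
    ordered = sorted(associations, key=lambda a: (-a.score, a.regulator_id, a.module_id))
    k = min(len(ordered), top_k) if top_k is not None else math.ceil(top_percent / 100 * len(ordered))
    kept = ordered[:k]
    for i, a in enumerate(kept, start=1):
        a.rank = i
    return kept


def passenger_filter(
    associations: Sequence[Association],
    passengers: set[str],
    module_members: Mapping[str, set[str]],
    min_fraction: float = 0.10,
) -> list[Association]:
    """Keep associations whose module accumulates passenger candidates.

    Fills in passenger counts per module and drops associations whose
    module has a passenger fraction below ``min_fraction``.
    """
    kept = []
    for a in associations:
        members = module_members.get(a.module_id)
        if not members:
            raise ValidationError(f"module {a.module_id} is empty or unknown")
        a.module_size = len(members)
        a.passenger_count = len(members & passengers)
        if a.passenger_fraction >= min_fraction:
            kept.append(a)
    return kept


def associations_to_frame(associations: Sequence[Association]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "regulator": a.regulator_id,
            "module": a.module_id,
            "score": a.score,
            "rank": a.rank,
            "module_size": a.module_size,
            "passenger_count": a.passenger_count,
            "passenger_fraction": a.passenger_fraction,
        }
        for a in associations
    ])
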