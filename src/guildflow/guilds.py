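"""Co-abundance guild detection.

The procedure: (1) within-subject (repeated-measures) correlation between
every pair of prevalent ASVs, computed on the pooled subject-centered
residuals so that mouse-level baselines do not inflate correlations;
(2) conversion to a distance, d = 1 - r; (3) Ward agglomerative
clustering; (4) a top-down walk of the dendrogram where each candidate
split (left clade vs right clade) is tested by PERMANOVA on the clade's
sub-distance-matrix, recursing only while splits are significant. Clades
that fail the test, or are too small to test, become guilds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import AbundanceTable, DistanceMatrix
from .diversity import permanova

__all__ = [
    "Dendrogram",
    "SplitRecord",
    "GuildAssignment",
    "within_subject_correlation",
    "coabundance_distance",
    "ward_linkage",
    "delineate_guilds",
]


def within_subject_correlation(
    x: Sequence[float], y: Sequence[float], subjects: Sequence
) -> float:
    """Repeated-measures correlation of two series sharing subjects.

    Each subject's mean is subtracted from its own observations of x and
    y, and the Pearson correlation of the pooled residuals is returned
    (the Bland-Altman within-subject correlation). Subjects with a single
    observation contribute zero residuals. Returns ``nan`` when either
    residual series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.shape == y.shape == subjects.shape):
        raise ValueError("x, y and subjects must be aligned 1-d arrays")
    if len(x) < 3 and len(np.unique(subjects)) < 2:
        raise ValueError("need >= 2 subjects or >= 3 observations")
    rx = np.empty_like(x)
    ry = np.empty_like(y)
    for s in np.unique(subjects):
        m = subjects == s
        rx[m] = x[m] - x[m].mean()
        ry[m] = y[m] - y[m].mean()
    vx = (rx**2).sum()
    vy = (ry**2).sum()
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float((rx * ry).sum() / np.sqrt(vx * vy))


def coabundance_distance(a: AbundanceTable, subjects: Sequence) -> DistanceMatrix:
    """Pairwise 1 - r distances among features via within-subject correlation.

    Undefined correlations (a feature constant within every subject) are
    treated as r = 0, distance 1, with a warning.
    """
    if a.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if a.n_features < 2:
        raise ValueError("need at least 2 features")
    subjects = np.asarray(subjects)
    if len(subjects) != a.n_samples:
        raise ValueError("subjects must align with samples")

    resid = a.values.copy()
    for s in np.unique(subjects):
        m = subjects == s
        resid[m] -= resid[m].mean(axis=0, keepdims=True)

    norms = np.sqrt((resid**2).sum(axis=0))
    degenerate = norms <= 0
    if degenerate.any():
        bad = [f for f, z in zip(a.feature_ids, degenerate) if z]
        warnings.warn(
            f"{len(bad)} feature(s) with zero within-subject variance treated as uncorrelated: {bad[:5]}",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = resid / safe
    r = unit.T @ unit
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(list(a.feature_ids), dist)


@dataclass
class Dendrogram:
    """Ward merge tree over feature ids (scipy linkage encoding)."""

    ids: list[str]
    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix

    def __post_init__(self) -> None:
        n = len(self.ids)
        z = np.asarray(self.linkage, dtype=float)
        if z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match ids")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing under Ward linkage")
        self.linkage = z

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl = node.dist - left.dist
            br = node.dist - right.dist
            return f"({render(left)}:{bl:.10g},{render(right)}:{br:.10g})"

        return render(tree) + ";"


def ward_linkage(d: DistanceMatrix) -> Dendrogram:
    """Ward's minimum-variance agglomeration of the given dissimilarities.

    Applies the Lance-Williams update to the supplied distances (they need
    not be Euclidean); deterministic given input order.
    """
    if d.n < 2:
        raise ValueError("need at least 2 items")
    condensed = squareform(d.d, checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(list(d.item_ids), z)


@dataclass
class SplitRecord:
    node: int  # linkage row index of the tested internal node
    n_left: int
    n_right: int
    pseudo_f: float
    p_value: float
    split: bool  # True when the clades were separated


@dataclass
class GuildAssignment:
    """Partition of features into guilds plus the evidence that produced it."""

    guild_of: dict[str, str]  # feature id -> guild label
    splits: list[SplitRecord] = field(default_factory=list)
    n_permutations: int = 9999
    alpha: float = 0.001

    @property
    def guild_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.guild_of.values():
            seen.setdefault(g)
        return list(seen)

    @property
    def n_guilds(self) -> int:
        return len(self.guild_ids)

    def members(self, guild: str) -> list[str]:
        return [f for f, g in self.guild_of.items() if g == guild]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.guild_of), "guild": list(self.guild_of.values())}
        ).set_index("feature_id")

    def splits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.splits])


def delineate_guilds(
    tree: Dendrogram,
    d: DistanceMatrix,
    n_perm: int = 9999,
    alpha: float = 0.001,
    seed: Optional[int] = None,
    min_split_size: int = 3,
    exhaustive_cap: int = 20000,
) -> GuildAssignment:
    """Cut the Ward tree into guilds by recursive PERMANOVA.

    Depth-first from the root: each internal node whose clade has at least
    ``min_split_size`` members is tested (labels = left vs right child) on
    the clade's sub-distance-matrix; significant splits (p < alpha) are
    recursed into, everything else becomes one guild. No multiplicity
    correction is applied across the sequential tests; the fixed, stringent
    alpha plays that role.
    """
    if list(tree.ids) != list(d.item_ids):
        raise ValueError("dendrogram leaves do not match distance matrix items")
    n = len(tree.ids)
    root = hierarchy.to_tree(tree.linkage)
    base_seed = seed if seed is not None else 0

    def node_seed(node_id: int) -> int:
        # per-node stream: the p-value at a node does not depend on the
        # traversal path, so tightening alpha can only merge guilds
        return int(np.random.SeedSequence((base_seed, node_id)).generate_state(1)[0] % (2**31 - 1))

    assignment: dict[str, str] = {}
    splits: list[SplitRecord] = []
    counter = 0

    def leaves(node) -> list[int]:
        return node.pre_order(lambda nd: nd.id)

    def make_guild(node) -> None:
        nonlocal counter
        counter += 1
        label = f"Guild_{counter}"
        for i in leaves(node):
            assignment[tree.ids[i]] = label

    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.count < min_split_size:
            make_guild(node)
            continue
        left, right = node.get_left(), node.get_right()
        idx = leaves(left) + leaves(right)
        labels = np.array([0] * left.count + [1] * right.count)
        sub = d.d[np.ix_(idx, idx)]
        res = permanova(
            sub,
            labels,
            n_perm=n_perm,
            seed=node_seed(int(node.id)),
            exhaustive_cap=exhaustive_cap,
        )
        significant = res.p_value < alpha
        splits.append(
            SplitRecord(
                node=int(node.id - n),
                n_left=left.count,
                n_right=right.count,
                pseudo_f=res.pseudo_f,
                p_value=res.p_value,
                split=significant,
            )
        )
        if significant:
            # push right first so the left clade is labelled first
            stack.append(right)
            stack.append(left)
        else:
            make_guild(node)

    guild_of = {fid: assignment[fid] for fid in tree.ids}
    return GuildAssignment(guild_of=guild_of, splits=splits, n_permutations=n_perm, alpha=alpha)
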