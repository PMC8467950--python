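"""Alpha/beta diversity, ordination and permutation tests.

PERMANOVA follows Anderson's pseudo-F on a distance matrix:

    SS_total  = (1/n) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F = [(SS_total - SS_within) / (g - 1)] / [SS_within / (n - g)]

with a permutation p-value p = (1 + #{F_perm >= F_obs}) / (1 + P). When the
number of distinct label arrangements is small the null is enumerated
exhaustively and the p-value is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import beta_diversity
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .core_io import CountTable, DistanceMatrix, PhyloTree

__all__ = [
    "PermanovaResult",
    "OrdinationResult",
    "shannon",
    "weighted_unifrac",
    "nmds",
    "permanova",
    "compare_groups",
    "group_dissimilarity",
]


def shannon(t: CountTable, log_base: float = 2.0) -> pd.Series:
    """Shannon diversity H = -sum p log(p) per sample (default base 2)."""
    totals = t.sample_totals()
    if (totals == 0).any():
        bad = t.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    h = stats.entropy(t.counts, base=log_base, axis=1)
    return pd.Series(h, index=t.sample_ids, name="shannon")


def weighted_unifrac(t: CountTable, tree: PhyloTree, variant: str = "unnormalized") -> DistanceMatrix:
    """Weighted UniFrac among samples.

    Unnormalized: sum over branches of b_i * |p_i^A - p_i^B| where p_i^X is
    the fraction of X's reads on leaves below branch i. The normalized
    variant divides by sum b_i * (p_i^A + p_i^B).
    """
    if variant not in ("unnormalized", "normalized"):
        raise ValueError("variant must be 'unnormalized' or 'normalized'")
    missing = set(t.feature_ids) - set(tree.leaf_names)
    if missing:
        raise ValueError(f"features not in tree: {sorted(missing)[:5]}")
    if (t.sample_totals() == 0).any():
        raise ValueError("zero-total sample")
    dm = beta_diversity(
        "weighted_unifrac",
        t.counts,
        ids=t.sample_ids,
        taxa=t.feature_ids,
        tree=tree.tree,
        normalized=(variant == "normalized"),
    )
    return DistanceMatrix(list(t.sample_ids), np.asarray(dm.data, dtype=float))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # items x k
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts: int


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: Optional[int] = None,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs SMACOF from ``n_restarts`` random configurations plus one
    classical-MDS (principal-coordinates) start and keeps the lowest-stress
    solution — the PCoA start usually dominates on near-Euclidean inputs
    while the random restarts guard against its failure modes.
    """
    if d.n < k + 1:
        raise ValueError(f"need at least {k + 1} items for a {k}-d ordination")

    def _fit(n_init: int, init: str) -> MDS:
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=n_init,
            init=init,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=seed,
        )
        model.fit(d.d)
        return model

    best = min(
        (_fit(n_restarts, "random"), _fit(1, "classical_mds")),
        key=lambda m: m.stress_,
    )
    converged = bool(best.n_iter_ < max_iter) and np.isfinite(best.stress_)
    return OrdinationResult(
        coordinates=pd.DataFrame(best.embedding_, index=d.item_ids, columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=float(best.stress_),
        converged=converged,
        n_restarts=n_restarts + 1,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float  # may be +inf when SS_within == 0
    p_value: float
    n_permutations: int
    exhaustive: bool
    n: int = 0
    n_groups: int = 0


_SS_EPS = 1e-12


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        z = codes == g
        n_g = int(z.sum())
        ss_within += d2[np.ix_(z, z)].sum() / (2.0 * n_g)
    if ss_within <= _SS_EPS * max(ss_total, 1.0):
        return math.inf
    return ((ss_total - ss_within) / (n_groups - 1)) / (ss_within / (n - n_groups))


def _pseudo_f_batch(d2: np.ndarray, codes_batch: np.ndarray, n_groups: int, group_sizes: np.ndarray) -> np.ndarray:
    """Vectorized pseudo-F for a batch of label vectors (P x n)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(codes_batch.shape[0])
    for g in range(n_groups):
        m = (codes_batch == g).astype(float)  # P x n
        ss_within += np.einsum("pi,pi->p", m @ d2, m) / (2.0 * group_sizes[g])
    f = np.empty_like(ss_within)
    degenerate = ss_within <= _SS_EPS * max(ss_total, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((ss_total - ss_within) / (n_groups - 1)) / (ss_within / (n - n_groups))
    f[degenerate] = math.inf
    return f


def permanova(
    d: Union[DistanceMatrix, np.ndarray],
    labels: Sequence,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    exhaustive_cap: int = 20000,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Labels are permuted jointly over rows/columns. If the number of
    distinct label arrangements is at most ``exhaustive_cap`` the null
    distribution is enumerated completely and the p-value is exact;
    otherwise ``n_perm`` random permutations are drawn.
    """
    mat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = mat.shape[0]
    if len(labels) != n:
        raise ValueError("labels length does not match distance matrix")
    if n < 3:
        raise ValueError("need at least 3 items")
    uniq, codes = np.unique(labels, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    group_sizes = np.bincount(codes)
    if n - n_groups == 0:
        raise ValueError("residual degrees of freedom are zero (n == number of groups)")

    d2 = mat**2
    f_obs = _pseudo_f(d2, codes, n_groups)

    n_arrangements = math.factorial(n) // math.prod(math.factorial(int(s)) for s in group_sizes)
    if n_arrangements <= exhaustive_cap:
        fs = np.array(
            [_pseudo_f(d2, np.array(perm), n_groups) for perm in multiset_permutations(codes.tolist())]
        )
        ge = _count_ge(fs, f_obs)
        return PermanovaResult(f_obs, ge / n_arrangements, n_arrangements, True, n, n_groups)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    fs = _pseudo_f_batch(d2, perms, n_groups, group_sizes.astype(float))
    ge = _count_ge(fs, f_obs)
    return PermanovaResult(f_obs, (1 + ge) / (1 + n_perm), n_perm, False, n, n_groups)


def _count_ge(fs: np.ndarray, f_obs: float) -> int:
    if math.isinf(f_obs):
        return int(np.isinf(fs).sum())
    tol = 1e-12 * max(1.0, abs(f_obs))
    return int((fs >= f_obs - tol).sum())


def compare_groups(
    values: Sequence[float],
    groups: Sequence,
    p_adjust: str = "holm",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across groups plus Dunn's pairwise post hoc.

    Returns (H, kw_p, pairwise frame) where the frame has one row per group
    pair with Dunn's z, raw two-sided p and the multiplicity-adjusted p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[groups == g] for g in uniq]
    if any(len(v) < 2 for v in by_group):
        small = [g for g, v in zip(uniq, by_group) if len(v) < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    h, kw_p = stats.kruskal(*by_group)

    # Dunn's test: z on mean ranks with tie correction
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a, b = uniq[i], uniq[j]
            se = math.sqrt(var_base * (1.0 / len(by_group[i]) + 1.0 / len(by_group[j])))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p"], method=p_adjust)[1]
    return float(h), float(kw_p), pairwise


def group_dissimilarity(
    d: DistanceMatrix, labels: Sequence, group_a, group_b
) -> np.ndarray:
    """All cross-group sample-pair distances between two groups."""
    labels = np.asarray(labels)
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ")
    for g in (group_a, group_b):
        if g not in labels:
            raise ValueError(f"unknown group label: {g!r}")
    ia = np.where(labels == group_a)[0]
    ib = np.where(labels == group_b)[0]
    return d.d[np.ix_(ia, ib)].ravel()
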