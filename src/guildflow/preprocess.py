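"""Rarefaction, abundance/prevalence filtering, normalization, guild rollup."""

from __future__ import annotations

import warnings
import zlib
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np

from .core_io import AbundanceTable, CountTable

if TYPE_CHECKING:  # pragma: no cover
    from .guilds import GuildAssignment

__all__ = [
    "rarefy",
    "remove_spurious",
    "prevalence_filter",
    "to_relative",
    "ast_transform",
    "guild_abundance",
]


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed by the sample id, so results do not depend on
    # sample order in the table
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(sample_id.encode()))))


def rarefy(t: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample's reads, without replacement, to ``depth``.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning; if none remain the call is fatal. The draw is made in a
    canonical feature order (sorted ids) with a per-sample stream, so the
    result is deterministic under a fixed seed and equivariant under
    permutation of the feature axis.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = t.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    if not keep.all():
        dropped = [s for s, k in zip(t.sample_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped[:5]}", stacklevel=2)

    order = np.argsort(np.asarray(t.feature_ids))  # canonical feature order
    inv = np.argsort(order)
    new_rows = []
    new_ids = []
    for i, sid in enumerate(t.sample_ids):
        if not keep[i]:
            continue
        row = t.counts[i, order]
        total = int(row.sum())
        if total == depth:
            new_rows.append(t.counts[i].copy())
            new_ids.append(sid)
            continue
        rng = _sample_rng(seed, sid)
        # rank all reads by iid uniform keys; keep the `depth` smallest
        keys = rng.random(total)
        kept_idx = np.argpartition(keys, depth)[:depth]
        feature_of_read = np.repeat(np.arange(row.size), row)
        sub = np.bincount(feature_of_read[kept_idx], minlength=row.size)
        new_rows.append(sub[inv])
        new_ids.append(sid)
    return CountTable(new_ids, list(t.feature_ids), np.array(new_rows, dtype=np.int64))


def remove_spurious(t: CountTable, min_mean_relabund: float = 1e-4) -> CountTable:
    """Drop features whose mean relative abundance is below the cutoff."""
    if not (0 <= min_mean_relabund < 1):
        raise ValueError("min_mean_relabund must be in [0, 1)")
    totals = t.sample_totals()
    if (totals == 0).any():
        raise ValueError("zero-total sample; rarefy or drop it first")
    mean_rel = (t.counts / totals[:, None]).mean(axis=0)
    keep = [f for f, m in zip(t.feature_ids, mean_rel) if m >= min_mean_relabund]
    if not keep:
        raise ValueError("abundance filter removed every feature")
    return t.select_features(keep)


def prevalence_filter(
    t: CountTable, threshold: float = 0.40, within_samples: Optional[Sequence[str]] = None
) -> CountTable:
    """Keep features present in strictly more than ``threshold`` of samples.

    Presence means count > 0. Prevalence is computed over ``within_samples``
    when given (e.g., the diseased-strain subset of a mixed-genotype study)
    but the returned table keeps all samples.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if within_samples is None:
        subset_idx = np.arange(t.n_samples)
    else:
        within = list(within_samples)
        if not within:
            raise ValueError("within_samples subset is empty")
        missing = set(within) - set(t.sample_ids)
        if missing:
            raise ValueError(f"unknown sample ids in subset: {sorted(missing)[:5]}")
        subset_idx = np.array([t.sample_ids.index(s) for s in within])
    present = (t.counts[subset_idx] > 0).sum(axis=0)
    keep = [f for f, c in zip(t.feature_ids, present) if c > threshold * len(subset_idx)]
    if not keep:
        raise ValueError("no feature passes the prevalence filter")
    return t.select_features(keep)


def to_relative(t: CountTable) -> AbundanceTable:
    """Counts -> per-sample relative abundance (rows sum to 1)."""
    totals = t.sample_totals().astype(float)
    if (totals == 0).any():
        bad = t.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return AbundanceTable(list(t.sample_ids), list(t.feature_ids), t.counts / totals[:, None], scale="relative")


def ast_transform(a: AbundanceTable) -> AbundanceTable:
    """Arcsine-square-root transform of proportions (variance stabilizing)."""
    if a.scale != "relative":
        raise ValueError("ast_transform expects a relative-abundance table")
    v = a.values
    if (v < -1e-12).any() or (v > 1 + 1e-12).any():
        raise ValueError("proportions must lie in [0, 1]")
    return AbundanceTable(list(a.sample_ids), list(a.feature_ids), np.arcsin(np.sqrt(np.clip(v, 0.0, 1.0))), scale="ast")


def guild_abundance(a: AbundanceTable, assignment: "GuildAssignment") -> AbundanceTable:
    """Sum member relative abundances per guild; feature axis becomes guilds."""
    if a.scale != "relative":
        raise ValueError("guild_abundance expects a relative-abundance table")
    unknown = set(assignment.guild_of) - set(a.feature_ids)
    if unknown:
        raise ValueError(f"guild members missing from table: {sorted(unknown)[:5]}")
    guild_ids = assignment.guild_ids
    col = {f: i for i, f in enumerate(a.feature_ids)}
    values = np.zeros((a.n_samples, len(guild_ids)))
    for g_i, g in enumerate(guild_ids):
        idx = [col[f] for f in assignment.members(g)]
        values[:, g_i] = a.values[:, idx].sum(axis=1)
    # raw scale: guild sums need not total 1 if the table was subset first
    scale = "relative" if np.allclose(values.sum(axis=1), 1.0, atol=1e-9) else "raw"
    return AbundanceTable(list(a.sample_ids), list(guild_ids), values, scale=scale)
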