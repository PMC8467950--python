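"""Shared domain types and plain-text I/O.

Count tables, abundance tables and distance matrices travel as TSV
(UTF-8, "." decimal); phylogenies as Newick; configuration as YAML.
Count tables are stored samples-as-rows; a flag accepts transposed
(features-as-rows, QIIME-style) input.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

__all__ = [
    "CountTable",
    "AbundanceTable",
    "SampleInfo",
    "PhyloTree",
    "DistanceMatrix",
    "PipelineConfig",
    "load_dataset",
    "save_table",
    "read_count_table",
    "read_abundance_table",
    "read_distance_matrix",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "samples_to_frame",
    "frame_to_samples",
]

ABUNDANCE_SCALES = ("relative", "ast", "log", "raw")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class CountTable:
    """Samples x features matrix of non-negative integer read counts."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        c = np.asarray(self.counts)
        if c.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if np.issubdtype(c.dtype, np.floating):
            bad = np.argwhere((c < 0) | (c != np.floor(c)))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    "counts must be non-negative integers; offending cell "
                    f"(sample={self.sample_ids[i]!r}, feature={self.feature_ids[j]!r}) "
                    f"= {c[i, j]}"
                )
            c = c.astype(np.int64)
        elif not np.issubdtype(c.dtype, np.integer):
            raise ValueError(f"counts dtype {c.dtype} is not numeric")
        if (c < 0).any():
            i, j = np.argwhere(c < 0)[0]
            raise ValueError(
                "counts must be non-negative; offending cell "
                f"(sample={self.sample_ids[i]!r}, feature={self.feature_ids[j]!r}) "
                f"= {c[i, j]}"
            )
        self.counts = c

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return CountTable(list(ids), list(self.feature_ids), self.counts[idx])

    def select_features(self, ids: Sequence[str]) -> "CountTable":
        idx = [self.feature_ids.index(f) for f in ids]
        return CountTable(list(self.sample_ids), list(ids), self.counts[:, idx])


@dataclass
class AbundanceTable:
    """Samples x features matrix of real-valued abundances.

    ``scale`` records the transform history: ``relative`` rows sum to 1,
    ``ast`` holds arcsine-square-root values in [0, pi/2], ``log`` holds
    log-transformed values, ``raw`` anything else.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match ids")
        if self.scale not in ABUNDANCE_SCALES:
            raise ValueError(f"scale must be one of {ABUNDANCE_SCALES}")
        if self.scale == "relative":
            sums = v.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"relative-abundance rows must sum to 1; sample "
                    f"{self.sample_ids[bad]!r} sums to {sums[bad]}"
                )
        if self.scale == "ast":
            if (v < -1e-12).any() or (v > np.pi / 2 + 1e-12).any():
                raise ValueError("ast values must lie in [0, pi/2]")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return AbundanceTable(list(ids), list(self.feature_ids), self.values[idx], self.scale)


@dataclass
class SampleInfo:
    """Per-sample host metadata for one fecal sample."""

    sample_id: str
    mouse_id: str
    group: str
    day: int
    food: Optional[float] = None  # g/day
    water: Optional[float] = None  # mL/day
    body_weight: Optional[float] = None  # g
    glucose: Optional[float] = None  # mg/dL

    def __post_init__(self) -> None:
        for name in ("food", "water", "body_weight", "glucose"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


METADATA_COLUMNS = ["sample_id", "mouse_id", "group", "day", "food", "water", "body_weight", "glucose"]


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in samples], columns=METADATA_COLUMNS)
    return df.set_index("sample_id")


def frame_to_samples(df: pd.DataFrame) -> list[SampleInfo]:
    df = df.reset_index() if df.index.name == "sample_id" else df
    _check_unique(df["sample_id"].tolist(), "sample")
    pairs = list(zip(df["mouse_id"], df["day"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("(mouse_id, day) pairs must be unique")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in ("food", "water", "body_weight", "glucose"):
            v = row.get(name)
            kwargs[name] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        out.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                mouse_id=str(row["mouse_id"]),
                group=str(row["group"]),
                day=int(row["day"]),
                **kwargs,
            )
        )
    return out


class PhyloTree:
    """Rooted phylogeny with branch lengths, consumed by UniFrac.

    Wraps a :class:`skbio.TreeNode`. Branch lengths are required on every
    non-root edge (UniFrac is undefined without them) and leaf labels must
    be unique.
    """

    def __init__(self, tree: TreeNode):
        leaves = [t.name for t in tree.tips()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("leaf labels must be unique")
        if any(n is None for n in leaves):
            raise ValueError("all leaves must be labelled")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError(
                    f"edge above {node.name or '<internal>'} has no branch length; "
                    "UniFrac is undefined without branch lengths"
                )
            if node.length < 0:
                raise ValueError("branch lengths must be >= 0")
        self.tree = tree

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(io.StringIO(newick)))


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarities among samples or among features."""

    item_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.item_ids = _check_unique(self.item_ids, "item")
        m = np.asarray(self.d, dtype=float)
        n = len(self.item_ids)
        if m.shape != (n, n):
            raise ValueError(f"distance matrix shape {m.shape} does not match {n} items")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be 0")
        if (m < -1e-12).any():
            raise ValueError("distances must be >= 0")
        m = np.clip((m + m.T) / 2.0, 0.0, None)
        np.fill_diagonal(m, 0.0)
        self.d = m

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.item_ids, columns=self.item_ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.item_ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis pipeline.

    Defaults follow the study design this package models: rarefaction to
    13,000 reads/sample, prevalence strictly above 40% of samples, 9999
    permutations at alpha 0.001 for guild splits, BH q < 0.25 for
    associations.
    """

    rarefaction_depth: int = 13000
    spurious_min_mean_relabund: float = 1e-4
    prevalence_threshold: float = 0.40
    n_permutations: int = 9999
    split_alpha: float = 0.001
    q_threshold: float = 0.25
    shannon_log_base: float = 2.0
    unifrac_variant: str = "unnormalized"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_threshold < 1):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not (0 < self.split_alpha < 1):
            raise ValueError("split_alpha must be in (0, 1)")
        if self.unifrac_variant not in ("unnormalized", "normalized"):
            raise ValueError("unifrac_variant must be 'unnormalized' or 'normalized'")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(vars(self), sort_keys=False))


# ---------------------------------------------------------------------------
# readers / writers

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles


def read_count_table(path: Union[str, Path], transposed: bool = False) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transposed:
        df = df.T
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: count table contains non-numeric values")
    return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), arr)


def read_abundance_table(path: Union[str, Path], scale: str = "raw") -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return AbundanceTable(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float), scale)


def read_distance_matrix(path: Union[str, Path]) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: distance matrix row and column ids differ")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float))


def read_metadata(path: Union[str, Path]) -> list[SampleInfo]:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "mouse_id": str, "group": str}, float_precision="round_trip"
    )
    missing = {"sample_id", "mouse_id", "group", "day"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return frame_to_samples(df)


def write_metadata(samples: Sequence[SampleInfo], path: Union[str, Path]) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_tree(path: Union[str, Path]) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path: Union[str, Path]) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def save_table(table: Union[CountTable, AbundanceTable, DistanceMatrix], path: Union[str, Path]) -> None:
    """Write any of the tabular types as TSV with ids; lossless round trip."""
    if isinstance(table, CountTable):
        df = table.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif isinstance(table, AbundanceTable):
        df = table.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif isinstance(table, DistanceMatrix):
        df = table.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    else:
        raise TypeError(f"cannot save object of type {type(table).__name__}")


def load_dataset(
    counts_path: Union[str, Path],
    metadata_path: Union[str, Path],
    tree_path: Optional[Union[str, Path]] = None,
    transposed: bool = False,
) -> tuple[CountTable, list[SampleInfo], Optional[PhyloTree]]:
    """Load counts + metadata (+ optional tree) and reconcile sample ids.

    The sample sets of the count table and the metadata are intersected;
    samples present in only one input are dropped with a warning. An empty
    intersection is fatal.
    """
    counts = read_count_table(counts_path, transposed=transposed)
    meta = read_metadata(metadata_path)
    meta_ids = {s.sample_id for s in meta}
    common = [s for s in counts.sample_ids if s in meta_ids]
    if not common:
        raise ValueError("no sample ids shared between counts and metadata")
    dropped = (set(counts.sample_ids) | meta_ids) - set(common)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) absent from counts or metadata: "
            f"{sorted(dropped)[:5]}",
            stacklevel=2,
        )
        counts = counts.select_samples(common)
        meta = [s for s in meta if s.sample_id in set(common)]
    order = {sid: i for i, sid in enumerate(counts.sample_ids)}
    meta.sort(key=lambda s: order[s.sample_id])
    tree = read_tree(tree_path) if tree_path is not None else None
    return counts, meta, tree
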