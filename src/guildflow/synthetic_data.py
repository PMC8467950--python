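"""Longitudinal community simulator with planted co-abundance guilds.

Emulates a five-arm mouse feeding study (10 mice per group, fecal
profiling on Days 0/14/28): a latent-factor softmax-multinomial model
plants guild blocks with a tunable within-guild correlation, mouse-level
random effects make repeated measures genuinely subject-correlated, and
host phenotypes (fasting glucose, body weight) are coupled to food and
water intake and to guild abundances.

Model for sample ``s`` (mouse m, group g, day t) and ASV ``j`` in guild
``G(j)``::

    lambda_js = base_j + load * f_{G(j),s} + shift_{G(j),g,t} + u_{j,m} + eps_js
    p_s       = softmax_j(lambda_js)
    counts_s  ~ Multinomial(L_s, p_s),  L_s ~ Uniform{library_size_range}

``f`` is a per-(guild, sample) standard-normal factor shared by all guild
members; ``load`` is chosen so that the latent within-guild correlation is
``within_guild_corr``. Treatment effects are additive shifts on the latent
log-abundance of a whole guild for specific (group, day) cells; the last
guild receives no shift by default and serves as a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from skbio import TreeNode

from .core_io import (
    CountTable,
    PhyloTree,
    SampleInfo,
    save_table,
    write_metadata,
    write_tree,
)

__all__ = ["SimConfig", "SyntheticTruth", "simulate_tree", "simulate_community", "simulate_phenotypes", "generate_dataset"]

GROUP_NAMES = ("control", "GTE1", "GTE2", "GTP1", "GTP2")


def _default_treatment_effects() -> dict[tuple[int, str, int], float]:
    """Per-(guild, group, day) latent log-abundance shifts.

    Each treated arm moves a couple of guilds up or down at Days 14/28,
    with the Day-28 shift larger (effects build up on diet). The last
    guild is never touched.
    """
    eff: dict[tuple[int, str, int], float] = {}
    plan = {
        "GTE1": {0: +1.0, 1: -1.0},
        "GTE2": {0: +0.8, 2: -1.0},
        "GTP1": {3: +1.0, 4: -0.8},
        "GTP2": {2: +1.0, 5: -1.0},
    }
    for group, shifts in plan.items():
        for guild, base in shifts.items():
            eff[(guild, group, 14)] = base
            eff[(guild, group, 28)] = 1.5 * base
    return eff


def _default_glucose_gammas(n_guilds: int) -> tuple[float, ...]:
    g = [0.0] * n_guilds
    g[0], g[1] = 40.0, -40.0
    return tuple(g)


def _default_weight_gammas(n_guilds: int) -> tuple[float, ...]:
    g = [0.0] * n_guilds
    g[2], g[0] = 3.0, 2.0
    return tuple(g)


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_groups: int = 5
    mice_per_group: int = 10
    days: tuple[int, ...] = (0, 14, 28)
    n_asvs: int = 60
    n_guilds: int = 8
    within_guild_corr: float = 0.8
    treatment_effects: Optional[Mapping[tuple[int, str, int], float]] = None
    mouse_random_effect_sd: float = 0.3
    latent_noise_sd: float = 1.0
    base_abundance_sd: float = 1.0
    library_size_range: tuple[int, int] = (15000, 25000)
    # phenotype coupling: y = beta0 + beta_food*food + beta_water*water
    #                       + sum_g gamma_g * AST(guild relabund) + noise
    beta0_glucose: float = 40.0
    beta_food_glucose: float = 40.0
    beta_water_glucose: float = 1.5
    gamma_glucose: Optional[tuple[float, ...]] = None
    noise_sd_glucose: float = 20.0
    beta0_weight: float = 22.0
    beta_food_weight: float = 2.5
    beta_water_weight: float = 0.2
    gamma_weight: Optional[tuple[float, ...]] = None
    noise_sd_weight: float = 1.5
    food_noise_sd: float = 0.7
    water_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_guilds <= self.n_asvs):
            raise ValueError("need n_asvs >= n_guilds >= 1")
        if self.treatment_effects is None:
            # default plan trimmed to the guilds/groups/days actually simulated
            self.treatment_effects = {
                (g, grp, d): v
                for (g, grp, d), v in _default_treatment_effects().items()
                if g < self.n_guilds and grp in self.group_names and d in self.days
            }
        if not (0 <= self.within_guild_corr < 1):
            raise ValueError("within_guild_corr must be in [0, 1)")
        for name in ("mouse_random_effect_sd", "latent_noise_sd", "noise_sd_glucose", "noise_sd_weight", "food_noise_sd", "water_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        if self.gamma_glucose is None:
            self.gamma_glucose = _default_glucose_gammas(self.n_guilds)
        if self.gamma_weight is None:
            self.gamma_weight = _default_weight_gammas(self.n_guilds)
        for name in ("gamma_glucose", "gamma_weight"):
            if len(getattr(self, name)) != self.n_guilds:
                raise ValueError(f"{name} must have one coefficient per guild")

    @property
    def group_names(self) -> tuple[str, ...]:
        if self.n_groups <= len(GROUP_NAMES):
            return GROUP_NAMES[: self.n_groups]
        return GROUP_NAMES + tuple(f"group{i}" for i in range(len(GROUP_NAMES), self.n_groups))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "days" in data:
            data["days"] = tuple(data["days"])
        if "library_size_range" in data:
            data["library_size_range"] = tuple(data["library_size_range"])
        for k in ("gamma_glucose", "gamma_weight"):
            if data.get(k) is not None:
                data[k] = tuple(data[k])
        if "treatment_effects" in data and data["treatment_effects"] is not None:
            data["treatment_effects"] = {
                (int(g), str(gr), int(d)): float(v)
                for (g, gr, d), v in (
                    ((e["guild"], e["group"], e["day"]), e["shift"]) for e in data["treatment_effects"]
                )
            }
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    guild_of: dict[str, int]  # asv id -> guild index
    guild_factors: np.ndarray  # n_guilds x n_samples latent factor draws
    gamma_glucose: tuple[float, ...]
    gamma_weight: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        guilds = set(self.guild_of.values())
        if guilds != set(range(len(guilds))):
            raise ValueError("guild map must partition ASVs into guilds 0..k-1")

    def partition_labels(self, feature_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.guild_of[f] for f in feature_ids])

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "seed": int(self.seed),
            "guild_of": {k: int(v) for k, v in self.guild_of.items()},
            "gamma_glucose": [float(x) for x in self.gamma_glucose],
            "gamma_weight": [float(x) for x in self.gamma_weight],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _asv_ids(n: int) -> list[str]:
    return [f"ASV_{i + 1:03d}" for i in range(n)]


def simulate_tree(n_asvs: int, seed: int = 0) -> PhyloTree:
    """Random rooted binary tree over ``n_asvs`` labelled leaves.

    Built by random sequential coalescence with exponential branch
    lengths; deterministic for a fixed seed.
    """
    if n_asvs < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in _asv_ids(n_asvs)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        left.length = float(rng.exponential(0.1)) + 1e-6
        right.length = float(rng.exponential(0.1)) + 1e-6
        nodes.append(parent)
    return PhyloTree(nodes[0])


def _sample_frame(cfg: SimConfig) -> tuple[list[str], list[str], list[str], list[int]]:
    sample_ids, mouse_ids, groups, days = [], [], [], []
    for group in cfg.group_names:
        for m in range(cfg.mice_per_group):
            mouse = f"{group}_m{m + 1:02d}"
            for day in cfg.days:
                sample_ids.append(f"{mouse}_d{day}")
                mouse_ids.append(mouse)
                groups.append(group)
                days.append(day)
    return sample_ids, mouse_ids, groups, days


def simulate_community(cfg: SimConfig) -> tuple[CountTable, SyntheticTruth]:
    """Draw a count table from the latent-factor softmax-multinomial model."""
    rng = np.random.default_rng(cfg.rng_seed)
    sample_ids, mouse_ids, groups, days = _sample_frame(cfg)
    n_samples = len(sample_ids)
    n = cfg.n_asvs

    guild_sizes = [len(a) for a in np.array_split(np.arange(n), cfg.n_guilds)]
    guild_idx = np.repeat(np.arange(cfg.n_guilds), guild_sizes)
    feature_ids = _asv_ids(n)
    guild_of = {f: int(g) for f, g in zip(feature_ids, guild_idx)}

    rho = cfg.within_guild_corr
    resid_var = cfg.mouse_random_effect_sd**2 + cfg.latent_noise_sd**2
    load = np.sqrt(rho / (1.0 - rho) * resid_var)

    base = rng.normal(0.0, cfg.base_abundance_sd, size=n)
    factors = rng.standard_normal((cfg.n_guilds, n_samples))

    lam = base[:, None] + load * factors[guild_idx, :]
    # treatment effects are additive shifts on the latent log-abundance of
    # every member of the guild, for samples in the given (group, day) cell
    for (guild, group, day), shift in cfg.treatment_effects.items():
        if not (0 <= guild < cfg.n_guilds):
            raise ValueError(f"treatment effect for unknown guild {guild}")
        cols = np.where([(g == group and d == day) for g, d in zip(groups, days)])[0]
        rows = np.where(guild_idx == guild)[0]
        lam[np.ix_(rows, cols)] += shift

    unique_mice = list(dict.fromkeys(mouse_ids))
    mouse_pos = {m: i for i, m in enumerate(unique_mice)}
    u = rng.normal(0.0, cfg.mouse_random_effect_sd, size=(n, len(unique_mice)))
    lam += u[:, [mouse_pos[m] for m in mouse_ids]]
    lam += rng.normal(0.0, cfg.latent_noise_sd, size=(n, n_samples))

    # softmax over ASVs per sample
    lam -= lam.max(axis=0, keepdims=True)
    p = np.exp(lam)
    p /= p.sum(axis=0, keepdims=True)

    lo, hi = cfg.library_size_range
    libs = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.empty((n_samples, n), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(libs[s], p[:, s])

    table = CountTable(sample_ids, feature_ids, counts)
    truth = SyntheticTruth(
        guild_of=guild_of,
        guild_factors=factors,
        gamma_glucose=tuple(cfg.gamma_glucose),
        gamma_weight=tuple(cfg.gamma_weight),
        seed=cfg.rng_seed,
    )
    return table, truth


# group-level intake baselines (g/day food, mL/day water): the first arm is
# the untreated control; treated arms span reduced to increased intake so
# that food consumption is the dominant phenotype driver, as in diabetic
# mice whose hyperphagia tracks disease progression.
_FOOD_BASE = {"control": 6.0, "GTE1": 4.8, "GTE2": 5.4, "GTP1": 7.2, "GTP2": 6.0}
_WATER_BASE = {"control": 14.0, "GTE1": 11.0, "GTE2": 12.5, "GTP1": 17.0, "GTP2": 14.0}


def _group_food_mean(group: str, day: int) -> float:
    return _FOOD_BASE.get(group, 6.0) + 0.01 * day


def _group_water_mean(group: str, day: int) -> float:
    return _WATER_BASE.get(group, 14.0) + 0.05 * day


def simulate_phenotypes(cfg: SimConfig, community: CountTable, truth: SyntheticTruth) -> list[SampleInfo]:
    """Couple food/water intake and host phenotypes to the community.

    Glucose and body weight are affine in food, water and the
    arcsine-square-root guild relative abundances, plus Gaussian noise;
    values are truncated at zero.
    """
    expected_ids, mouse_ids, groups, days = _sample_frame(cfg)
    if list(community.sample_ids) != expected_ids:
        raise ValueError("community sample ids do not match the configured design")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 0xF00D)))

    n_samples = community.n_samples
    rel = community.counts / community.counts.sum(axis=1, keepdims=True)
    guild_rel = np.zeros((n_samples, cfg.n_guilds))
    for j, f in enumerate(community.feature_ids):
        guild_rel[:, truth.guild_of[f]] += rel[:, j]
    guild_ast = np.arcsin(np.sqrt(np.clip(guild_rel, 0.0, 1.0)))

    food = np.array([_group_food_mean(g, d) for g, d in zip(groups, days)])
    food = np.maximum(food + rng.normal(0.0, cfg.food_noise_sd, n_samples), 0.0)
    water = np.array([_group_water_mean(g, d) for g, d in zip(groups, days)])
    water = np.maximum(water + rng.normal(0.0, cfg.water_noise_sd, n_samples), 0.0)

    glucose = (
        cfg.beta0_glucose
        + cfg.beta_food_glucose * food
        + cfg.beta_water_glucose * water
        + guild_ast @ np.asarray(cfg.gamma_glucose)
        + rng.normal(0.0, cfg.noise_sd_glucose, n_samples)
    )
    weight = (
        cfg.beta0_weight
        + cfg.beta_food_weight * food
        + cfg.beta_water_weight * water
        + guild_ast @ np.asarray(cfg.gamma_weight)
        + rng.normal(0.0, cfg.noise_sd_weight, n_samples)
    )
    glucose = np.maximum(glucose, 0.0)
    weight = np.maximum(weight, 0.0)

    return [
        SampleInfo(
            sample_id=sid,
            mouse_id=m,
            group=g,
            day=int(d),
            food=float(f),
            water=float(w),
            body_weight=float(bw),
            glucose=float(gl),
        )
        for sid, m, g, d, f, w, bw, gl in zip(expected_ids, mouse_ids, groups, days, food, water, weight, glucose)
    ]


def generate_dataset(
    cfg: SimConfig, out_dir: Optional[Union[str, Path]] = None
) -> tuple[CountTable, list[SampleInfo], PhyloTree, SyntheticTruth]:
    """Community + phenotypes + tree; optionally write all artifacts."""
    table, truth = simulate_community(cfg)
    samples = simulate_phenotypes(cfg, table, truth)
    # tree seed derived from the master seed, kept independent of the draw
    tree_seed = int(np.random.SeedSequence((cfg.rng_seed, 0x7BEE)).generate_state(1)[0] % 2**31)
    tree = simulate_tree(cfg.n_asvs, seed=tree_seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_table(table, out / "counts.tsv")
        write_metadata(samples, out / "metadata.tsv")
        write_tree(tree, out / "tree.nwk")
        truth.to_yaml(out / "truth.yaml")
    return table, samples, tree, truth
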