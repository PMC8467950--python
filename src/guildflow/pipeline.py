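"""One-command orchestration: simulate/load -> preprocess -> diversity ->
guilds -> associations -> phenotype prediction, with a reproducibility
manifest.

The run is configured by a YAML file with up to four blocks::

    seed: 42              # master seed
    simulate: {...}       # SimConfig fields, or instead
    inputs:               # paths to counts/metadata/tree
      counts: counts.tsv
      metadata: metadata.tsv
      tree: tree.nwk
    pipeline: {...}       # PipelineConfig fields
    predict:
      n_trees: 500
      cv: 5               # folds for feature-selection CV, or "loo"

The master seed is expanded into independent per-stage seeds via
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` so stages can be
re-run in isolation with identical results.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_frame, run_association
from .core_io import PipelineConfig, load_dataset, samples_to_frame, save_table
from .diversity import nmds, permanova, shannon, weighted_unifrac
from .guilds import coabundance_distance, delineate_guilds, ward_linkage
from .predict import rf_report
from .preprocess import (
    ast_transform,
    guild_abundance,
    prevalence_filter,
    rarefy,
    remove_spurious,
    to_relative,
)
from .synthetic_data import SimConfig, generate_dataset

__all__ = ["RunManifest", "run_all"]

log = logging.getLogger("guildflow")

_STAGES = ("simulate", "preprocess", "diversity", "guilds", "associate", "predict")
_TOP_KEYS = {"seed", "simulate", "inputs", "pipeline", "predict"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)  # relative path -> sha256
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(vars(self), sort_keys=False))


def _stage_seed(master: int, stage: str) -> int:
    i = _STAGES.index(stage)
    return int(np.random.SeedSequence(master, spawn_key=(i,)).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g")


def _load_config(config_path: Union[str, Path, dict]) -> dict:
    if isinstance(config_path, dict):
        cfg = dict(config_path)
    else:
        cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "simulate" in cfg and "inputs" in cfg:
        raise ValueError("config must give either a 'simulate' block or 'inputs', not both")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' block or an 'inputs' block")
    return cfg


def run_all(config_path: Union[str, Path, dict], out_dir: Union[str, Path]) -> RunManifest:
    """Execute every stage in order; abort on the first failing stage."""
    cfg = _load_config(config_path)
    seed = int(cfg.get("seed", 0))
    pipe = PipelineConfig(**(cfg.get("pipeline") or {}))
    predict_cfg = dict(cfg.get("predict") or {})
    n_trees = int(predict_cfg.pop("n_trees", 500))
    cv = predict_cfg.pop("cv", 5)
    if predict_cfg:
        raise ValueError(f"unknown predict options: {sorted(predict_cfg)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stage_seeds = {s: _stage_seed(seed, s) for s in _STAGES}
    manifest = RunManifest(
        config=cfg,
        seed=seed,
        stage_seeds=stage_seeds,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    stage = "simulate"
    try:
        log.info("config: %s", {k: v for k, v in cfg.items() if k != "simulate"})
        log.info("stage seeds: %s", stage_seeds)

        # -- simulate / load -------------------------------------------------
        if "simulate" in cfg:
            sim = SimConfig(**{**(cfg["simulate"] or {}), "rng_seed": stage_seeds["simulate"]})
            sim_dir = out / "simulate"
            counts, samples, tree, truth = generate_dataset(sim, out_dir=sim_dir)
            for f in ("counts.tsv", "metadata.tsv", "tree.nwk", "truth.yaml"):
                record(sim_dir / f)
            log.info("simulated %d samples x %d ASVs", counts.n_samples, counts.n_features)
        else:
            paths = cfg["inputs"]
            counts, samples, tree = load_dataset(
                paths["counts"], paths["metadata"], paths.get("tree"), transposed=bool(paths.get("transposed", False))
            )
            truth = None
            log.info("loaded %d samples x %d ASVs", counts.n_samples, counts.n_features)
        meta = samples_to_frame(samples)

        # -- preprocess -------------------------------------------------------
        stage = "preprocess"
        log.info("rarefying to %d reads/sample", pipe.rarefaction_depth)
        rare = rarefy(counts, pipe.rarefaction_depth, seed=stage_seeds["preprocess"])
        rare = remove_spurious(rare, pipe.spurious_min_mean_relabund)
        log.info("abundance filter (mean relabund >= %g): %d ASVs kept", pipe.spurious_min_mean_relabund, rare.n_features)
        prevalent = prevalence_filter(rare, pipe.prevalence_threshold)
        log.info("prevalence filter (> %.0f%% of samples): %d ASVs", 100 * pipe.prevalence_threshold, prevalent.n_features)
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        save_table(rare, pre_dir / "rarefied.tsv")
        save_table(prevalent, pre_dir / "prevalent.tsv")
        record(pre_dir / "rarefied.tsv")
        record(pre_dir / "prevalent.tsv")
        meta = meta.loc[rare.sample_ids]

        # -- diversity --------------------------------------------------------
        stage = "diversity"
        div_dir = out / "diversity"
        div_dir.mkdir(exist_ok=True)
        alpha = shannon(rare, pipe.shannon_log_base)
        _write(alpha.to_frame(), div_dir / "shannon.tsv")
        record(div_dir / "shannon.tsv")
        if tree is not None:
            beta = weighted_unifrac(rare, tree, pipe.unifrac_variant)
            save_table(beta, div_dir / "weighted_unifrac.tsv")
            record(div_dir / "weighted_unifrac.tsv")
            ord_res = nmds(beta, seed=stage_seeds["diversity"])
            _write(ord_res.coordinates, div_dir / "nmds.tsv")
            record(div_dir / "nmds.tsv")
            perm_by_day = {}
            for day, ids in meta.groupby("day").groups.items():
                ids = list(ids)
                res = permanova(
                    beta.submatrix(ids),
                    meta.loc[ids, "group"],
                    n_perm=pipe.n_permutations,
                    seed=stage_seeds["diversity"],
                )
                perm_by_day[int(day)] = {
                    "pseudo_f": float(res.pseudo_f),
                    "p_value": float(res.p_value),
                    "n_permutations": int(res.n_permutations),
                    "exhaustive": bool(res.exhaustive),
                }
            summary = {"nmds_stress": float(ord_res.stress), "permanova_group_by_day": perm_by_day}
            (div_dir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
            record(div_dir / "summary.yaml")
            log.info("nmds stress %.4f", ord_res.stress)
        else:
            log.info("no tree supplied; skipping UniFrac/NMDS/PERMANOVA")

        # -- guilds -----------------------------------------------------------
        stage = "guilds"
        guild_dir = out / "guilds"
        guild_dir.mkdir(exist_ok=True)
        rel = to_relative(prevalent)
        dist = coabundance_distance(rel, meta["mouse_id"].to_numpy())
        dendro = ward_linkage(dist)
        assignment = delineate_guilds(
            dendro,
            dist,
            n_perm=pipe.n_permutations,
            alpha=pipe.split_alpha,
            seed=stage_seeds["guilds"],
        )
        log.info("%d prevalent ASVs grouped into %d guilds", prevalent.n_features, assignment.n_guilds)
        _write(assignment.to_frame(), guild_dir / "guild_map.tsv")
        _write(assignment.splits_frame(), guild_dir / "splits.tsv")
        (guild_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        guild_rel = guild_abundance(rel, assignment)
        save_table(guild_rel, guild_dir / "guild_abundance.tsv")
        for f in ("guild_map.tsv", "splits.tsv", "dendrogram.nwk", "guild_abundance.tsv"):
            record(guild_dir / f)

        # -- associations -------------------------------------------------------
        stage = "associate"
        assoc_dir = out / "associate"
        assoc_dir.mkdir(exist_ok=True)
        # guild proportions may not total 1 after the prevalence subset;
        # AST expects proportions, so the raw fractions (of retained reads)
        # are used as-is — they already lie in [0, 1]
        from .core_io import AbundanceTable

        guild_prop = AbundanceTable(
            list(guild_rel.sample_ids),
            list(guild_rel.feature_ids),
            guild_rel.values / guild_rel.values.sum(axis=1, keepdims=True),
            scale="relative",
        )
        guild_ast = ast_transform(guild_prop)
        records = run_association(guild_ast, meta, q_threshold=pipe.q_threshold)
        assoc = association_frame(records)
        _write(assoc, assoc_dir / "associations.tsv")
        record(assoc_dir / "associations.tsv")
        n_sig = int(assoc["significant"].sum()) if len(assoc) else 0
        log.info("%d significant guild/term associations at q < %g", n_sig, pipe.q_threshold)

        # -- prediction ---------------------------------------------------------
        stage = "predict"
        pred_dir = out / "predict"
        pred_dir.mkdir(exist_ok=True)
        day = int(meta["day"].max())
        day_ids = list(meta.index[meta["day"] == day])
        X = guild_ast.select_samples(day_ids).to_frame()
        X["food"] = meta.loc[day_ids, "food"]
        X["water"] = meta.loc[day_ids, "water"]
        pred_summary = {}
        for phenotype in ("glucose", "body_weight"):
            y = meta.loc[day_ids, phenotype].to_numpy(float)
            rep = rf_report(X, y, cv=cv, seed=stage_seeds["predict"], n_trees=n_trees)
            _write(rep.importances.to_frame(), pred_dir / f"{phenotype}_importance.tsv")
            _write(rep.mse_curve.set_index("n_predictors"), pred_dir / f"{phenotype}_mse_curve.tsv")
            loo = pd.DataFrame({"measured": y, "predicted": rep.loo_predictions.to_numpy()}, index=day_ids)
            _write(loo, pred_dir / f"{phenotype}_loo.tsv")
            for f in (f"{phenotype}_importance.tsv", f"{phenotype}_mse_curve.tsv", f"{phenotype}_loo.tsv"):
                record(pred_dir / f)
            pred_summary[phenotype] = {
                "selected": rep.selected,
                "pearson_r": float(rep.pearson_r),
                "pearson_p": float(rep.pearson_p),
            }
            log.info("%s: %d predictors selected, LOO r=%.3f", phenotype, len(rep.selected), rep.pearson_r)
        (pred_dir / "summary.yaml").write_text(yaml.safe_dump(pred_summary, sort_keys=False))
        record(pred_dir / "summary.yaml")
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
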