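"""End-to-end orchestration: simulate -> normalize -> epistasis -> classify
-> phenotype, with a single YAML-loadable configuration, TSV outputs and a
run manifest. Deterministic given the seed: rerunning with the same config
writes byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .core import InducerLevel
from .simulate import (
    Interaction,
    PlateLayoutConfig,
    SimulationConfig,
    generate_dataset,
    generate_raw_plates,
)
from . import plates as plate_norm
from .epistasis import epistasis_table, log_fold_changes
from .classify import (
    category_census,
    inducer_dependence,
    summarize_by_genotype,
    type_class_table,
)
from .phenotype import (
    class_census,
    distance_and_diversity,
    expected_points,
    observed_points,
)

logger = logging.getLogger(__name__)


class LevelSpec(BaseModel):
    label: str
    pct: float = Field(ge=0)


class InteractionSpec(BaseModel):
    genotype: str
    level: str
    delta: float


class PipelineConfig(BaseModel):
    """All tunables of a run; defaults reproduce the assay design
    (M = 10 mutants per node, triplicates, 0 / 0.0002 / 0.2 % arabinose)."""

    mutants_per_node: int = Field(default=10, ge=1)
    n_replicates: int = Field(default=3, ge=2)
    replicate_cv: float = Field(default=0.10, ge=0)
    levels: list[LevelSpec] = Field(
        default_factory=lambda: [
            LevelSpec(label="low", pct=0.0),
            LevelSpec(label="medium", pct=0.0002),
            LevelSpec(label="high", pct=0.2),
        ]
    )
    mode: Literal[
        "mechanistic", "multiplicative_null", "multiplicative_plus_interactions"
    ] = "mechanistic"
    input_stage: Literal["raw", "tidy"] = "tidy"
    interactions: list[InteractionSpec] = Field(default_factory=list)
    sigma_mode: Literal["as_printed", "sum_of_variances"] = "as_printed"
    fdr_method_epistasis: Literal["storey", "bh", "bky"] = "storey"
    alpha_epistasis: float = Field(default=0.05, gt=0, lt=1)
    fdr_method_dependence: Literal["storey", "bh", "bky"] = "bky"
    alpha_dependence: float = Field(default=0.1, gt=0, lt=1)
    flat_radius: float = Field(default=0.0, ge=0)
    seed: int = 0

    @field_validator("levels")
    @classmethod
    def _three_levels(cls, v: list[LevelSpec]) -> list[LevelSpec]:
        labels = [lvl.label for lvl in v]
        if sorted(labels) != sorted(["low", "medium", "high"]):
            raise ValueError("levels must be exactly low/medium/high")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            mutants_per_node=self.mutants_per_node,
            n_replicates=self.n_replicates,
            replicate_cv=self.replicate_cv,
            levels=tuple(
                InducerLevel(lvl.label, lvl.pct)
                for lvl in sorted(self.levels, key=lambda l: l.pct)
            ),
            interactions=tuple(
                Interaction(i.genotype, i.level, i.delta) for i in self.interactions
            ),
        )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline and write every table under ``outdir``.

    Stages run in order; a failing stage aborts with a stage-named error and
    earlier outputs are retained on disk. Returns the in-memory tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation_config()
    results: dict = {}

    # -- simulate -----------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        if config.input_stage == "raw":
            raw = generate_raw_plates(sim_cfg, seed=config.seed, mode=config.mode)
            _write(raw, out / "raw_plates.tsv")
            return raw, None
        ds = generate_dataset(sim_cfg, mode=config.mode, seed=config.seed)
        _write(ds.data, out / "simulated_data.tsv")
        _write(ds.truth, out / "ground_truth.tsv")
        return None, ds

    raw, ds = _simulate()
    results["dataset"] = ds

    # -- normalize ----------------------------------------------------------
    @_stage("normalize")
    def _normalize():
        if raw is not None:
            timepoint = plate_norm.select_timepoint_from_plates(raw)
            wells = plate_norm.correct_and_normalize(raw, timepoint)
            kept, qc = plate_norm.qc_filter(wells)
            tidy = plate_norm.to_tidy(kept)
            _write(qc.excluded, out / "qc_excluded.tsv")
            _write(qc.surviving_n, out / "qc_surviving_n.tsv")
        else:
            tidy = ds.data
        if "WT" not in set(tidy["genotype"]):
            raise ValueError("wild-type genotype absent from input table")
        summary = plate_norm.summarize(tidy)
        _write(summary, out / "expression_summary.tsv")
        return tidy, summary

    tidy, summary = _normalize()
    results["summary"] = summary

    # -- epistasis ----------------------------------------------------------
    @_stage("epistasis")
    def _epistasis():
        lfc = log_fold_changes(tidy)
        records = epistasis_table(
            lfc,
            sigma_mode=config.sigma_mode,
            fdr_method=config.fdr_method_epistasis,
            alpha=config.alpha_epistasis,
            n_replicates=config.n_replicates,
        )
        _write(lfc, out / "log_fold_changes.tsv")
        _write(records, out / "epistasis.tsv")
        return lfc, records

    lfc, records = _epistasis()
    results["lfc"], results["records"] = lfc, records

    # -- classify -----------------------------------------------------------
    @_stage("classify")
    def _classify():
        types = type_class_table(records, lfc, significant_only=True)
        profiles = inducer_dependence(
            records,
            alpha=config.alpha_dependence,
            sigma_mode=config.sigma_mode,
            n_replicates=config.n_replicates,
            fdr_method=config.fdr_method_dependence,
        )
        census = category_census(profiles)
        gsum = summarize_by_genotype(records, grouping="genotype")
        _write(types, out / "type_classes.tsv")
        _write(profiles, out / "inducer_profiles.tsv")
        _write(census, out / "category_census.tsv")
        _write(gsum, out / "genotype_summaries.tsv")
        return types, profiles, census, gsum

    types, profiles, census, gsum = _classify()
    results.update(types=types, profiles=profiles, census=census, gsum=gsum)

    # -- phenotype ----------------------------------------------------------
    @_stage("phenotype")
    def _phenotype():
        obs = observed_points(summary, flat_radius=config.flat_radius)
        exp = expected_points(summary, lfc, flat_radius=config.flat_radius)
        wt_row = obs[obs["genotype"] == "WT"].iloc[0]
        wt_point = (wt_row["Mx"], wt_row["My"])
        points = pd.concat([obs, exp], ignore_index=True)
        points["dist_to_wt"] = (
            (points["Mx"] - wt_point[0]) ** 2 + (points["My"] - wt_point[1]) ** 2
        ) ** 0.5
        _write(points, out / "phenotypes.tsv")
        _write(class_census(points), out / "phenotype_census.tsv")
        diversity = {}
        combo_obs = obs[obs["genotype"] != "WT"]
        for order, label in ((2, "pairwise"), (3, "triplet")):
            sel_obs = combo_obs[
                combo_obs["genotype"].map(lambda s: s.count("+") + 1) == order
            ]
            sel_exp = exp[exp["genotype"].isin(sel_obs["genotype"])]
            if sel_obs.empty:
                continue
            dist_table, div = distance_and_diversity(sel_obs, sel_exp, wt_point)
            _write(dist_table, out / f"distances_{label}.tsv")
            diversity[label] = div
        return points, diversity

    points, diversity = _phenotype()
    results["points"], results["diversity"] = points, diversity

    # -- manifest -----------------------------------------------------------
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = {
        "package": "stripenet",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "diversity": diversity,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d tables in %s", len(manifest["outputs"]), out)
    return results
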