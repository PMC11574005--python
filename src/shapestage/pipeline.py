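"""End-to-end staging pipeline: simulate -> thickness -> per-stage maps ->
spin similarity -> stage classifiers, from a single YAML-able config.

The pipeline mirrors the analysis sequence of a staging study: per-HY-stage
case-control effect maps against age/sex-matched controls, clinical
correlation maps, spin-permutation similarity between consecutive stage
maps, and binary plus ordinal structured-sparsity classification.  Every
random draw traces to a child seed spawned deterministically from the master
seed, so re-running a config reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import default_lambda_grid, nested_cv
from .cohort import (
    ThicknessMatrix,
    default_effect_spec,
    group_stages,
    match_controls,
    simulate_cohort,
    simulate_thickness,
)
from .errors import ConfigError
from .io import (
    FLOAT_FMT,
    write_cohort,
    write_effect_map,
    write_json,
    write_thickness,
)
from .massuni import DesignSpec, map_effects, searchlight_fdr, summarize_map
from .mesh import DEFAULT_ATLAS_CONFIG, MeshAtlas, build_atlas
from .spin import spin_test

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "DEMO_CONFIG"]


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-serializable."""

    atlas_config: list[dict] | None = None  # None -> full default atlas
    n_per_group: dict = field(
        default_factory=lambda: {"control": 160, 1: 60, 2: 60, 3: 60, 4: 30, 5: 30}
    )
    n_cohorts: int = 5
    stage_contrasts: bool = True  # HY stage vs matched controls maps
    clinical_correlations: tuple[str, ...] = ()  # e.g. ("time_since_diagnosis",)
    spin_pairs: str = "consecutive"  # consecutive stage-map pairs
    spin_structures: tuple[str, ...] = ()  # () -> all structures
    classification_tasks: tuple[str, ...] = (
        "pd_vs_control",
        "hy1_vs_hy2",
        "hy2_vs_hy345",
        "ordinal",
    )
    q: float = 0.05
    fdr_radius: int | None = 5
    n_rotations: int = 300
    outer_k: int = 4
    inner_k: int = 4
    lambda_grid: list | None = None  # None -> default 5x5 log grid
    match_ratio: int = 2
    null_structures: tuple[str, ...] = ()  # structures left without effects
    seed: int = 0
    fit_kwargs: dict = field(default_factory=lambda: {"max_iter": 200, "tol": 1e-7})

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ConfigError("q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys {sorted(bad)}")
        if "n_per_group" in raw:
            raw["n_per_group"] = {
                (k if k == "control" else float(k)): v
                for k, v in raw["n_per_group"].items()
            }
        for tup in ("clinical_correlations", "classification_tasks", "spin_structures", "null_structures"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


#: A small demonstration configuration: full 14-structure layout at reduced
#: mesh resolution, moderate group sizes — the planted staging effects are
#: detectable in minutes on one CPU.
def _demo_atlas_config() -> list[dict]:
    cfg = []
    for entry in DEFAULT_ATLAS_CONFIG:
        e = dict(entry)
        e["rings"], e["cols"] = 6, 8  # 50 vertices per structure
        cfg.append(e)
    return cfg


DEMO_CONFIG = PipelineConfig(
    atlas_config=_demo_atlas_config(),
    n_per_group={"control": 120, 1: 40, 2: 40, 3: 30, 4: 15, 5: 15},
    n_rotations=150,
    inner_k=2,
    lambda_grid=[(0.5, 0.5), (4.0, 4.0)],
    null_structures=("pallidum",),
    fit_kwargs={"max_iter": 150, "tol": 1e-7},
)


def _child_seed(master: int, label: str) -> int:
    """Named, stable child seed derived from the master seed (< 2**31)."""
    import zlib

    h = np.random.SeedSequence([master, zlib.crc32(label.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def validate_inputs(
    thickness: ThicknessMatrix, cohort: pd.DataFrame, atlas: MeshAtlas
) -> list[dict]:
    """Machine-readable diagnostics; issues are data, not exceptions."""
    issues: list[dict] = []
    if thickness.n_vertices != atlas.n_vertices:
        issues.append(
            {
                "kind": "vertex_count",
                "detail": f"thickness has {thickness.n_vertices} columns, atlas {atlas.n_vertices}",
            }
        )
    if thickness.n_subjects != len(cohort) or not np.array_equal(
        thickness.subject_ids, cohort["subject_id"].to_numpy()
    ):
        issues.append({"kind": "subject_alignment", "detail": "row order mismatch"})
    if (cohort["age"] <= 0).any():
        issues.append({"kind": "covariate_range", "detail": "non-positive age"})
    if (cohort["icv"] <= 0).any():
        issues.append({"kind": "covariate_range", "detail": "non-positive ICV"})
    moca = cohort["moca"].dropna()
    if ((moca < 0) | (moca > 30)).any():
        issues.append({"kind": "covariate_range", "detail": "MoCA outside [0, 30]"})
    stages = cohort.loc[cohort["group"] == "PD", "hy_stage"].dropna()
    bad = set(stages) - {1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0}
    if bad:
        issues.append({"kind": "stage_validity", "detail": f"invalid stages {sorted(bad)}"})
    if cohort.loc[cohort["group"] == "control", "hy_stage"].notna().any():
        issues.append({"kind": "stage_validity", "detail": "controls carry HY stages"})
    return issues


def _stage_mass_univariate(cfg, atlas, cohort, thickness, outdir, manifest):
    """Per-HY-stage case-control maps with matched controls."""
    controls = cohort[cohort["group"] == "control"]
    pd_rows = cohort[cohort["group"] == "PD"].copy()
    pd_rows["analysis_stage"] = group_stages(pd_rows["hy_stage"], "HY45")
    maps = {}
    for stage in ["1", "2", "3", "45"]:
        cases = pd_rows[pd_rows["analysis_stage"] == stage]
        if len(cases) == 0:
            continue
        matched = match_controls(
            cases,
            controls,
            ratio=cfg.match_ratio,
            seed=_child_seed(cfg.seed, f"match-{stage}"),
        )
        sub = pd.concat([cases.drop(columns="analysis_stage"), matched.drop(columns="matched_case_id")])
        sub = sub.sort_values("subject_id").reset_index(drop=True)
        sub["is_pd"] = (sub["group"] == "PD").astype(int)
        idx = {s: i for i, s in enumerate(thickness.subject_ids)}
        rows = np.array([idx[s] for s in sub["subject_id"]])
        tm = ThicknessMatrix(thickness.values[rows], sub["subject_id"].to_numpy())
        design = DesignSpec(predictor="is_pd")
        emap = map_effects(tm, design, sub)
        emap.sig_mask = searchlight_fdr(emap.p, atlas.adjacency, cfg.fdr_radius, cfg.q)
        emap.q_level = cfg.q
        write_effect_map(emap, outdir / f"effectmap_hy{stage}.tsv")
        summary = summarize_map(emap, atlas)
        summary.to_csv(outdir / f"summary_hy{stage}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        manifest["analyses"].append(
            {"stage": stage, "n_cases": int(len(cases)), "n_controls": int(len(matched))}
        )
        maps[stage] = emap
    return maps


def _clinical_maps(cfg, atlas, cohort, thickness, outdir, manifest):
    pd_mask = (cohort["group"] == "PD").to_numpy()
    sub = cohort[pd_mask].reset_index(drop=True)
    tm = ThicknessMatrix(thickness.values[pd_mask], sub["subject_id"].to_numpy())
    for var in cfg.clinical_correlations:
        if var not in cohort.columns:
            raise ConfigError(f"unknown clinical variable {var!r}")
        design = DesignSpec(predictor=var)
        emap = map_effects(tm, design, sub)
        emap.sig_mask = searchlight_fdr(emap.p, atlas.adjacency, cfg.fdr_radius, cfg.q)
        emap.q_level = cfg.q
        write_effect_map(emap, outdir / f"effectmap_{var}.tsv")
        summarize_map(emap, atlas).to_csv(
            outdir / f"summary_{var}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        manifest["analyses"].append({"clinical": var, "n": int(pd_mask.sum())})


def _spin_similarity(cfg, atlas, maps, outdir, manifest):
    pairs = [("1", "2"), ("2", "3"), ("3", "45")]
    keys = list(cfg.spin_structures) or atlas.structure_keys
    results = {}
    for a, b in pairs:
        if a not in maps or b not in maps:
            continue
        for key in keys:
            sl = atlas.structure_slice(key)
            map_a = maps[a].beta[sl]
            map_b = maps[b].beta[sl]
            res = spin_test(
                map_a,
                map_b,
                atlas.sphere_for(key),
                n_rotations=cfg.n_rotations,
                seed=_child_seed(cfg.seed, f"spin-{a}-{b}-{key}"),
            )
            results[f"hy{a}_vs_hy{b}/{key}"] = {
                "r_obs": res.r_obs,
                "p": res.p,
                "n_rotations": res.n_rotations,
                "seed": res.seed,
            }
    write_json(results, outdir / "spin_results.json")
    manifest["analyses"].append({"spin_pairs": len(results)})
    return results


def _classification(cfg, atlas, cohort, thickness, outdir, manifest):
    grid = cfg.lambda_grid or default_lambda_grid()
    grid = [tuple(g) for g in grid]
    pd_mask = (cohort["group"] == "PD").to_numpy()
    stages = np.full(len(cohort), "", dtype=object)
    stages[pd_mask] = group_stages(cohort.loc[pd_mask, "hy_stage"], "HY345")
    reports = {}
    for task in cfg.classification_tasks:
        if task == "pd_vs_control":
            mask = np.ones(len(cohort), dtype=bool)
            y = np.where(pd_mask, "PD", "control")
        elif task == "hy1_vs_hy2":
            mask = np.isin(stages, ["1", "2"])
            y = stages
        elif task == "hy2_vs_hy345":
            mask = np.isin(stages, ["2", "345"])
            y = stages
        elif task == "ordinal":
            mask = np.isin(stages, ["1", "2", "345"])
            y = np.select(
                [stages == "1", stages == "2", stages == "345"], [1, 2, 3], default=0
            )
        else:
            raise ConfigError(f"unknown classification task {task!r}")
        ordinal = task == "ordinal"
        rep = nested_cv(
            thickness.values[mask],
            np.asarray(y)[mask],
            grid,
            atlas.adjacency,
            outer_k=cfg.outer_k,
            inner_k=cfg.inner_k,
            metric="balanced_f1" if ordinal else "roc_auc",
            seed=_child_seed(cfg.seed, f"cv-{task}"),
            ordinal=ordinal,
            fit_kwargs=cfg.fit_kwargs,
        )
        reports[task] = {
            "metric": rep.metric,
            "fold_metrics": rep.fold_metrics,
            "mean_metric": rep.mean_metric,
            "selected_lambdas": [list(s) for s in rep.selected],
            "seed": rep.seed,
        }
    write_json(reports, outdir / "classification.json")
    manifest["analyses"].append({"classification_tasks": list(reports)})
    return reports


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full analysis; returns the report directory.

    Any stage failure aborts with the failing stage named; partial outputs
    are kept next to a ``FAILED`` marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "child_seeds": {},
        "analyses": [],
    }
    stage = "setup"
    try:
        stage = "atlas"
        atlas = build_atlas(config.atlas_config, seed=_child_seed(config.seed, "atlas"))
        stage = "simulate"
        cohort = simulate_cohort(
            config.n_per_group,
            n_cohorts=config.n_cohorts,
            seed=_child_seed(config.seed, "cohort"),
        )
        write_cohort(cohort, outdir / "cohort.csv")
        spec = default_effect_spec(atlas, tuple(config.null_structures))
        thickness = simulate_thickness(
            atlas, cohort, spec, seed=_child_seed(config.seed, "thickness")
        )
        write_thickness(thickness, outdir / "thickness.tsv", atlas)
        stage = "validate"
        issues = validate_inputs(thickness, cohort, atlas)
        write_json(issues, outdir / "validation.json")
        if issues:
            logger.warning("validation issues: %s", issues)
        maps = {}
        if config.stage_contrasts:
            stage = "mass-univariate"
            maps = _stage_mass_univariate(config, atlas, cohort, thickness, outdir, manifest)
        if config.clinical_correlations:
            stage = "clinical-correlations"
            _clinical_maps(config, atlas, cohort, thickness, outdir, manifest)
        if maps and config.spin_pairs:
            stage = "spin"
            _spin_similarity(config, atlas, maps, outdir, manifest)
        if config.classification_tasks:
            stage = "classification"
            _classification(config, atlas, cohort, thickness, outdir, manifest)
        stage = "manifest"
        manifest["child_seeds"] = {
            name: _child_seed(config.seed, name)
            for name in ["atlas", "cohort", "thickness"]
        }
        write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir
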