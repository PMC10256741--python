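"""Pipeline orchestration: simulate -> features -> classify -> gradients ->
asymmetry -> ancova -> heritability, chained through documented TSV files so
any stage can be re-run in isolation and reproduces its outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, gradients, heritability, metrics, stats
from .cohort import CohortConfig, GroupEffect, PedigreeSpec, simulate_cohort, write_cohort
from .datamodel import (
    config_hash,
    read_atlas,
    read_covariates,
    read_pedigree,
    read_timeseries,
    write_results,
)
from .gradients import GradientConfig

log = logging.getLogger("latgrad")

STAGES = ("simulate", "features", "classify", "gradients", "asymmetry", "ancova", "heritability")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    k: int = 3
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_boot: int = 100
    n_tests: int = 7
    threads: int = 1

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort_d = dict(d.pop("cohort", {}))
        if "beta_effects" in cohort_d:
            cohort_d["beta_effects"] = {
                g: GroupEffect(**v) if isinstance(v, dict) else v
                for g, v in cohort_d["beta_effects"].items()
            }
        if cohort_d.get("pedigree") is not None:
            ped = cohort_d["pedigree"]
            cohort_d["pedigree"] = PedigreeSpec(**ped) if isinstance(ped, dict) else ped
        if "group_proportions" in cohort_d:
            cohort_d["group_proportions"] = tuple(cohort_d["group_proportions"])
        if cohort_d.get("inject_groups") is not None:
            cohort_d["inject_groups"] = tuple(cohort_d["inject_groups"])
        grad_d = dict(d.pop("gradient", {}))
        if "scale_range" in grad_d:
            grad_d["scale_range"] = tuple(grad_d["scale_range"])
        known = {"seed", "k", "k_range", "n_boot", "n_tests", "threads"}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(cohort=CohortConfig(**cohort_d), gradient=GradientConfig(**grad_d), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing input {path.name!r}: run the {produced_by!r} stage first"
        )
    return path


def _load_connectivity(out: Path):
    """Read the cohort from disk and build each subject's whole-cortex
    connectivity matrix (scan-averaged in Fisher z)."""
    cohort_dir = _require(out / "cohort", "simulate")
    atlas = read_atlas(_require(cohort_dir / "atlas.tsv", "simulate"))
    ts_dir = _require(cohort_dir / "timeseries", "simulate")
    betas = pd.read_csv(_require(cohort_dir / "betas.tsv", "simulate"), sep="\t",
                        dtype={"subject_id": str})
    subject_ids = list(dict.fromkeys(betas["subject_id"]))
    conns = []
    for sid in subject_ids:
        scans = []
        k = 0
        while (ts_dir / f"{sid}_scan{k}.tsv").exists():
            scans.append(read_timeseries(ts_dir / f"{sid}_scan{k}.tsv", atlas))
            k += 1
        if not scans:
            raise PipelineError(f"no time-series files for subject {sid}")
        conns.append(metrics.build_connectivity(scans))
    return atlas, subject_ids, conns, betas


def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    bundle = simulate_cohort(config.cohort)
    write_cohort(bundle, out / "cohort")
    return {"n_subjects": len(bundle.subjects)}


def stage_features(config: PipelineConfig, out: Path) -> dict:
    atlas, subject_ids, conns, betas = _load_connectivity(out)
    rows = []
    for sid, conn in zip(subject_ids, conns):
        sub = betas[betas["subject_id"] == sid]
        order = [atlas.position(int(r)) for r in sub["region_id"]]
        b = np.empty(atlas.n_regions)
        b[order] = sub["beta"].to_numpy(dtype=float)
        s_sum, s_asym = metrics.strength_metrics(conn, atlas)
        rows.append(
            {
                "subject_id": sid,
                "beta_network_asym": metrics.task_asymmetry(b, atlas, "network"),
                "beta_hubs_asym": metrics.task_asymmetry(b, atlas, "hubs"),
                "interhemi_rz": metrics.homotopic_connectivity(conn, atlas),
                "strength_sum": s_sum,
                "strength_asym": s_asym,
            }
        )
    df = pd.DataFrame(rows)
    write_results({"features": df}, out, config.to_dict(), manifest_name="manifest_features.json")
    return {"n_subjects": len(df)}


def stage_classify(config: PipelineConfig, out: Path) -> dict:
    feats = pd.read_csv(_require(out / "features.tsv", "features"), sep="\t",
                        dtype={"subject_id": str})
    std = clustering.standardize_features(feats[list(metrics.FEATURE_NAMES)])
    result = clustering.ward_cluster(std, config.k)
    if config.k == 3:
        result = clustering.label_groups(result, feats)
        names = result.named_labels()
    else:
        names = np.array([f"cluster{c}" for c in result.labels], dtype=object)
    labels = pd.DataFrame(
        {"subject_id": feats["subject_id"], "cluster": result.labels, "group_name": names}
    )
    stability = clustering.cluster_stability(
        std, k_range=config.k_range, n_boot=config.n_boot, seed=config.seed
    )
    write_results({"labels": labels, "stability": stability}, out, config.to_dict(),
                  manifest_name="manifest_classify.json")
    return {"k": config.k}


def stage_gradients(config: PipelineConfig, out: Path) -> dict:
    atlas, subject_ids, conns, _ = _load_connectivity(out)
    ref = gradients.serial_position_reference(atlas)
    gsets, template = gradients.embed_cohort(
        [c.values for c in conns], config.gradient, sign_reference=ref
    )
    k = config.gradient.n_components
    cols = [f"g{j + 1}" for j in range(k)]
    frames = []
    for sid, gs in zip(subject_ids, gsets):
        df = pd.DataFrame(gs.values, columns=cols)
        df.insert(0, "region_id", atlas.region_ids)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    grad_df = pd.concat(frames, ignore_index=True)
    tmpl_df = pd.DataFrame(template.values, columns=cols)
    tmpl_df.insert(0, "region_id", atlas.region_ids)
    info = pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "eigenvalue": template.eigenvalues,
            "variance_explained": template.variance_explained,
        }
    )
    write_results(
        {"gradients": grad_df, "gradient_template": tmpl_df, "gradient_info": info},
        out, config.to_dict(), manifest_name="manifest_gradients.json",
    )
    return {"variance_explained": template.variance_explained.tolist()}


def stage_asymmetry(config: PipelineConfig, out: Path) -> dict:
    atlas = read_atlas(_require(out / "cohort" / "atlas.tsv", "simulate"))
    grad_df = pd.read_csv(_require(out / "gradients.tsv", "gradients"), sep="\t",
                          dtype={"subject_id": str})
    cols = [c for c in grad_df.columns if c.startswith("g")]
    frames = []
    for sid, sub in grad_df.groupby("subject_id", sort=False):
        order = [atlas.position(int(r)) for r in sub["region_id"]]
        V = np.empty((atlas.n_regions, len(cols)))
        V[order, :] = sub[cols].to_numpy(dtype=float)
        df = gradients.network_gradient_asymmetry(V, atlas)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    asym = pd.concat(frames, ignore_index=True)
    write_results({"network_asymmetry": asym}, out, config.to_dict(),
                  manifest_name="manifest_asymmetry.json")
    return {"rows": len(asym)}


def _load_labels_covariates(out: Path):
    labels = pd.read_csv(_require(out / "labels.tsv", "classify"), sep="\t",
                         dtype={"subject_id": str})
    cov = read_covariates(_require(out / "cohort" / "covariates.tsv", "simulate")).table
    return labels, cov


def stage_ancova(config: PipelineConfig, out: Path) -> dict:
    feats = pd.read_csv(_require(out / "features.tsv", "features"), sep="\t",
                        dtype={"subject_id": str})
    asym = pd.read_csv(_require(out / "network_asymmetry.tsv", "asymmetry"), sep="\t",
                       dtype={"subject_id": str})
    labels, cov = _load_labels_covariates(out)
    merged = feats.merge(labels, on="subject_id").merge(cov, on="subject_id")
    groups = merged["group_name"].to_numpy(dtype=object)
    main, posthoc = stats.feature_group_stats(
        merged[["subject_id", *metrics.FEATURE_NAMES]], groups, merged
    )
    typicality = labels[["subject_id"]].copy()
    typicality["typicality"] = np.where(
        labels["group_name"] == "atypical", "atypical", "typical"
    )
    grid = stats.gradient_grid_stats(asym, typicality, cov, n_tests=config.n_tests)
    write_results(
        {"ancova_features": main, "ancova_posthoc": posthoc, "ancova_gradients": grid},
        out, config.to_dict(), manifest_name="manifest_ancova.json",
    )
    return {"n_grid_cells": len(grid)}


def stage_heritability(config: PipelineConfig, out: Path) -> dict:
    labels, cov = _load_labels_covariates(out)
    asym = pd.read_csv(_require(out / "network_asymmetry.tsv", "asymmetry"), sep="\t",
                       dtype={"subject_id": str})
    pedigree = read_pedigree(_require(out / "cohort" / "pedigree.tsv", "simulate"))
    order = pd.Index(pedigree.subject_ids)
    traits = pd.DataFrame(index=order)
    traits["atypical_phenotype"] = (
        labels.set_index("subject_id")["group_name"].reindex(order) == "atypical"
    ).astype(float)
    wide = asym.pivot_table(
        index="subject_id", columns=["gradient", "network"], values="asymmetry"
    ).reindex(order)
    grads = sorted({g for g, _ in wide.columns})
    for g in grads:
        traits[f"gradient{g}_asymmetry"] = wide[g].mean(axis=1)
        for net in wide[g].columns:
            traits[f"gradient{g}_{net}"] = wide[(g, net)]
    covi = cov.set_index("subject_id").reindex(order)
    X = covi[
        ["age", "sex_female", "age2", "age_x_sex", "age2_x_sex", "is_left_handed",
         "intracranial_volume"]
    ].to_numpy(dtype=float)
    kin = heritability.kinship_matrix(pedigree)
    eig = heritability.eigendecompose(kin)
    table = heritability.heritability_table(traits, X, eig, n_tests=config.n_tests)
    write_results({"heritability": table}, out, config.to_dict(),
                  manifest_name="manifest_heritability.json")
    return {"n_traits": len(table)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "classify": stage_classify,
    "gradients": stage_gradients,
    "asymmetry": stage_asymmetry,
    "ancova": stage_ancova,
    "heritability": stage_heritability,
}


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested stages in dependency order and write a run manifest
    (per-stage timings, seeds, config hash)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}")
    ordered = [s for s in STAGES if s in stages]
    manifest = {"config_hash": config_hash(config.to_dict()), "seed": config.seed, "stages": {}}
    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage=%s status=start seed=%d", stage, config.seed)
        info = _STAGE_FUNCS[stage](config, out)
        dt = time.perf_counter() - t0
        log.info("stage=%s status=done elapsed=%.2fs", stage, dt)
        manifest["stages"][stage] = {"elapsed_s": round(dt, 3), **info}
    with open(out / "pipeline_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
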