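"""End-to-end orchestration: generate -> harmonize -> normative model ->
deviations -> deviation statistics -> subtyping -> stability validation.

A single :class:`PipelineConfig` (loadable from YAML) drives the run; all
randomness descends from one root seed split per stage.  Outputs are
written as TSV/JSON files under a run directory together with a manifest
recording the config snapshot, per-stage wall-clock, and output checksums.
Stages whose inputs are unchanged (same checksum recorded in a previous
manifest) are reused rather than recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combat, devstats, normative, subtyping
from .synthetic import (
    CohortConfig,
    generate_hc_cohort,
    generate_mdd_cohort,
    generate_region_specs,
    region_network_map,
    write_cohort,
    write_features,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "rehonorm_run"
    seed: int = 0
    # generator
    n_hc: int = 200
    n_mdd: int = 220
    n_sites: int = 6
    n_regions: int = 246
    noise_sd: float = 0.10
    site_location_sd: float = 0.05
    site_scale_range: tuple[float, float] = (0.8, 1.25)
    subtype_proportions: tuple[float, float] = (0.36, 0.64)
    # stage toggles
    harmonize: bool = True
    protect_diagnosis: bool = False
    # normative model
    cv_folds: int = 10
    gpr_restarts: int = 1
    extreme_threshold: float = 2.6
    # subtyping
    k_range: tuple[int, int] = (2, 8)
    kmeans_restarts: int = 50
    min_site_n_patients: int = 30
    run_k_selection: bool = True
    run_validation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("site_scale_range", "subtype_proportions", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    reused_stages: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(root_seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def load_feature_table(
    feature_path, phenotype_path, n_regions: int = 246
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Real-data ingestion: regional feature TSV + phenotype TSV.

    Validates the region column count, rejects duplicated subject ids and
    non-numeric cells, and drops (with a log message) subjects missing
    age or sex.
    """
    features = pd.read_csv(feature_path, sep="\t", index_col="subject_id")
    if features.shape[1] != n_regions:
        raise ValueError(
            f"expected {n_regions} region columns, found {features.shape[1]}"
        )
    if features.index.duplicated().any():
        dupes = features.index[features.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated subject_id values: {dupes[:5]}")
    try:
        features = features.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric feature cells: {exc}") from exc

    pheno = pd.read_csv(phenotype_path, sep="\t")
    if "subject_id" not in pheno.columns:
        raise ValueError("phenotype table needs a subject_id column")
    if pheno["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in phenotype table")
    pheno = pheno.set_index("subject_id")
    missing = pheno["age"].isna() | pheno["sex"].isna()
    if missing.any():
        log.info("dropping %d subjects with missing demographics", int(missing.sum()))
        pheno = pheno[~missing]
    common = features.index.intersection(pheno.index)
    return features.loc[common], pheno.loc[common].reset_index()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [
        "generate", "harmonize", "normative", "deviations",
        "devstats", "subtype", "validate",
    ]
    seeds = _stage_seeds(config.seed, stages)
    manifest = RunManifest(
        config=config.to_dict(), package_version=_version(), stage_seeds=seeds
    )
    prev = _load_previous_manifest(out)

    def finish(stage: str, t0: float, files: dict[str, Path]) -> None:
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        for name, path in files.items():
            manifest.checksums[name] = _checksum(path)

    # ---- generate -------------------------------------------------------
    t0 = time.perf_counter()
    cohort_cfg = CohortConfig(
        n_hc=config.n_hc,
        n_mdd=config.n_mdd,
        n_sites=config.n_sites,
        noise_sd=config.noise_sd,
        site_location_sd=config.site_location_sd,
        site_scale_range=config.site_scale_range,
        subtype_proportions=config.subtype_proportions,
        seed=seeds["generate"],
    )
    regions = generate_region_specs(seed=seeds["generate"], n_regions=config.n_regions)
    hc_cohort, hc_feat = generate_hc_cohort(cohort_cfg, regions)
    mdd_cohort, mdd_feat = generate_mdd_cohort(cohort_cfg, regions)
    net_map = region_network_map(regions)
    files = {
        "hc_cohort.tsv": out / "hc_cohort.tsv",
        "mdd_cohort.tsv": out / "mdd_cohort.tsv",
        "hc_features.tsv": out / "hc_features.tsv",
        "mdd_features.tsv": out / "mdd_features.tsv",
    }
    write_cohort(hc_cohort, files["hc_cohort.tsv"])
    write_cohort(mdd_cohort, files["mdd_cohort.tsv"])
    write_features(hc_feat, files["hc_features.tsv"])
    write_features(mdd_feat, files["mdd_features.tsv"])
    finish("generate", t0, files)
    if prev and all(
        prev.get("checksums", {}).get(k) == manifest.checksums[k] for k in files
    ):
        manifest.reused_stages.append("generate")  # inputs identical to last run

    all_cohort = pd.concat([hc_cohort, mdd_cohort], ignore_index=True)

    # ---- harmonize ------------------------------------------------------
    t0 = time.perf_counter()
    if config.harmonize and config.n_sites >= 2:
        all_feat = pd.concat([hc_feat, mdd_feat])
        covs = all_cohort[["age", "sex"]].copy()
        covs["sex"] = (covs["sex"] == "F").astype(float)
        if config.protect_diagnosis:
            covs["mdd"] = (all_cohort["group"] == "MDD").astype(float)
        harmonized, model = combat.harmonize(
            all_feat, all_cohort["site_id"].to_numpy(), covs
        )
        hc_feat = harmonized.loc[hc_feat.index]
        mdd_feat = harmonized.loc[mdd_feat.index]
        model.to_json(out / "combat_model.json")
        finish("harmonize", t0, {"combat_model.json": out / "combat_model.json"})
    else:
        log.info("harmonization skipped (disabled or single site)")
        manifest.stage_seconds["harmonize"] = 0.0

    # ---- normative model ------------------------------------------------
    t0 = time.perf_counter()
    hc_cov = hc_cohort[["age", "sex"]]
    model_set = normative.fit_normative_set(
        hc_feat, hc_cov, seed=seeds["normative"], n_restarts=config.gpr_restarts
    )
    cv_metrics, hc_z = normative.crossval_metrics(
        hc_feat, hc_cov, k_folds=config.cv_folds, seed=seeds["normative"],
        n_restarts=config.gpr_restarts,
    )
    model_set.cv_metrics = cv_metrics
    cv_metrics.to_csv(out / "cv_metrics.tsv", sep="\t")
    finish("normative", t0, {"cv_metrics.tsv": out / "cv_metrics.tsv"})

    # ---- deviations -----------------------------------------------------
    t0 = time.perf_counter()
    mdd_z = model_set.deviations(mdd_feat, mdd_cohort[["age", "sex"]])
    write_features(mdd_z, out / "mdd_deviations.tsv")
    write_features(hc_z, out / "hc_deviations.tsv")
    finish(
        "deviations", t0,
        {"mdd_deviations.tsv": out / "mdd_deviations.tsv",
         "hc_deviations.tsv": out / "hc_deviations.tsv"},
    )

    # ---- deviation statistics ------------------------------------------
    t0 = time.perf_counter()
    thr = config.extreme_threshold
    indices_mdd = devstats.deviation_indices(mdd_z, thr)
    indices_hc = devstats.deviation_indices(hc_z, thr)
    overlap = devstats.overlap_map(mdd_z, thr)
    prevalence = devstats.prevalence_stats(mdd_z, thr)
    group_tests = devstats.regionwise_group_test(mdd_z, hc_z)
    indices_mdd.to_csv(out / "mdd_indices.tsv", sep="\t")
    indices_hc.to_csv(out / "hc_indices.tsv", sep="\t")
    overlap.to_csv(out / "overlap_map.tsv", sep="\t")
    group_tests.to_csv(out / "region_tests.tsv", sep="\t")
    with open(out / "prevalence.json", "w") as fh:
        json.dump(prevalence, fh, indent=2)
    finish(
        "devstats", t0,
        {name: out / name for name in (
            "mdd_indices.tsv", "hc_indices.tsv", "overlap_map.tsv",
            "region_tests.tsv", "prevalence.json")},
    )

    # ---- subtyping ------------------------------------------------------
    t0 = time.perf_counter()
    if config.run_k_selection:
        report = subtyping.select_k(
            mdd_z, k_range=config.k_range, seed=seeds["subtype"]
        )
        k = report.winning_k
        with open(out / "k_selection.json", "w") as fh:
            json.dump(
                {"winning_k": report.winning_k, "votes": report.votes,
                 "tally": {str(kk): v for kk, v in report.tally.items()}},
                fh, indent=2,
            )
    else:
        k = 2
    result = subtyping.cluster_subjects(
        mdd_z, k, n_restarts=config.kmeans_restarts, seed=seeds["subtype"]
    )
    result.labels.to_frame().to_csv(out / "subtype_labels.tsv", sep="\t")
    net_z = subtyping.network_aggregate(mdd_z, net_map)
    write_features(net_z, out / "mdd_network_deviations.tsv")
    finish(
        "subtype", t0,
        {"subtype_labels.tsv": out / "subtype_labels.tsv",
         "mdd_network_deviations.tsv": out / "mdd_network_deviations.tsv"},
    )

    # ---- validation -----------------------------------------------------
    t0 = time.perf_counter()
    if config.run_validation:
        sites = mdd_cohort.set_index("subject_id")["site_id"]
        loso = subtyping.leave_one_site_out(
            mdd_z, sites, k, seed=seeds["validate"], primary=result,
            n_restarts=config.kmeans_restarts,
        )
        subgroups = subtyping.subgroup_validation(
            mdd_z, mdd_cohort, result, seed=seeds["validate"],
            n_restarts=config.kmeans_restarts,
        )
        validation = {
            "leave_one_site_out": {
                "per_site_overlap": {str(k_): v for k_, v in loso.fold_overlap.items()},
                "min_overlap": loso.min_overlap,
                "mean_overlap": loso.mean_overlap,
                "failed_folds": loso.failed_folds,
            },
            "subgroups": {
                "overlap": subgroups.fold_overlap,
                "ari": subgroups.fold_ari,
                "skipped": subgroups.failed_folds,
            },
        }
        with open(out / "validation.json", "w") as fh:
            json.dump(validation, fh, indent=2, default=str)
        finish("validate", t0, {"validation.json": out / "validation.json"})
    else:
        manifest.stage_seconds["validate"] = 0.0

    manifest.save(out / "manifest.json")
    return manifest


def _load_previous_manifest(out: Path) -> dict | None:
    path = out / "manifest.json"
    if path.exists():
        try:
            return json.loads(path.read_text())
        except json.JSONDecodeError:
            return None
    return None


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("rehonorm")
    except Exception:
        return "unknown"
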