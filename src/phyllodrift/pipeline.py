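"""End-to-end orchestration: simulate-or-load, analyse, report.

A run is fully described by a RunConfig (usually loaded from YAML), which
supplies either input paths (count table + metadata) or a simulation
configuration — never both. One global seed deterministically derives
per-stage seeds by hashing the stage name, so any stage can be re-run in
isolation with identical results. Every stage's warnings are first-class
entries in the JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .table_io import Dataset, align, read_asv_table, read_sample_frame, write_asv_table, write_sample_frame
from .synthetic_community import SimConfig, SpeciesConfig, generate_dataset
from .occupancy_null import (
    compare_group_divergence,
    null_occupancy_ratios,
    preferential_occupancy,
    sharing_by_species,
    site_null_suite,
)
from .core_prevalence import core_asvs, core_overlap, cumulative_core_abundance, kruskal_bh, shared_with_soil
from .beta_spatial import dispersion, dissimilarity, distance_decay_suite, rarefied_alpha

__all__ = ["RunConfig", "ConfigError", "validate_config", "stage_seed", "run"]

logger = logging.getLogger("phyllodrift")


class ConfigError(ValueError):
    """Aggregated configuration problems, each naming its key path."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    table_path: str | None = None
    meta_path: str | None = None
    table_format: str = "tsv"
    focal_species: str = "manuka"
    sim: SimConfig | None = None
    min_count: int = 1
    core_threshold: float = 1.0
    rarefaction_depth: int = 6192
    rarefaction_reps: int = 100
    abundance_boundary: float = 0.001
    permutations: int = 999
    min_distance_m: float = 1.0
    mc_pvalue: bool = False
    seed: int = 0
    out_dir: str = "phyllodrift_out"


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (global seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def validate_config(source: str | Path | dict) -> tuple[RunConfig, list[str]]:
    """Normalise a YAML/dict config to a RunConfig; aggregate all errors.

    Unknown keys are warnings, out-of-domain values errors; errors never
    fail-on-first. Returns (config, warnings); raises ConfigError with the
    full error list if any value is invalid.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    warnings: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            warnings.append(f"unknown key {key!r} ignored")
    clean = {k: v for k, v in raw.items() if k in known}
    sim_raw = clean.pop("sim", None)
    if sim_raw is not None:
        try:
            species = sim_raw.pop("species", None)
            if species is not None:
                sim_raw["species"] = tuple(SpeciesConfig(**sp) for sp in species)
            if "site_positions_m" in sim_raw:
                sim_raw["site_positions_m"] = tuple(sim_raw["site_positions_m"])
            clean["sim"] = SimConfig(**sim_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"sim: {exc}")
    cfg = RunConfig(**clean)
    if (cfg.table_path is None) == (cfg.sim is None):
        errors.append("exactly one of (table_path+meta_path, sim) must be supplied")
    if cfg.table_path is not None and cfg.meta_path is None:
        errors.append("meta_path: required when table_path is given")
    if not 0 < cfg.core_threshold <= 1:
        errors.append(f"core_threshold: {cfg.core_threshold} outside (0, 1]")
    if not 0 < cfg.abundance_boundary < 1:
        errors.append(f"abundance_boundary: {cfg.abundance_boundary} outside (0, 1)")
    if cfg.min_count < 1:
        errors.append(f"min_count: {cfg.min_count} must be >= 1")
    if cfg.rarefaction_depth < 1 or cfg.rarefaction_reps < 1:
        errors.append("rarefaction depth and reps must be >= 1")
    if cfg.permutations < 99:
        errors.append(f"permutations: {cfg.permutations} must be >= 99")
    if errors:
        raise ConfigError(errors)
    return cfg, warnings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load(config: RunConfig) -> tuple[Dataset, dict[str, Any]]:
    prov: dict[str, Any] = {}
    if config.sim is not None:
        sim = config.sim.replace(seed=stage_seed(config.seed, "simulate"))
        dataset, _truth = generate_dataset(sim)
        prov["source"] = "simulation"
        prov["sim_config"] = dataclasses.asdict(sim)
    else:
        table = read_asv_table(config.table_path, format=config.table_format)
        meta = read_sample_frame(config.meta_path, config.focal_species)
        dataset = align(table, meta)
        prov["source"] = "files"
        prov["input_checksums"] = {
            "table": _sha256(Path(config.table_path)),
            "meta": _sha256(Path(config.meta_path)),
        }
        prov["dropped_table_samples"] = list(dataset.dropped_table_samples)
        prov["dropped_meta_samples"] = list(dataset.dropped_meta_samples)
    return dataset, prov


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle.

    Stages: load/simulate -> occupancy null -> preferential occupancy ->
    cores & soil sharing -> alpha/dispersion/distance-decay. Deterministic
    given the seed; outputs are TSVs per stage plus report.json and a
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "warnings": {}}

    dataset, provenance = _load(config)
    report["provenance"] = provenance
    write_asv_table(dataset.table, out / "asv_table.tsv")
    write_sample_frame(dataset.meta, out / "sample_metadata.tsv")
    logger.info("dataset: %d samples x %d ASVs", dataset.table.n_samples, dataset.table.n_asvs)

    # --- occupancy null -----------------------------------------------------
    null_results = site_null_suite(
        dataset, min_count=config.min_count, mc_pvalue=config.mc_pvalue,
        seed=stage_seed(config.seed, "occupancy"),
    )
    null_df = pd.DataFrame(
        [
            dict(site_id=r.site_id, unit=r.unit, n_asvs=r.n_asvs,
                 chi_square=r.chi_square, p_value=r.p_value, jsd=r.jsd,
                 observed=",".join(map(str, r.observed_counts)))
            for r in null_results
        ]
    )
    null_df.to_csv(out / "site_null_results.tsv", sep="\t", index=False)
    report["warnings"]["occupancy"] = sorted(
        {w for r in null_results for w in r.warnings}
    )
    focal_jsd = [r.jsd for r in null_results if r.unit == "focal-group" and r.site_id != "pooled"]
    neigh_jsd = [r.jsd for r in null_results if r.unit == "neighbour-group" and r.site_id != "pooled"]
    stat, p, warns = compare_group_divergence(focal_jsd, neigh_jsd, alternative="greater")
    report["group_divergence"] = {
        "focal_jsds": focal_jsd, "neighbour_jsds": neigh_jsd,
        "statistic": stat, "p_value": p, "alternative": "greater",
        "warnings": list(warns),
    }

    calls = [c for s in dataset.meta.site_ids for c in preferential_occupancy(dataset, s, config.min_count)]
    calls_df = pd.DataFrame(
        [dict(asv_id=c.asv_id, site_id=c.site_id, occ_focal=c.occ_focal,
              occ_neighbour=c.occ_neighbour, total_occurrence=c.total_occurrence,
              preference=c.preference) for c in calls]
    )
    calls_df.to_csv(out / "occupancy_calls.tsv", sep="\t", index=False)
    n_groups = len(dataset.phyllosphere_samples(site_id=dataset.meta.site_ids[0], host_group="focal"))
    report["null_occupancy_ratios"] = {
        str(m): [float(x) for x in null_occupancy_ratios(m, (n_groups, n_groups))]
        for m in range(1, 2 * n_groups + 1)
    }
    report["sharing_by_species"] = {
        "+".join(k): v for k, v in sharing_by_species(dataset, config.min_count).items()
    }

    # --- cores and soil -----------------------------------------------------
    species = sorted(dataset.meta.phyllosphere()["host_species"].unique())
    cores = [core_asvs(dataset, sp, config.core_threshold, config.min_count) for sp in species]
    pd.DataFrame(
        [dict(host_species=c.host_species, threshold=c.prevalence_threshold,
              n_samples=c.n_samples_considered, core_size=len(c.asv_ids),
              asv_ids=",".join(sorted(c.asv_ids))) for c in cores]
    ).to_csv(out / "core_sets.tsv", sep="\t", index=False)
    report["core_sizes"] = {c.host_species: len(c.asv_ids) for c in cores}
    report["core_overlap"] = {"+".join(k): v for k, v in core_overlap(cores).items()}

    focal_core = next(c for c in cores if c.host_species == dataset.meta.focal_species)
    core_ab = cumulative_core_abundance(dataset, focal_core)
    by_species = {
        sp: core_ab.loc[[s for s in dataset.phyllosphere_samples(host_species=sp)
                         if s in core_ab.index]].to_numpy()
        for sp in species
    }
    tests = kruskal_bh({"focal_core_relabund": by_species})
    report["core_abundance_tests"] = [
        dict(variable=t.variable, H=t.h_statistic, p_raw=t.p_raw,
             p_adjusted=t.p_adjusted, tested=t.tested, note=t.note)
        for t in tests
    ]
    if dataset.soil_samples():
        n_shared, shared_ids = shared_with_soil(dataset, None, config.min_count)
        report["soil_sharing"] = {"all": n_shared}
        for sp in species:
            report["soil_sharing"][sp] = shared_with_soil(dataset, sp, config.min_count)[0]
        (out / "soil_shared_asvs.txt").write_text("\n".join(shared_ids) + "\n")

    # --- alpha, dispersion, distance-decay ----------------------------------
    phyl_ids = dataset.phyllosphere_samples()
    phyl_table = dataset.table.subset_samples(phyl_ids)
    depth = min(config.rarefaction_depth, int(phyl_table.counts.sum(axis=1).min()))
    alpha = rarefied_alpha(phyl_table, depth, config.rarefaction_reps,
                           seed=stage_seed(config.seed, "alpha"))
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    report["rarefaction_depth_used"] = depth

    species_of = dict(zip(dataset.meta.phyllosphere()["sample_id"],
                          dataset.meta.phyllosphere()["host_species"]))
    disp_report = {}
    for metric in ("bray-curtis", "jaccard"):
        dm = dissimilarity(phyl_table, metric, min_count=config.min_count)
        disp = dispersion(dm, species_of, config.permutations,
                          seed=stage_seed(config.seed, f"dispersion-{metric}"))
        disp_report[metric] = {
            "group_means": disp.group_means,
            "f_statistic": disp.f_statistic,
            "p_overall": disp.p_overall,
            "pairwise_p": {"|".join(k): v for k, v in disp.pairwise_p.items()},
            "warnings": list(disp.warnings),
        }
    report["dispersion"] = disp_report

    decay = distance_decay_suite(
        dataset, per_species=True, boundary=config.abundance_boundary,
        permutations=config.permutations, seed=stage_seed(config.seed, "decay"),
        min_distance_m=config.min_distance_m, min_count=config.min_count,
    )
    pd.DataFrame(
        [dict(host_species=d.host_species, abundance_class=d.abundance_class,
              metric=d.metric, mantel_r=d.mantel_r, p_value=d.p_value,
              n_pairs=d.n_pairs, permutations=d.permutations) for d in decay]
    ).to_csv(out / "distance_decay.tsv", sep="\t", index=False)
    report["distance_decay"] = [
        dict(host_species=d.host_species, abundance_class=d.abundance_class,
             metric=d.metric, mantel_r=d.mantel_r, p_value=d.p_value)
        for d in decay
    ]

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
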