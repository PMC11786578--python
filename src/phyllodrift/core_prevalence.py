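"""Prevalence-based core microbiomes and rank-based group comparisons.

A host species' core microbiome is the set of ASVs detected in at least
ceil(threshold * n) of that species' phyllosphere samples; the stringent
default threshold of 1.0 requires presence in every sample. Cores are
computed on raw counts (rarefaction is reserved for alpha diversity); an
optional pre-rarefaction path exists for sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .table_io import Dataset

__all__ = [
    "CoreSet",
    "GroupTestResult",
    "core_asvs",
    "core_overlap",
    "cumulative_core_abundance",
    "kruskal_bh",
    "shared_with_soil",
]


@dataclass(frozen=True)
class CoreSet:
    host_species: str
    prevalence_threshold: float
    asv_ids: frozenset[str]
    n_samples_considered: int


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    group_medians: dict[str, float]
    h_statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    tested: bool
    note: str = ""


def core_asvs(
    dataset: Dataset,
    host_species: str,
    threshold: float = 1.0,
    min_count: int = 1,
) -> CoreSet:
    """ASVs meeting the prevalence rule over one species' phyllosphere samples."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    samples = dataset.phyllosphere_samples(host_species=host_species)
    if not samples:
        raise ValueError(f"no phyllosphere samples for host species {host_species!r}")
    pres = dataset.table.presence(min_count).loc[samples]
    needed = math.ceil(threshold * len(samples))
    prevalent = pres.sum(axis=0) >= needed
    return CoreSet(
        host_species=host_species,
        prevalence_threshold=threshold,
        asv_ids=frozenset(str(a) for a in pres.columns[prevalent]),
        n_samples_considered=len(samples),
    )


def core_overlap(cores: list[CoreSet]) -> dict[tuple[str, ...], int]:
    """Exact-subset membership counts over the union of core ASVs.

    Every ASV in any core is assigned to the exact set of species whose core
    contains it, so the returned counts partition the union. Singleton keys
    give each species' species-unique core count.
    """
    if len(cores) < 2:
        raise ValueError("need at least 2 core sets")
    species = [c.host_species for c in cores]
    if len(set(species)) != len(species):
        raise ValueError("duplicate host species among core sets")
    union = set().union(*(c.asv_ids for c in cores))
    counts: dict[tuple[str, ...], int] = {}
    for asv in union:
        key = tuple(sorted(c.host_species for c in cores if asv in c.asv_ids))
        counts[key] = counts.get(key, 0) + 1
    return counts


def cumulative_core_abundance(
    dataset: Dataset,
    core: CoreSet,
    target_samples: list[str] | None = None,
) -> pd.Series:
    """Per-sample summed relative abundance of a core's ASVs.

    Defaults to all phyllosphere samples, so a focal species' core can be
    tracked across every host. Zero-read samples are excluded with a warning.
    """
    samples = target_samples if target_samples is not None else dataset.phyllosphere_samples()
    counts = dataset.table.counts.loc[samples]
    row_sums = counts.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        _warnings.warn(
            f"excluding zero-read samples: {list(counts.index[zero])}", stacklevel=2
        )
        counts = counts.loc[~zero]
        row_sums = row_sums[~zero]
    members = [a for a in counts.columns if str(a) in core.asv_ids]
    frac = counts[members].sum(axis=1) / row_sums
    frac.name = f"core_{core.host_species}_relabund"
    return frac


def kruskal_bh(
    data: dict[str, dict[str, np.ndarray]],
) -> list[GroupTestResult]:
    """Kruskal-Wallis per variable with Benjamini-Hochberg step-up across the family.

    ``data`` maps variable name -> group name -> observations. The BH
    adjustment spans exactly the variables passed in one call (one declared
    family). A variable with any group below 2 observations is flagged and
    excluded from testing and adjustment.
    """
    results: list[GroupTestResult] = []
    tested_idx: list[int] = []
    raw_ps: list[float] = []
    for i, (var, groups) in enumerate(data.items()):
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        medians = {g: float(np.median(v)) if len(v) else float("nan") for g, v in arrays.items()}
        if len(arrays) < 2 or any(len(v) < 2 for v in arrays.values()):
            results.append(GroupTestResult(var, medians, None, None, None, False,
                                           "a group has < 2 observations"))
            continue
        vals = list(arrays.values())
        if all(np.all(v == vals[0][0]) for v in vals):
            results.append(GroupTestResult(var, medians, 0.0, 1.0, None, True,
                                           "all observations identical"))
            tested_idx.append(len(results) - 1)
            raw_ps.append(1.0)
            continue
        h, p = stats.kruskal(*vals)
        results.append(GroupTestResult(var, medians, float(h), float(p), None, True))
        tested_idx.append(len(results) - 1)
        raw_ps.append(float(p))
    if raw_ps:
        adj = multipletests(raw_ps, method="fdr_bh")[1]
        for idx, p_adj in zip(tested_idx, adj):
            r = results[idx]
            results[idx] = GroupTestResult(
                r.variable, r.group_medians, r.h_statistic, r.p_raw,
                float(p_adj), r.tested, r.note,
            )
    return results


def shared_with_soil(
    dataset: Dataset,
    host_species: str | None = None,
    min_count: int = 1,
) -> tuple[int, list[str]]:
    """ASVs detected in both the phyllosphere (of the scope) and surface soil.

    Scope is one host species' phyllosphere samples or, with None, all of
    them. Returns the shared count and the sorted ASV identifiers.
    """
    soil = dataset.soil_samples()
    if not soil:
        raise ValueError("dataset contains no soil samples")
    phyl = dataset.phyllosphere_samples(host_species=host_species)
    if not phyl:
        raise ValueError(f"no phyllosphere samples in scope {host_species!r}")
    pres = dataset.table.presence(min_count)
    in_phyl = pres.loc[phyl].any(axis=0)
    in_soil = pres.loc[soil].any(axis=0)
    shared = sorted(str(a) for a in pres.columns[in_phyl & in_soil])
    return len(shared), shared
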