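"""Alpha diversity, community dissimilarity, dispersion and distance-decay.

Alpha diversity is computed by repeated rarefaction: each sample is
subsampled without replacement to an even depth many times and the mean
observed richness and Shannon index (natural log by default) reported.

Beta diversity uses Bray-Curtis dissimilarity on relative abundances and
Jaccard on presence/absence. Intraspecies dispersion follows the
distance-to-centroid construction in principal-coordinate space (all axes
retained; squared distances on negative-eigenvalue axes are subtracted,
floored at zero), with group differences assessed by permuting group labels
of the centroid distances. Distance-decay is tested by a seeded Mantel
permutation test of community dissimilarity against (log10) transect
distance, overall and within abundance classes.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .table_io import AsvTable, Dataset, SampleFrame

__all__ = [
    "DistanceMatrix",
    "DispersionResult",
    "DecayResult",
    "rarefied_alpha",
    "dissimilarity",
    "dispersion",
    "geo_distance",
    "abundance_partition",
    "mantel",
    "distance_decay_suite",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with sample labels and a metric tag."""

    ids: tuple[str, ...]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match id count")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class DispersionResult:
    groups: tuple[str, ...]
    sample_ids: tuple[str, ...]
    sample_groups: tuple[str, ...]
    distances: np.ndarray            # per-sample distance to its group centroid
    group_means: dict[str, float]
    f_statistic: float
    p_overall: float
    pairwise_p: dict[tuple[str, str], float]
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class DecayResult:
    host_species: str                # species name or "all"
    abundance_class: str             # all | high | low | presence-absence
    mantel_r: float
    p_value: float
    n_pairs: int
    permutations: int
    metric: str


def rarefied_alpha(
    table: AsvTable,
    depth: int = 6192,
    reps: int = 100,
    seed: int | None = None,
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """Mean richness and Shannon index over repeated without-replacement rarefaction.

    Each rep draws exactly ``depth`` reads per sample via multivariate
    hypergeometric sampling. Samples with fewer reads than the depth are
    excluded with a warning; natural-log Shannon by default.
    """
    if depth < 1 or reps < 1:
        raise ValueError("depth and reps must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=1)
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    if (~keep).any():
        _warnings.warn(
            f"excluding samples below depth {depth}: {list(sums.index[~keep])}",
            stacklevel=2,
        )
    log = np.log if shannon_base is None else (lambda x: np.log(x) / np.log(shannon_base))
    rows = []
    for sid in table.counts.index[keep]:
        counts = table.counts.loc[sid].to_numpy()
        rich = np.empty(reps)
        shan = np.empty(reps)
        nz = counts[counts > 0]
        for r in range(reps):
            sub = rng.multivariate_hypergeometric(nz, depth)
            present = sub[sub > 0]
            rich[r] = len(present)
            p = present / depth
            shan[r] = float(-(p * log(p)).sum())
        rows.append((str(sid), rich.mean(), shan.mean()))
    return pd.DataFrame(rows, columns=["sample_id", "mean_richness", "mean_shannon"]).set_index(
        "sample_id"
    )


def dissimilarity(
    table: AsvTable,
    metric: Literal["bray-curtis", "jaccard"] = "bray-curtis",
    min_count: int = 1,
) -> DistanceMatrix:
    """Pairwise Bray-Curtis (on relative abundances) or Jaccard (on presence).

    Bray-Curtis d = sum|x_i - y_i| / sum(x_i + y_i) after row normalisation;
    Jaccard d = 1 - |A n B| / |A u B| on presence sets at the detection
    threshold.
    """
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-read samples cannot enter dissimilarities: {bad}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if metric == "bray-curtis":
        rel = table.relative_abundance().to_numpy()
        cond = pdist(rel, metric="braycurtis")
    elif metric == "jaccard":
        pres = table.presence(min_count).to_numpy()
        cond = pdist(pres, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(tuple(table.sample_ids), squareform(cond), metric)


def _pcoa_axes(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All principal-coordinate axes, split by eigenvalue sign.

    Gower-centred double-centering of -D^2/2; returns (positive-axis
    coordinates, negative-axis coordinates), each scaled by sqrt(|lambda|).
    """
    d2 = dist.data ** 2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    tol = 1e-8 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    coords_pos = vecs[:, pos] * np.sqrt(vals[pos])
    coords_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return coords_pos, coords_neg


def _anova_f(d: np.ndarray, labels: np.ndarray) -> float:
    groups = [d[labels == g] for g in np.unique(labels)]
    k = len(groups)
    n = len(d)
    grand = d.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def dispersion(
    dist: DistanceMatrix,
    groups: dict[str, str],
    permutations: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Multivariate dispersion: distance to group centroid in PCoA space.

    All axes are retained; a sample's squared distance to its group centroid
    is the positive-axis contribution minus the negative-axis contribution,
    floored at zero (semi-metric dissimilarities produce negative
    eigenvalues). Overall and pairwise group differences are tested with an
    F-type statistic under seeded permutation of group labels of the
    centroid distances. Groups of size 1 are excluded with a warning.
    """
    warnings: list[str] = []
    labels = np.array([groups[i] for i in dist.ids])
    sizes = pd.Series(labels).value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.append(f"excluding single-sample groups: {singletons}")
        keep = ~np.isin(labels, singletons)
        dist = dist.subset([i for i, k in zip(dist.ids, keep) if k])
        labels = labels[keep]
    uniq = tuple(sorted(set(labels)))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    coords_pos, coords_neg = _pcoa_axes(dist)
    d = np.empty(dist.n)
    for g in uniq:
        m = labels == g
        c_pos = coords_pos[m].mean(axis=0)
        c_neg = coords_neg[m].mean(axis=0)
        sq = ((coords_pos[m] - c_pos) ** 2).sum(axis=1) - (
            (coords_neg[m] - c_neg) ** 2
        ).sum(axis=1)
        d[m] = np.sqrt(np.maximum(sq, 0.0))
    rng = np.random.default_rng(seed)
    f_obs = _anova_f(d, labels)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        if _anova_f(d, perm) >= f_obs:
            count += 1
    p_overall = (1 + count) / (1 + permutations)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(uniq, 2):
        m = np.isin(labels, (a, b))
        f_ab = _anova_f(d[m], labels[m])
        c = 0
        for _ in range(permutations):
            perm = rng.permutation(labels[m])
            if _anova_f(d[m], perm) >= f_ab:
                c += 1
        pairwise[(a, b)] = (1 + c) / (1 + permutations)
    means = {g: float(d[labels == g].mean()) for g in uniq}
    return DispersionResult(
        groups=uniq,
        sample_ids=dist.ids,
        sample_groups=tuple(labels),
        distances=d,
        group_means=means,
        f_statistic=f_obs,
        p_overall=p_overall,
        pairwise_p=pairwise,
        warnings=tuple(warnings),
    )


def geo_distance(
    frame: SampleFrame,
    sample_ids: Sequence[str] | None = None,
    log_transform: bool = True,
    min_distance_m: float = 1.0,
) -> DistanceMatrix:
    """Pairwise transect distances, optionally floored and log10-transformed.

    Co-located pairs (same tree/site, separation 0 m) are raised to
    ``min_distance_m`` before the log so log10(1) = 0; the floor applies
    only off the diagonal.
    """
    ids = list(sample_ids) if sample_ids is not None else frame.sample_ids
    pos = frame.frame.loc[ids, "position_m"].to_numpy(dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    if log_transform:
        off = ~np.eye(len(ids), dtype=bool)
        d[off] = np.log10(np.maximum(d[off], min_distance_m))
        metric = "euclidean-log-geo"
    else:
        metric = "euclidean-geo"
    return DistanceMatrix(tuple(str(i) for i in ids), d, metric)


def abundance_partition(
    table: AsvTable,
    boundary: float = 0.001,
    sample_ids: Sequence[str] | None = None,
) -> tuple[AsvTable, AsvTable, tuple[str, ...]]:
    """Split ASVs into high/low mean relative-abundance classes.

    The mean is taken across the scope's samples; ASVs at or above the
    boundary go to the high table, the rest to the low table. Both keep all
    scope samples, so the two column sets partition the original ASVs.
    """
    if not 0 < boundary < 1:
        raise ValueError("boundary must lie in (0, 1)")
    sub = table if sample_ids is None else table.subset_samples(list(sample_ids))
    mean_rel = sub.relative_abundance().mean(axis=0)
    high_cols = mean_rel.index[mean_rel >= boundary]
    low_cols = mean_rel.index[mean_rel < boundary]
    warnings = []
    if len(high_cols) == 0:
        warnings.append("high-abundance partition is empty")
    if len(low_cols) == 0:
        warnings.append("low-abundance partition is empty")
    return (
        AsvTable(sub.counts[high_cols]),
        AsvTable(sub.counts[low_cols]),
        tuple(warnings),
    )


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices' lower triangles.

    Rows/columns of the second matrix are permuted jointly;
    p = (1 + #{permuted r at least as extreme}) / (1 + permutations). The
    directional "greater" alternative is the distance-decay default.
    """
    if dist_a.ids != dist_b.ids:
        raise ValueError("distance matrices must share sample ids and order")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    va = dist_a.condensed()
    vb = dist_b.condensed()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = dist_a.n
    iu = np.triu_indices(n, k=1)
    a_full = dist_a.data
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        vp = a_full[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(vp, vb)[0, 1])
        if alternative == "greater":
            extreme = r_p >= r_obs
        elif alternative == "less":
            extreme = r_p <= r_obs
        else:
            extreme = abs(r_p) >= abs(r_obs)
        count += extreme
    return r_obs, (1 + count) / (1 + permutations)


def distance_decay_suite(
    dataset: Dataset,
    per_species: bool = True,
    boundary: float = 0.001,
    permutations: int = 999,
    seed: int | None = None,
    log_transform: bool = True,
    min_distance_m: float = 1.0,
    min_count: int = 1,
) -> list[DecayResult]:
    """Species-specific distance-decay: Mantel tests per abundance class.

    For the all-species scope and (optionally) each host species: Bray-Curtis
    vs log10 transect distance on all ASVs and on the high/low
    mean-relative-abundance classes, plus Jaccard on presence/absence. The
    abundance split is recomputed within each scope's samples.
    """
    scopes: list[tuple[str, list[str]]] = [("all", dataset.phyllosphere_samples())]
    if per_species:
        scopes += [
            (sp, dataset.phyllosphere_samples(host_species=sp))
            for sp in dataset.meta.phyllosphere()["host_species"].unique()
        ]
    results: list[DecayResult] = []
    rng = np.random.default_rng(seed)
    for scope, samples in scopes:
        sites = dataset.meta.frame.loc[samples, "site_id"].nunique()
        if sites < 3:
            raise ValueError(f"scope {scope!r} spans only {sites} sites; need >= 3")
        sub = dataset.table.subset_samples(samples)
        geo = geo_distance(dataset.meta, samples, log_transform, min_distance_m)
        high, low, warns = abundance_partition(sub, boundary, None)
        jobs: list[tuple[str, AsvTable, str]] = [("all", sub, "bray-curtis")]
        if "high-abundance partition is empty" not in warns:
            jobs.append(("high", high, "bray-curtis"))
        if "low-abundance partition is empty" not in warns:
            jobs.append(("low", low, "bray-curtis"))
        jobs.append(("presence-absence", sub, "jaccard"))
        for label, tab, metric in jobs:
            nonzero = tab.counts.sum(axis=1) > 0
            if (~nonzero).any():
                tab = AsvTable(tab.counts.loc[nonzero])
            if tab.n_samples < 4:
                continue  # too few informative samples in this abundance class
            comm = dissimilarity(tab, metric, min_count=min_count)
            geo_sub = geo.subset(tab.sample_ids) if tab.n_samples < len(samples) else geo
            r, p = mantel(
                comm, geo_sub, permutations=permutations,
                seed=int(rng.integers(2**31)), alternative="greater",
            )
            results.append(
                DecayResult(scope, label, r, p, len(comm.condensed()), permutations, metric)
            )
    return results
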