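"""Zero-truncated combinatorial occurrence null model and host-occupancy tests.

Under complete neutrality — every ASV equally likely to establish in each of
a site's n microbiomes, exposed to one shared pool — each of the 2^n - 1
non-empty presence/absence patterns is equally likely. The probability that
an ASV is detected in exactly k of the n microbiomes ("microbiome
occurrence") is therefore

    p_k = C(n, k) / (2^n - 1),   k = 1..n,

zero-truncated because never-detected ASVs are unobservable. Empirical
occurrence spectra are compared with this null by chi-square goodness of fit
and by Jensen-Shannon divergence (base 2, so bounded [0, 1]); host-group
spectra (focal vs neighbour trees, n = 3 each) are compared across sites by
an exact one-sided rank-sum test on the per-site divergences.

The same enumeration logic classifies each shared ASV's preferential host:
the group in which it attains strictly greater within-group occurrence.

Note the null's exchangeability assumption ignores per-ASV detection
probability and sequencing-depth differences; calibration holds only for
detection-matched data (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .table_io import Dataset

__all__ = [
    "OccurrenceSpectrum",
    "GofResult",
    "SiteNullResult",
    "OccupancyCall",
    "occurrence_probabilities",
    "empirical_occurrence",
    "gof_test",
    "jensen_shannon",
    "compare_group_divergence",
    "preferential_occupancy",
    "null_occupancy_ratios",
    "sharing_by_species",
    "site_null_suite",
]

Unit = Literal["whole-site", "focal-group", "neighbour-group"]


@dataclass(frozen=True)
class OccurrenceSpectrum:
    """Zero-truncated distribution over occurrence levels 1..n."""

    n: int
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if len(p) != self.n:
            raise ValueError("spectrum length must equal n")
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("spectrum must sum to 1")
        if (p < 0).any():
            raise ValueError("spectrum entries must be non-negative")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class GofResult:
    chi_square: float
    p_value: float
    warnings: tuple[str, ...] = ()
    mc_p_value: float | None = None


@dataclass(frozen=True)
class SiteNullResult:
    site_id: str
    unit: str
    observed_counts: np.ndarray
    predicted: OccurrenceSpectrum
    chi_square: float
    p_value: float
    jsd: float
    n_asvs: int
    warnings: tuple[str, ...] = ()

    @property
    def observed_proportions(self) -> np.ndarray:
        return self.observed_counts / self.n_asvs


@dataclass(frozen=True)
class OccupancyCall:
    asv_id: str
    site_id: str
    occ_focal: int
    occ_neighbour: int
    preference: str  # focal | neighbour | none

    @property
    def total_occurrence(self) -> int:
        return self.occ_focal + self.occ_neighbour


def occurrence_probabilities(n: int) -> OccurrenceSpectrum:
    """Null occurrence spectrum p_k = C(n, k) / (2^n - 1) for k = 1..n.

    For n = 6 (a whole site) the denominator is 63 and p_1 = p_5 = 6/63;
    for n = 3 (one host group) the denominator is 7 and p_1 = p_2 = 3/7.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = 2 ** n - 1
    p = np.array([math.comb(n, k) / total for k in range(1, n + 1)])
    return OccurrenceSpectrum(n=n, p=p)


def empirical_occurrence(
    dataset: Dataset,
    site_id: str,
    unit: Unit = "whole-site",
    min_count: int = 1,
    expected_n: int | None = None,
) -> np.ndarray:
    """Observed counts of ASVs at each occurrence level 1..n within a site unit.

    The unit is either all phyllosphere microbiomes at the site or one host
    group's microbiomes. ASVs absent from every microbiome of the unit are
    excluded (zero-truncation); for a host-group unit this truncation is per
    group, so an ASV seen only on neighbour trees does not enter the focal
    spectrum.
    """
    group = {"whole-site": None, "focal-group": "focal", "neighbour-group": "neighbour"}[unit]
    samples = dataset.phyllosphere_samples(site_id=site_id, host_group=group)
    n = len(samples)
    if n == 0:
        raise ValueError(f"no phyllosphere microbiomes for unit {unit!r} at site {site_id!r}")
    if expected_n is not None and n != expected_n:
        raise ValueError(
            f"site {site_id!r}: expected {expected_n} microbiomes for unit {unit!r}, found {n}"
        )
    presence = dataset.table.presence(min_count).loc[samples]
    occ = presence.sum(axis=0).to_numpy()
    return np.bincount(occ, minlength=n + 1)[1:]


def gof_test(
    observed_counts: Sequence[int],
    predicted: OccurrenceSpectrum,
    mc_pvalue: bool = False,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> GofResult:
    """Chi-square goodness of fit of an observed spectrum against the null.

    X^2 = sum_k (O_k - E_k)^2 / E_k with E_k = N p_k; p from chi-square with
    n - 1 degrees of freedom (the null is fully specified, no fitted
    parameters). Bins with expected count < 5 raise a warning flag and can
    additionally be covered by a seeded Monte-Carlo multinomial p-value;
    bins are never silently pooled.
    """
    observed = np.asarray(observed_counts, dtype=float)
    if len(observed) != predicted.n:
        raise ValueError("observed vector length must equal spectrum length")
    total = observed.sum()
    if total < 1:
        raise ValueError("at least one observed ASV is required")
    expected = total * predicted.p
    chi2, p = stats.chisquare(observed, f_exp=expected)
    warnings: list[str] = []
    if (expected < 5).any():
        warnings.append(
            f"{int((expected < 5).sum())} bin(s) with expected count < 5; "
            "chi-square approximation may be poor"
        )
    mc_p = None
    if mc_pvalue:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(total), predicted.p, size=n_mc)
        sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=1)
        mc_p = (1 + int((sim_chi2 >= chi2).sum())) / (1 + n_mc)
    return GofResult(float(chi2), float(p), tuple(warnings), mc_p)


def jensen_shannon(p: Sequence[float], q: Sequence[float]) -> float:
    """Base-2 Jensen-Shannon divergence between two spectra; bounded [0, 1].

    JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p + q)/2, using the
    convention 0 log(0/x) = 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("spectra must have equal length")
    for name, v in (("p", p), ("q", q)):
        if not math.isclose(v.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"{name} must sum to 1")
        if (v < 0).any():
            raise ValueError(f"{name} must be non-negative")
    # scipy returns the JS *distance* (sqrt of the divergence)
    d = jensenshannon(p, q, base=2)
    return float(np.clip(d * d, 0.0, 1.0))


def compare_group_divergence(
    focal_jsds: Sequence[float],
    neighbour_jsds: Sequence[float],
    alternative: Literal["greater", "less"] = "greater",
) -> tuple[float, float, tuple[str, ...]]:
    """Unpaired one-sided rank-sum test of per-site JSD between host groups.

    ``alternative="greater"`` tests whether focal divergences tend to exceed
    neighbour divergences. Exact enumeration when the combined sample is
    <= 20 and tie-free; normal approximation with tie correction otherwise.
    Fully tied data returns p = 1 with a degenerate-data warning.
    """
    x = np.asarray(focal_jsds, dtype=float)
    y = np.asarray(neighbour_jsds, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values per group")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return float(len(x) * len(y) / 2), 1.0, ("all values tied; test degenerate",)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), ()


def preferential_occupancy(
    dataset: Dataset, site_id: str, min_count: int = 1
) -> list[OccupancyCall]:
    """Classify each site's zero-truncated ASVs by preferential host group.

    An ASV present in strictly more focal than neighbour microbiomes (e.g.
    all three focal and one neighbour) is called focal-preferred; the strict
    converse is neighbour-preferred; equal occupancies give no preference.
    """
    focal = dataset.phyllosphere_samples(site_id=site_id, host_group="focal")
    neigh = dataset.phyllosphere_samples(site_id=site_id, host_group="neighbour")
    if not focal or not neigh:
        raise ValueError(f"site {site_id!r} lacks focal or neighbour microbiomes")
    pres = dataset.table.presence(min_count)
    occ_f = pres.loc[focal].sum(axis=0)
    occ_n = pres.loc[neigh].sum(axis=0)
    calls = []
    for asv in dataset.table.asv_ids:
        f, nn = int(occ_f[asv]), int(occ_n[asv])
        if f + nn == 0:
            continue
        pref = "focal" if f > nn else ("neighbour" if nn > f else "none")
        calls.append(OccupancyCall(asv, site_id, f, nn, pref))
    return calls


def null_occupancy_ratios(
    total_occurrence: int, group_sizes: tuple[int, int] = (3, 3)
) -> tuple[Fraction, Fraction, Fraction]:
    """Exact null fractions of (focal, neighbour, none) preference calls.

    Conditional on an ASV occupying m of the n = g1 + g2 microbiomes, every
    C(n, m) presence pattern is equally likely under the null; each pattern
    is classified by the strict-majority preference rule. Returned as exact
    fractions summing to 1, computed by hypergeometric counting (the test
    suite cross-checks against full pattern enumeration).
    """
    g1, g2 = group_sizes
    n = g1 + g2
    m = total_occurrence
    if not 1 <= m <= n:
        raise ValueError(f"total occurrence must lie in 1..{n}")
    total = math.comb(n, m)
    counts = {"focal": 0, "neighbour": 0, "none": 0}
    for a in range(max(0, m - g2), min(g1, m) + 1):
        ways = math.comb(g1, a) * math.comb(g2, m - a)
        b = m - a
        key = "focal" if a > b else ("neighbour" if b > a else "none")
        counts[key] += ways
    return (
        Fraction(counts["focal"], total),
        Fraction(counts["neighbour"], total),
        Fraction(counts["none"], total),
    )


def sharing_by_species(dataset: Dataset, min_count: int = 1) -> dict[tuple[str, ...], int]:
    """Count ASVs by the exact set of host species they are detected in.

    Detection is anywhere on the transect (any phyllosphere sample of the
    species). The counts over non-empty species subsets partition the
    detected ASVs — the numbers behind an upset plot.
    """
    phyl = dataset.meta.phyllosphere()
    species = sorted(phyl["host_species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 host species")
    pres = dataset.table.presence(min_count)
    per_species = {
        sp: pres.loc[phyl.loc[phyl["host_species"] == sp, "sample_id"]].any(axis=0)
        for sp in species
    }
    counts: dict[tuple[str, ...], int] = {}
    det = np.column_stack([per_species[sp].to_numpy() for sp in species])
    for row in det[det.any(axis=1)]:
        key = tuple(sp for sp, flag in zip(species, row) if flag)
        counts[key] = counts.get(key, 0) + 1
    return counts


def site_null_suite(
    dataset: Dataset,
    units: Sequence[Unit] = ("whole-site", "focal-group", "neighbour-group"),
    min_count: int = 1,
    mc_pvalue: bool = False,
    seed: int | None = None,
) -> list[SiteNullResult]:
    """Per-site goodness-of-fit and divergence against the combinatorial null.

    One result per (site, unit), plus one pooled result per unit over counts
    summed across sites (labelled site_id="pooled"); the pooled test answers
    the across-site question but is reported separately, never merged with
    per-site results.
    """
    results: list[SiteNullResult] = []
    for unit in units:
        pooled: np.ndarray | None = None
        spectrum: OccurrenceSpectrum | None = None
        for site in dataset.meta.site_ids:
            observed = empirical_occurrence(dataset, site, unit, min_count)
            spectrum = occurrence_probabilities(len(observed))
            gof = gof_test(observed, spectrum, mc_pvalue=mc_pvalue, seed=seed)
            jsd = jensen_shannon(observed / observed.sum(), spectrum.p)
            results.append(
                SiteNullResult(site, unit, observed, spectrum, gof.chi_square,
                               gof.p_value, jsd, int(observed.sum()), gof.warnings)
            )
            pooled = observed if pooled is None else pooled + observed
        if pooled is not None and spectrum is not None:
            gof = gof_test(pooled, spectrum, mc_pvalue=mc_pvalue, seed=seed)
            jsd = jensen_shannon(pooled / pooled.sum(), spectrum.p)
            results.append(
                SiteNullResult("pooled", unit, pooled, spectrum, gof.chi_square,
                               gof.p_value, jsd, int(pooled.sum()), gof.warnings)
            )
    return results
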