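"""Synthetic transect communities with tunable host selection and dispersal.

Emulates a hierarchical phyllosphere sampling design: six sites at
quasi-exponential positions along an 1800-m transect; at each site one focal
tree sampled in triplicate plus three single-replicate neighbour trees, and
one surface-soil sample per tree. Community structure is generated in four
layers:

1. a regional ASV pool with log-normal relative abundances, partitioned into
   per-species preferred sets plus an unlabelled remainder;
2. per-site pools: log-abundance perturbations drawn from a Gaussian process
   whose between-site correlation is exp(-|dx| / L_d), so site pools decay in
   similarity with transect distance;
3. per-tree expected compositions: establishment odds multiplied by
   (1 + sigma_h) on the host's preferred set (host selection), and directional
   focal->neighbour immigration seeded with probability rho per ASV
   (source-sink dispersal);
4. reads: multinomial draws at negative-binomial sequencing depth.

All randomness flows from ``SimConfig.seed`` through independent spawned
streams per layer, so fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table_io import AsvTable, Dataset, SampleFrame, align

__all__ = [
    "SpeciesConfig",
    "SimConfig",
    "SimTruth",
    "Pool",
    "generate_pool",
    "generate_site_pools",
    "assemble_samples",
    "generate_dataset",
    "sample_exchangeable_presence",
]

DEFAULT_POSITIONS = (0.0, 4.0, 16.0, 80.0, 400.0, 1800.0)


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-host-species simulation parameters.

    selection_strength is the multiplier sigma_h on establishment odds of the
    species' preferred ASVs (0 = neutral); preferred_set_size is how many
    regional-pool ASVs are assigned to this species as preferred.
    """

    name: str
    n_replicates: int = 1
    selection_strength: float = 0.0
    preferred_set_size: int = 200


def _default_species() -> tuple[SpeciesConfig, ...]:
    # focal host under strong selection, three near-neutral neighbours --
    # the scenario the transect design was built to discriminate
    return (
        SpeciesConfig("manuka", n_replicates=3, selection_strength=50.0,
                      preferred_set_size=300),
        SpeciesConfig("kanuka", n_replicates=1, selection_strength=0.0,
                      preferred_set_size=200),
        SpeciesConfig("tawiniwini", n_replicates=1, selection_strength=0.0,
                      preferred_set_size=200),
        SpeciesConfig("toatoa", n_replicates=1, selection_strength=0.0,
                      preferred_set_size=200),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated transect study.

    Defaults mirror the target design: positions 0/4/16/80/400/1800 m, a
    2000-ASV regional pool, sequencing depth ~17,000 reads per sample with
    negative-binomial spread, and a surface-soil pool nearly disjoint from
    the phyllosphere pool.
    """

    site_positions_m: tuple[float, ...] = DEFAULT_POSITIONS
    pool_size: int = 2000
    pool_meanlog: float = 0.0
    pool_sdlog: float = 2.0
    species: tuple[SpeciesConfig, ...] = field(default_factory=_default_species)
    interhost_dispersal: float = 0.2      # rho: P(focal ASV seeds a neighbour's pool)
    specialist_quantile: float = 0.6      # preferred ASVs drawn below this abundance quantile
    decay_length_m: float = 400.0         # L_d: spatial autocorrelation scale
    site_sd: float = 1.0                  # amplitude of log-scale site perturbations
    branch_sd: float = 2.0                # per-microbiome log-scale colonisation noise
    depth_mean: float = 17000.0
    depth_dispersion: float = 17.0        # negative-binomial size parameter
    deterministic_depth: bool = False
    soil_pool_overlap: float = 0.01
    soil_samples_per_tree: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions_m, dtype=float)
        if pos.ndim != 1 or len(pos) < 1 or np.any(pos < 0):
            raise ValueError("site positions must be non-negative reals")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.pool_size < 1:
            raise ValueError("pool_size must be positive")
        if not 0.0 <= self.interhost_dispersal <= 1.0:
            raise ValueError("interhost_dispersal must lie in [0, 1]")
        if not 0.0 <= self.soil_pool_overlap <= 1.0:
            raise ValueError("soil_pool_overlap must lie in [0, 1]")
        if not 0.0 < self.specialist_quantile <= 1.0:
            raise ValueError("specialist_quantile must lie in (0, 1]")
        if self.decay_length_m <= 0:
            raise ValueError("decay_length_m must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.site_sd < 0 or self.branch_sd < 0:
            raise ValueError("noise scales must be non-negative")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for sp in self.species:
            if sp.n_replicates < 1 or sp.preferred_set_size < 0:
                raise ValueError(f"invalid species config for {sp.name!r}")
            if sp.selection_strength < 0:
                raise ValueError(f"selection_strength must be >= 0 ({sp.name!r})")
        if sum(sp.preferred_set_size for sp in self.species) > self.pool_size:
            raise ValueError("sum of preferred_set_sizes exceeds pool_size")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions_m)

    @property
    def focal_species(self) -> str:
        return max(self.species, key=lambda sp: sp.n_replicates).name

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Pool:
    """Regional species pool: ids, normalised abundances, preferred-host labels."""

    asv_ids: tuple[str, ...]
    abundance: np.ndarray          # relative abundances, sum to 1
    preferred_host: tuple[str, ...]  # species name or "" per ASV

    def preferred_mask(self, species: str) -> np.ndarray:
        return np.array([h == species for h in self.preferred_host])


@dataclass(frozen=True)
class SimTruth:
    """Ground truth retained for parameter-recovery tests."""

    preferred_host: dict[str, str]        # asv_id -> species ("" = unlabelled)
    site_pools: pd.DataFrame              # sites x ASVs, rows sum to 1
    expected_composition: pd.DataFrame    # samples x ASVs, rows sum to 1


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    seq = np.random.SeedSequence(config.seed)
    names = ("pool", "sites", "assembly", "depth", "soil")
    return {n: np.random.default_rng(s) for n, s in zip(names, seq.spawn(len(names)))}


def generate_pool(config: SimConfig, rng: np.random.Generator | None = None) -> Pool:
    """Draw the regional pool: log-normal abundances, disjoint preferred sets.

    Preferred (host-specialist) ASVs are drawn from the pool's lower
    abundance tail (below ``specialist_quantile``): specialists are rare in
    the shared environment and reach high abundance only on their host,
    which is what makes the focal host a source of otherwise-rare taxa.
    """
    rng = rng if rng is not None else _rngs(config)["pool"]
    S = config.pool_size
    raw = rng.lognormal(config.pool_meanlog, config.pool_sdlog, size=S)
    abundance = raw / raw.sum()
    labels = [""] * S
    cutoff = np.quantile(abundance, config.specialist_quantile)
    eligible = np.flatnonzero(abundance <= cutoff)
    n_needed = sum(sp.preferred_set_size for sp in config.species)
    if n_needed > len(eligible):
        # fall back to the full pool when the tail is too small for the sets
        eligible = np.arange(S)
    order = eligible[rng.permutation(len(eligible))]
    cursor = 0
    for sp in config.species:
        for idx in order[cursor:cursor + sp.preferred_set_size]:
            labels[idx] = sp.name
        cursor += sp.preferred_set_size
    ids = tuple(f"ASV{i:05d}" for i in range(S))
    return Pool(asv_ids=ids, abundance=abundance, preferred_host=tuple(labels))


def generate_site_pools(
    pool: Pool, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-site pools as spatially autocorrelated perturbations of the regional pool.

    Log-abundance offsets for each ASV follow an Ornstein-Uhlenbeck field
    along the transect, anchored to the regional pool at the origin:
    Cov(u_i, u_j) = site_sd^2 * (exp(-|x_i - x_j| / L_d)
    - exp(-(x_i + x_j) / L_d)). Nearby sites share perturbations and pool
    similarity decays with distance; as L_d -> infinity every offset
    vanishes and all site pools equal the regional pool, while as L_d -> 0
    the offsets become independent across sites.
    """
    rng = rng if rng is not None else _rngs(config)["sites"]
    pos = np.asarray(config.site_positions_m, dtype=float)
    n = len(pos)
    ld = config.decay_length_m
    cov = np.exp(-np.abs(pos[:, None] - pos[None, :]) / ld) - np.exp(
        -(pos[:, None] + pos[None, :]) / ld
    )
    # anchored field: rank-deficient when an origin site is present
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
    chol = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))
    z = rng.standard_normal((n, config.pool_size))
    pert = config.site_sd * (chol @ z)
    log_ab = np.log(pool.abundance)[None, :] + pert
    ab = np.exp(log_ab - log_ab.max(axis=1, keepdims=True))
    ab /= ab.sum(axis=1, keepdims=True)
    sites = [f"S{i + 1}" for i in range(n)]
    return pd.DataFrame(ab, index=pd.Index(sites, name="site_id"), columns=list(pool.asv_ids))


def _tree_composition(
    local: np.ndarray, site_pool: np.ndarray, mask: np.ndarray, sigma: float
) -> np.ndarray:
    """Establishment odds: stochastic local term + deterministic host recruitment.

    odds = local + sigma * site_pool * mask. Host selection recruits the
    preferred set deterministically from the site pool (reproducible across
    a host's replicate microbiomes), while the local term carries the
    branch-level colonisation noise. With no noise (local == site_pool) this
    is exactly site_pool * (1 + sigma) on the preferred set and site_pool
    elsewhere.
    """
    odds = local + sigma * site_pool * mask
    return odds / odds.sum()


def _draw_depth(config: SimConfig, rng: np.random.Generator) -> int:
    if config.deterministic_depth:
        return int(round(config.depth_mean))
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    return max(1, int(rng.negative_binomial(r, p)))


def assemble_samples(
    pool: Pool,
    site_pools: pd.DataFrame,
    config: SimConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[AsvTable, SampleFrame, SimTruth]:
    """Assemble per-tree communities and draw sequencing reads.

    Each microbiome's expected composition is the site pool, jittered by
    branch-level multiplicative log-normal noise (stochastic colonisation at
    the branch scale, sd ``branch_sd``), then re-weighted by (1 + sigma_h)
    on that host's preferred set and renormalised — so strong selection
    pins a host's communities to its preferred profile while neutral hosts
    drift with the noise. Every neighbour microbiome additionally receives,
    independently per ASV with probability rho, immigration mass equal to
    that ASV's expected relative abundance on the co-located focal tree
    (directional source->sink). Read counts are independent multinomial
    draws at negative-binomial depth. Soil samples are drawn from a separate pool
    sharing ``soil_pool_overlap`` of its ASVs with the regional pool.
    """
    rngs = rngs if rngs is not None else _rngs(config)
    rng_a, rng_d, rng_s = rngs["assembly"], rngs["depth"], rngs["soil"]
    focal = config.focal_species
    S = config.pool_size
    masks = {sp.name: pool.preferred_mask(sp.name) for sp in config.species}
    sigmas = {sp.name: sp.selection_strength for sp in config.species}

    # soil pool: overlap fraction drawn from the regional pool, rest soil-only
    n_shared = int(round(config.soil_pool_overlap * S))
    shared_idx = rng_s.choice(S, size=n_shared, replace=False) if n_shared else np.array([], int)
    n_soil_only = S - n_shared
    soil_ids = [pool.asv_ids[i] for i in shared_idx] + [
        f"SOIL{i:05d}" for i in range(n_soil_only)
    ]
    soil_raw = rng_s.lognormal(config.pool_meanlog, config.pool_sdlog, size=S)
    soil_ab = soil_raw / soil_raw.sum()

    all_ids = list(pool.asv_ids) + [f"SOIL{i:05d}" for i in range(n_soil_only)]
    col_index = {a: i for i, a in enumerate(all_ids)}
    soil_cols = np.array([col_index[a] for a in soil_ids])

    rows: list[np.ndarray] = []
    expected_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    sample_ids: list[str] = []

    for site, x in zip(site_pools.index, config.site_positions_m):
        sp_pool = site_pools.loc[site].to_numpy()
        # immigration source: the focal tree's selection-weighted composition,
        # before branch-level noise
        focal_tree = _tree_composition(sp_pool, sp_pool, masks[focal], sigmas[focal])
        for sp in config.species:
            mask, sigma = masks[sp.name], sigmas[sp.name]
            for rep in range(1, sp.n_replicates + 1):
                local = sp_pool
                if config.branch_sd > 0:
                    local = sp_pool * np.exp(rng_a.normal(0.0, config.branch_sd, S))
                    local = local / local.sum()
                comp = _tree_composition(local, sp_pool, mask, sigma)
                if sp.name != focal and config.interhost_dispersal > 0:
                    seeds = rng_a.random(S) < config.interhost_dispersal
                    comp = comp + seeds * focal_tree
                    comp = comp / comp.sum()
                depth = _draw_depth(config, rng_d)
                counts = rng_a.multinomial(depth, comp)
                full = np.zeros(len(all_ids), dtype=np.int64)
                full[:S] = counts
                rows.append(full)
                exp_full = np.zeros(len(all_ids))
                exp_full[:S] = comp
                expected_rows.append(exp_full)
                sid = f"{site}_{sp.name}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, site_id=site, position_m=x,
                         host_species=sp.name, replicate_id=f"r{rep}",
                         sample_type="phyllosphere")
                )
            for srep in range(1, config.soil_samples_per_tree + 1):
                depth = _draw_depth(config, rng_d)
                counts = rng_s.multinomial(depth, soil_ab)
                full = np.zeros(len(all_ids), dtype=np.int64)
                full[soil_cols] = counts
                rows.append(full)
                exp_full = np.zeros(len(all_ids))
                exp_full[soil_cols] = soil_ab
                expected_rows.append(exp_full)
                sid = f"{site}_{sp.name}_soil{srep}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, site_id=site, position_m=x,
                         host_species=sp.name, replicate_id=f"soil{srep}",
                         sample_type="soil")
                )

    counts_df = pd.DataFrame(
        np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"), columns=all_ids
    )
    table = AsvTable(counts_df)
    meta = SampleFrame(pd.DataFrame(meta_rows), focal_species=focal)
    truth = SimTruth(
        preferred_host={a: h for a, h in zip(pool.asv_ids, pool.preferred_host)},
        site_pools=site_pools,
        expected_composition=pd.DataFrame(
            np.vstack(expected_rows), index=pd.Index(sample_ids), columns=all_ids
        ),
    )
    return table, meta, truth


def generate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Run the full generator and return an aligned dataset plus ground truth."""
    rngs = _rngs(config)
    pool = generate_pool(config, rngs["pool"])
    site_pools = generate_site_pools(pool, config, rngs["sites"])
    table, meta, truth = assemble_samples(pool, site_pools, config, rngs)
    return align(table, meta), truth


def sample_exchangeable_presence(
    n_asvs: int,
    n_microbiomes: int,
    rng: np.random.Generator,
    p_detect: float = 0.5,
) -> np.ndarray:
    """Presence/absence under the combinatorial null's exchangeability assumption.

    Every ASV is independently present in each microbiome with the same
    probability (0.5 makes all 2^n - 1 non-empty patterns equally likely
    after zero-truncation, exactly matching the combinatorial occurrence
    null). Used for detection-matched calibration of the goodness-of-fit
    test; ASVs absent everywhere are resampled so the matrix is already
    zero-truncated.
    """
    if not 0 < p_detect < 1:
        raise ValueError("p_detect must lie in (0, 1)")
    out = np.zeros((n_asvs, n_microbiomes), dtype=bool)
    todo = np.arange(n_asvs)
    while todo.size:
        draws = rng.random((todo.size, n_microbiomes)) < p_detect
        out[todo] = draws
        todo = todo[~draws.any(axis=1)]
    return out
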