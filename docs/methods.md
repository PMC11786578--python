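# Methods

`phyllodrift` asks a single ecological question of a hierarchical transect
dataset: is the composition of leaf-surface (phyllosphere) bacterial
communities driven by host selection, or by stochastic dispersal among
neighbouring plants? It answers it with a combinatorial occurrence null
model, prevalence-based core microbiomes, multivariate dispersion, and
species-specific distance-decay tests, all exercised against a synthetic
community generator that emulates the transect design and provides ground
truth.

## The sampling design the package assumes

Six sites at quasi-exponentially increasing positions along a transect
(default 0, 4, 16, 80, 400, 1800 m). At each site, one focal host tree is
sampled in triplicate (three branch microbiomes) and three neighbouring
plant species are sampled once each, giving six phyllosphere microbiomes per
site — three "focal" and three "neighbour" — plus surface-soil samples at
the base of each tree. The focal species defaults to mānuka (*Leptospermum
scoparium*) with kānuka, tawiniwini and toatoa as neighbours, but all labels
are configuration.

## The combinatorial occurrence null

Assume complete neutrality: every ASV is equally likely to establish in each
of a site's n microbiomes, all drawing on one shared pool. Then each of the
2^n − 1 non-empty presence/absence patterns is equally likely, and the
probability that an ASV is detected in exactly k microbiomes ("microbiome
occurrence") is

    p_k = C(n, k) / (2^n − 1),   k = 1..n.

The distribution is zero-truncated because never-detected ASVs are
unobservable. For n = 6 the denominator is 63 and p_1 = p_5 = 6/63; for a
host group of n = 3 it is 7 and p_1 = p_2 = 3/7. Observed spectra are
compared with this null by a chi-square goodness-of-fit test (df = n − 1;
the null has no fitted parameters) and by Jensen–Shannon divergence in log
base 2, which bounds the statistic in [0, 1]. Expected bin counts below 5
raise a warning and can be covered by a seeded Monte-Carlo multinomial
p-value; bins are never silently pooled. Per-site results are reported
alongside a separately labelled pooled test over summed counts, because the
per-site/pooled choice is a genuine analysis fork and both answers should be
visible.

The focal-vs-neighbour divergence comparison is an **unpaired** exact
rank-sum (Mann–Whitney) test on the six per-site JSD values of each group:
with six paired sites a signed-rank test cannot produce a p-value below
1/64, whereas the unpaired exact test can reach 1/924, so the unpaired form
is the default (exact enumeration when the pooled sample is ≤ 20 and
tie-free, normal approximation with tie correction otherwise; fully tied
input returns p = 1 with a degenerate-data warning).

**Preferential host occupancy** classifies each ASV at a site by strict
majority of within-group occurrences: focal if occ_focal > occ_neighbour,
neighbour on the converse, none on a tie. `null_occupancy_ratios` gives the
exact neutral expectation of the three classes conditional on total
occurrence m, by hypergeometric counting over all C(6, m) equally likely
patterns (the test suite cross-checks this against full enumeration).

**Known limitation.** The null's exchangeability assumption ignores per-ASV
detection probability: abundant taxa are detected everywhere, rare taxa
nowhere, and sequencing depth varies. On real or realistically simulated
counts the goodness-of-fit test therefore rejects for reasons that include,
but are not limited to, non-neutral assembly. Calibration (rejection rate ≈
α) holds only for detection-matched data, which the generator provides via
`sample_exchangeable_presence` (presence Bernoulli(1/2) per microbiome,
zero-truncated — exactly the uniform-pattern null). This conditioning is a
property of the method, not of the implementation, and is left visible
rather than "corrected".

## Core microbiomes and soil sharing

A host species' core is the set of ASVs present (count ≥ min_count, default
1, on raw counts) in at least ceil(threshold × n) of its phyllosphere
samples; the default threshold 1.0 means every sample. ceil() guarantees
threshold 1.0 is strict, and lowering the threshold can only grow the set.
Cores are computed without prior rarefaction — rarefaction is reserved for
alpha diversity — and the count of samples considered is always reported.
Cross-species structure is summarised by exact-subset overlap counts (the
numbers behind an upset plot), cumulative core relative abundance per
sample, Kruskal–Wallis tests with Benjamini–Hochberg correction applied
within one declared variable family per call, and phyllosphere–soil shared
ASV counts.

## Diversity, dispersion and distance-decay

*Alpha diversity* uses repeated rarefaction: each sample is subsampled
without replacement (multivariate hypergeometric) to an even depth (default
6192 reads, 100 repetitions) and mean richness and Shannon index (natural
log, configurable base) are reported.

*Dissimilarities*: Bray–Curtis on relative abundances, Jaccard on
presence/absence.

*Intraspecies dispersion* embeds the distance matrix in principal-coordinate
space keeping all axes; a sample's squared distance to its group centroid is
the positive-eigenvalue contribution minus the negative-eigenvalue
contribution, floored at zero (the standard treatment of semi-metric
dissimilarities, numerically identical to vegan's betadisper, against which
the tests verify it). Group differences use an F-type statistic with seeded
permutation of group labels of the centroid distances, overall and pairwise.
Low dispersion within a species is read as strong host selection.

*Distance-decay* is a seeded Mantel permutation test (Pearson correlation of
lower triangles, p = (1 + #{permuted r ≥ observed}) / (1 + permutations),
one-sided "greater" by default because the distance-decay hypothesis is
directional) of community dissimilarity against transect distance,
log10-transformed with co-located pairs floored to 1 m so log10 = 0. The
suite runs the all-species scope and each species separately, on all ASVs,
on high and low mean-relative-abundance classes (default boundary 0.1%,
always reported so conclusions can be checked across boundaries), and on
presence/absence.

## The synthetic community generator

The generator is the package's ground-truth instrument; its defaults are the
study conditions it emulates. Structure, in four layers:

1. **Regional pool.** `pool_size` = 2000 ASVs with log-normal relative
   abundances (meanlog 0, sdlog 2 — a typical microbial species-abundance
   spread). Each species receives a disjoint preferred ("specialist") set
   (default 300 focal / 200 per neighbour), drawn from the lower 60% of the
   pool's abundance distribution (`specialist_quantile`): host specialists
   are rare in the shared environment and reach high abundance only on
   their host. This choice keeps the focal community roughly half selected
   taxa at the default selection strength (matching the observed dominance
   of core taxa) while leaving richness comparable across hosts; drawing
   specialists uniformly instead concentrates ~15% of regional mass in the
   preferred set, and renormalisation then dilutes all other taxa
   several-fold on the focal host — an unrealistically depauperate
   community.
2. **Site pools.** Per-ASV log-abundance offsets follow an
   Ornstein–Uhlenbeck field along the transect anchored to the regional
   pool at the origin, Cov(u_i, u_j) = site_sd² (e^{−|x_i−x_j|/L_d} −
   e^{−(x_i+x_j)/L_d}), with `decay_length_m` L_d = 400 m and `site_sd` =
   1.0. Pool similarity decays monotonically with distance; as L_d → ∞ all
   offsets vanish (every site pool equals the regional pool) and as L_d → 0
   sites become independent. `site_sd` is the amplitude the correlation
   length needs to act on; 1.0 log-unit gives between-site compositional
   turnover comparable to the branch-scale noise below without dominating
   it.
3. **Tree communities.** Establishment odds for a microbiome are
   odds = local + σ_h · site_pool · preferred_mask, renormalised, where
   `local` is the site pool jittered by per-microbiome log-normal noise
   (`branch_sd` = 2.0 — branch-scale colonisation is highly stochastic, and
   without this term replicate microbiomes would be i.i.d. multinomial
   draws, unrealistically clean for amplicon data). Selection is thus a
   deterministic recruitment term: strong σ pins a host's communities to
   its preferred profile, while a pure multiplicative boost would preserve
   the noise and stabilise nothing. With noise off the formula reduces to
   site_pool × (1 + σ) on the preferred set. Defaults: σ_focal = 50,
   σ_neighbour = 0 — the strong-selection-vs-neutral contrast the transect
   design exists to discriminate. Directional source→sink dispersal then
   adds, independently per ASV with probability ρ (`interhost_dispersal`,
   default 0.2 — a placeholder, as no field estimate of inter-host
   dispersal exists), the focal tree's expected relative abundance of that
   ASV to each neighbour microbiome before renormalisation. A symmetric
   variant is out of scope; the directional form is the hypothesis under
   test.
4. **Reads.** Multinomial draws at negative-binomial depth (mean 17,000,
   size 17, reproducing a ±4,000-read spread; a deterministic-depth flag
   exists for exact-depth tests). Soil samples draw from a separate
   log-normal pool sharing `soil_pool_overlap` (default 1%) of its ASVs
   with the regional pool — phyllosphere and soil communities are nearly
   disjoint in the field.

All randomness flows from one integer seed through independent spawned
streams per layer; fixed seeds give bit-identical output.

**What the generator does not emulate:** phylogenetic structure among ASVs,
temporal dynamics, within-leaf spatial structure, read-level overdispersion
beyond depth variation, chimeras/contamination, or taxonomy. Passing
recovery tests therefore show that the statistics detect the planted
selection/dispersal structure under this model — not that real communities
satisfy the model.

## Problem sizes used by the automated checks

The calibration and recovery checks choose sizes that make Monte-Carlo error
small while keeping each run short: goodness-of-fit calibration uses 200
detection-matched sites of 500 ASVs (500 keeps every expected bin count
above 5, the chi-square validity condition); Mantel calibration uses 150
reduced-size neutral transects (pool 200, depth 2000, 199 permutations);
parameter recovery runs 20 transects at the full default scale (pool 2000,
depth 17,000). Calibration rates are judged within three binomial standard
errors of the nominal α = 0.05.

## Numerical choices and degenerate inputs

- Presence means count ≥ 1 in the raw table everywhere downstream
  (configurable `min_count`); no detection threshold is imposed silently.
- JSD inputs must sum to 1 within 1e−9; 0·log(0/x) ≡ 0.
- Chi-square requires at least one observed ASV; an all-zero spectrum is a
  precondition error, not a zero statistic.
- Mantel requires non-constant lower triangles and ≥ 99 permutations;
  permutation p-values can never be exactly 0 by construction.
- Dispersion excludes single-sample groups with a warning; squared centroid
  distances are floored at 0 before the square root.
- TSV orientation (ASVs-as-rows by default) is always declared, never
  inferred from shape; on-disk/in-memory round-trips are identities.
- The pipeline derives per-stage seeds by hashing the global seed with the
  stage name, so any stage reruns in isolation with identical results.
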