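# phyllodrift

Is a plant's leaf-surface (phyllosphere) bacterial community assembled by
**host selection** or by **stochastic dispersal** from its neighbours?
`phyllodrift` implements an analysis pipeline for answering that question on
hierarchical transect designs — several sites at increasing distances, each
with replicate microbiomes of a focal host species plus single microbiomes
of neighbouring species — together with a synthetic community generator
that emulates the design and provides ground truth for every statistic.

It was built around the mānuka (*Leptospermum scoparium*) phyllosphere
system, where the focal host is sampled in triplicate alongside kānuka,
tawiniwini and toatoa at six sites along an 1800-m transect, but every
design element is configurable.

## The core model

Under complete neutrality each ASV is equally likely to establish in each of
a site's *n* microbiomes, so all 2ⁿ − 1 non-empty presence/absence patterns
are equally likely and the probability of detection in exactly *k*
microbiomes (microbiome occurrence, Oᵐ) is the zero-truncated

&nbsp;&nbsp;&nbsp;&nbsp;p(k) = C(n, k) / (2ⁿ − 1),  k = 1…n.

For a whole site (n = 6): 63 patterns, p₁ = p₅ = 6/63. For one host group
(n = 3): 7 patterns, p₁ = p₂ = 3/7. Empirical occurrence spectra are tested
against this null with chi-square goodness-of-fit (df = n − 1) and measured
against it with base-2 Jensen–Shannon divergence; each shared ASV is further
classified by *preferential host occupancy* (the group with strictly greater
within-group occurrence) and compared with the exact neutral class ratios.
Around the null model the pipeline provides 100%-prevalence core
microbiomes, Benjamini–Hochberg-corrected Kruskal–Wallis comparisons,
repeated-rarefaction alpha diversity, betadisper-style intraspecies
dispersion, and species-specific Mantel distance-decay tests with
abundance-class partitioning. See `docs/methods.md` for the full account.

## Worked example

Simulate the default transect (strong focal selection σ = 50, neutral
neighbours, directional inter-host dispersal ρ = 0.2) and run the occupancy
null:

```python
from phyllodrift import (SimConfig, generate_dataset, site_null_suite,
                         compare_group_divergence, core_asvs)

ds, truth = generate_dataset(SimConfig(seed=42))
print(ds.table.counts.shape)            # (60, 3980): 42 phyllosphere + 24 soil ... samples x ASVs

for r in site_null_suite(ds, units=("whole-site",))[:3]:
    print(f"{r.site_id}: n_asvs={r.n_asvs} X2={r.chi_square:.1f} "
          f"p={r.p_value:.3g} JSD={r.jsd:.3f}")

foc = [r.jsd for r in site_null_suite(ds, units=("focal-group",)) if r.site_id != "pooled"]
nei = [r.jsd for r in site_null_suite(ds, units=("neighbour-group",)) if r.site_id != "pooled"]
_stat, p, _ = compare_group_divergence(foc, nei, alternative="greater")
print(f"focal JSD mean={sum(foc)/6:.3f} neighbour JSD mean={sum(nei)/6:.3f} p={p:.4f}")

for sp in ("manuka", "kanuka", "tawiniwini", "toatoa"):
    print(sp, "core size:", len(core_asvs(ds, sp).asv_ids))
```

Output:

```
(60, 3980)
S1: n_asvs=1627 X2=506.2 p=3.63e-107 JSD=0.037
S2: n_asvs=1646 X2=600.6 p=1.51e-127 JSD=0.043
S3: n_asvs=1644 X2=706.7 p=1.74e-150 JSD=0.047
focal JSD mean=0.046 neighbour JSD mean=0.007 p=0.0011
manuka core size: 222
kanuka core size: 94
tawiniwini core size: 77
toatoa core size: 100
```

Reading it: every site rejects the neutral occurrence null (selection and
dispersal are both planted in the simulation); focal-group spectra diverge
more from neutrality than neighbour-group spectra (one-sided rank-sum
p ≈ 0.001), the signature of a host that actively shapes its microbiome;
and the focal host's 100%-prevalence core is roughly twice the size of any
neighbour's despite being required across three times as many samples.

## Command line

```sh
phyllodrift simulate  --seed 1 --out-dir sim_out
phyllodrift occupancy --table sim_out/asv_table.tsv --meta sim_out/sample_metadata.tsv
phyllodrift core      --table sim_out/asv_table.tsv --meta sim_out/sample_metadata.tsv
phyllodrift spatial   --table sim_out/asv_table.tsv --meta sim_out/sample_metadata.tsv
phyllodrift run       --config config.yaml          # full pipeline + JSON report
```

Count tables are TSV (ASVs as rows by default; orientation is always
declared, never guessed) or BIOM 1.0 JSON; metadata is TSV with columns
`sample_id, site_id, position_m, host_species, replicate_id, sample_type`.

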