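import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phyllodrift import (
    AsvTable,
    SampleFrame,
    abundance_partition,
    dissimilarity,
    dispersion,
    distance_decay_suite,
    geo_distance,
    mantel,
    rarefied_alpha,
)
from phyllodrift.beta_spatial import DistanceMatrix

from conftest import small_sim_config
from phyllodrift.synthetic_community import generate_dataset


def _table(counts, samples=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    asvs = [f"a{i}" for i in range(counts.shape[1])]
    return AsvTable(pd.DataFrame(counts, index=samples, columns=asvs))


# ---------------------------------------------------------------------------
# rarefied alpha diversity


def test_forced_subsample_gives_exact_richness_and_shannon():
    table = _table([[1, 1]])
    res = rarefied_alpha(table, depth=2, reps=5, seed=0)
    assert res.loc["s0", "mean_richness"] == 2.0
    assert math.isclose(res.loc["s0", "mean_shannon"], math.log(2))


def test_single_asv_sample_has_zero_shannon():
    table = _table([[50]])
    res = rarefied_alpha(table, depth=10, reps=3, seed=0)
    assert res.loc["s0", "mean_richness"] == 1.0
    assert res.loc["s0", "mean_shannon"] == 0.0


def test_depth_equal_to_row_sum_recovers_observed_richness():
    table = _table([[3, 2, 5, 0]])
    res = rarefied_alpha(table, depth=10, reps=4, seed=0)
    assert res.loc["s0", "mean_richness"] == 3.0


def test_rarefied_richness_never_exceeds_observed(sim_dataset):
    ds, _ = sim_dataset
    phyl = ds.table.subset_samples(ds.phyllosphere_samples()[:8])
    depth = int(phyl.counts.sum(axis=1).min() // 2)
    res = rarefied_alpha(phyl, depth=depth, reps=5, seed=1)
    observed = (phyl.counts > 0).sum(axis=1)
    assert (res["mean_richness"] <= observed.loc[res.index] + 1e-9).all()
    assert (res["mean_shannon"] >= 0).all()


def test_shallow_samples_excluded_with_warning():
    table = _table([[10, 10], [1, 0]])
    with pytest.warns(UserWarning, match="s1"):
        res = rarefied_alpha(table, depth=5, reps=2, seed=0)
    assert list(res.index) == ["s0"]
    with pytest.raises(ValueError):
        rarefied_alpha(table, depth=100, reps=2, seed=0)


# ---------------------------------------------------------------------------
# dissimilarities


@pytest.mark.parametrize("metric", ["bray-curtis", "jaccard"])
def test_identical_and_disjoint_samples(metric):
    same = _table([[5, 5, 0], [10, 10, 0]])  # identical compositions
    d = dissimilarity(same, metric)
    assert math.isclose(d.data[0, 1], 0.0, abs_tol=1e-12)
    disjoint = _table([[5, 0], [0, 7]])
    assert math.isclose(dissimilarity(disjoint, metric).data[0, 1], 1.0)


def test_bray_curtis_hand_evaluated_value():
    # relative abundances (0.5, 0.5, 0) vs (0.25, 0.25, 0.5):
    # sum|x-y| = 1.0, sum(x+y) = 2 -> d = 0.5
    table = _table([[2, 2, 0], [1, 1, 2]])
    d = dissimilarity(table, "bray-curtis")
    assert math.isclose(d.data[0, 1], 0.5)


def test_zero_sum_sample_names_offender():
    table = _table([[1, 0], [0, 0]])
    with pytest.raises(ValueError, match="s1"):
        dissimilarity(table, "bray-curtis")


def test_jaccard_triangle_inequality_on_fixture_sets():
    table = _table([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]])
    d = dissimilarity(table, "jaccard").data
    n = d.shape[0]
    for i, j, k in combinations(range(n), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_dissimilarity_matches_skbio_reference(sim_dataset):
    skbio_distance = pytest.importorskip("skbio.diversity")
    ds, _ = sim_dataset
    phyl = ds.table.subset_samples(ds.phyllosphere_samples()[:10])
    mine = dissimilarity(phyl, "bray-curtis")
    rel = phyl.relative_abundance().to_numpy()
    ref = skbio_distance.beta_diversity("braycurtis", rel, validate=False)
    np.testing.assert_allclose(mine.data, ref.data, atol=1e-12)


# ---------------------------------------------------------------------------
# geographic distance


def _positions_frame(ids, positions):
    return SampleFrame(
        pd.DataFrame(
            dict(sample_id=ids, site_id=[f"S{i}" for i in range(len(ids))],
                 position_m=positions, host_species="manuka",
                 replicate_id=ids, sample_type="phyllosphere")
        ),
        "manuka",
    )


def test_geo_distance_log_and_floor_rules():
    frame = _positions_frame(["a", "b", "c"], [0.0, 0.0, 1800.0])
    d = geo_distance(frame, log_transform=True, min_distance_m=1.0)
    assert math.isclose(d.data[0, 2], math.log10(1800))
    assert d.data[0, 1] == 0.0  # co-located pair floored to 1 m, log10(1) = 0
    raw = geo_distance(frame, log_transform=False)
    assert raw.data[0, 2] == 1800.0 and raw.data[0, 1] == 0.0


# ---------------------------------------------------------------------------
# abundance partition


def test_abundance_partition_splits_and_preserves():
    table = _table([[300, 1, 699], [300, 1, 699]])
    high, low, warns = abundance_partition(table, boundary=0.01)
    assert set(high.asv_ids) == {"a0", "a2"}
    assert set(low.asv_ids) == {"a1"}
    assert not warns
    assert set(high.asv_ids) | set(low.asv_ids) == set(table.asv_ids)
    assert set(high.asv_ids) & set(low.asv_ids) == set()


def test_abundance_partition_empty_class_warns():
    table = _table([[1, 1], [1, 1]])
    high, _low, warns = abundance_partition(table, boundary=0.9)
    assert high.n_asvs == 0
    assert any("high" in w for w in warns)


# ---------------------------------------------------------------------------
# Mantel


def _random_distance(rng, n, metric="x"):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), m, metric)


def test_mantel_self_correlation():
    rng = np.random.default_rng(0)
    d = _random_distance(rng, 8)
    r, p = mantel(d, d, permutations=99, seed=1)
    assert math.isclose(r, 1.0)
    assert math.isclose(p, 1 / 100)


def test_mantel_exact_negative_relation():
    rng = np.random.default_rng(1)
    d = _random_distance(rng, 3)
    flipped = DistanceMatrix(d.ids, np.where(np.eye(3, dtype=bool), 0.0, 2.0 - d.data), "y")
    r, _p = mantel(d, flipped, permutations=99, seed=0, alternative="less")
    assert math.isclose(r, -1.0)


def test_mantel_p_invariant_under_joint_relabelling():
    rng = np.random.default_rng(2)
    a, b = _random_distance(rng, 10), _random_distance(rng, 10, "y")
    r1, p1 = mantel(a, b, permutations=499, seed=7)
    perm = rng.permutation(10)
    ids = tuple(a.ids[i] for i in perm)
    a2 = DistanceMatrix(ids, a.data[np.ix_(perm, perm)], a.metric)
    b2 = DistanceMatrix(ids, b.data[np.ix_(perm, perm)], b.metric)
    r2, p2 = mantel(a2, b2, permutations=499, seed=7)
    assert math.isclose(r1, r2, abs_tol=1e-12)
    assert abs(p1 - p2) < 0.06  # same null distribution, different draws


def test_mantel_agrees_with_skbio_reference():
    skbio_mantel = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(3)
    a, b = _random_distance(rng, 12), _random_distance(rng, 12, "y")
    r, p = mantel(a, b, permutations=999, seed=0)
    ref_r, ref_p, _n = skbio_mantel.mantel(
        skbio_mantel.DistanceMatrix(a.data, a.ids),
        skbio_mantel.DistanceMatrix(b.data, b.ids),
        method="pearson", permutations=999, alternative="greater",
    )
    assert math.isclose(r, ref_r, abs_tol=1e-12)
    assert abs(p - ref_p) < 0.07


def test_mantel_rejects_constant_matrix():
    rng = np.random.default_rng(4)
    a = _random_distance(rng, 5)
    const = DistanceMatrix(a.ids, np.where(np.eye(5, dtype=bool), 0.0, 1.0), "c")
    with pytest.raises(ValueError, match="constant"):
        mantel(a, const, permutations=99, seed=0)


# ---------------------------------------------------------------------------
# dispersion


def test_identical_samples_have_zero_dispersion():
    table = _table([[5, 5], [5, 5], [1, 9], [9, 1]])
    d = dissimilarity(table, "bray-curtis")
    res = dispersion(d, {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"},
                     permutations=99, seed=0)
    g1 = [x for x, g in zip(res.distances, res.sample_groups) if g == "g1"]
    assert np.allclose(g1, 0.0)
    assert res.group_means["g2"] > res.group_means["g1"]


def test_dispersion_matches_coordinate_oracle():
    # Euclidean distances from 4 planted 2-D points: centroid distances in
    # PCoA space must equal the direct coordinate computation
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [10.0, 4.0]])
    from scipy.spatial.distance import pdist, squareform

    d = DistanceMatrix(("p0", "p1", "p2", "p3"), squareform(pdist(pts)), "euclidean")
    groups = {"p0": "a", "p1": "a", "p2": "b", "p3": "b"}
    res = dispersion(d, groups, permutations=99, seed=0)
    expected = {
        "p0": 1.0, "p1": 1.0,   # centroid (1, 0)
        "p2": 2.0, "p3": 2.0,   # centroid (10, 2)
    }
    for sid, dist in zip(res.sample_ids, res.distances):
        assert math.isclose(dist, expected[sid], abs_tol=1e-9)


def test_dispersion_matches_skbio_permdisp_statistic():
    # independent reference on a metric (Euclidean) matrix, where the
    # negative-eigenvalue correction is inactive and both constructions
    # must coincide exactly
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(5)
    pts = rng.normal(size=(16, 4))
    ids = tuple(f"s{i}" for i in range(16))
    d = DistanceMatrix(ids, squareform(pdist(pts)), "euclidean")
    groups = {i: ("a", "b", "c", "d")[k % 4] for k, i in enumerate(ids)}
    mine = dispersion(d, groups, permutations=99, seed=0)
    ref = skbio_distance.permdisp(
        skbio_distance.DistanceMatrix(d.data, d.ids),
        [groups[i] for i in d.ids],
        test="centroid", permutations=0,
    )
    assert math.isclose(mine.f_statistic, float(ref["test statistic"]), rel_tol=1e-6)


def test_dispersion_matches_vegan_betadisper_on_semimetric():
    # Bray-Curtis produces negative eigenvalues; the imaginary-axis
    # subtraction must reproduce vegan's betadisper centroid distances
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(12, 30))
    counts[0, :15] = 0
    table = _table(counts)
    d = dissimilarity(table, "bray-curtis")
    groups = {f"s{i}": f"g{i % 3}" for i in range(12)}
    mine = dispersion(d, groups, permutations=99, seed=0)
    script = (
        "suppressMessages(library(vegan));"
        "d <- as.dist(matrix(scan('stdin', quiet=TRUE), nrow=12));"
        "g <- factor(rep(c('g0','g1','g2'), 4));"
        "b <- betadisper(d, g, type='centroid');"
        "cat(b$distances, sep=',')"
    )
    out = subprocess.run(
        ["Rscript", "-e", script],
        input="\n".join(str(x) for x in d.data.ravel()),
        capture_output=True, text=True, check=True,
    )
    ref = np.array([float(x) for x in out.stdout.strip().split(",")])
    np.testing.assert_allclose(mine.distances, ref, atol=1e-6)


def test_singleton_groups_excluded_with_warning():
    table = _table([[5, 5], [4, 6], [1, 9], [9, 1], [3, 7]])
    d = dissimilarity(table, "bray-curtis")
    res = dispersion(
        d, {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2", "s4": "lone"},
        permutations=99, seed=0,
    )
    assert "lone" not in res.groups
    assert any("lone" in w for w in res.warnings)


# ---------------------------------------------------------------------------
# distance-decay suite


def test_decay_suite_emits_all_abundance_classes(sim_dataset):
    ds, _ = sim_dataset
    results = distance_decay_suite(ds, per_species=True, permutations=99, seed=0)
    scopes = {r.host_species for r in results}
    assert "all" in scopes and "manuka" in scopes
    all_rows = {r.abundance_class for r in results if r.host_species == "all"}
    assert {"all", "presence-absence"} <= all_rows
    for r in results:
        assert -1.0 <= r.mantel_r <= 1.0
        assert 0.0 < r.p_value <= 1.0


def test_decay_suite_requires_three_sites():
    cfg = small_sim_config(seed=3, site_positions_m=(0.0, 100.0))
    ds, _ = generate_dataset(cfg)
    with pytest.raises(ValueError, match="sites"):
        distance_decay_suite(ds, permutations=99, seed=0)


def test_planted_spatial_structure_yields_positive_decay():
    # short decay length -> strong site turnover -> positive Mantel r for
    # the neutral all-species scope
    hits = 0
    for seed in range(8):
        cfg = small_sim_config(
            seed=seed, decay_length_m=2.0, branch_sd=0.5,
            species=tuple(
                type(sp)(sp.name, sp.n_replicates, 0.0, sp.preferred_set_size)
                for sp in small_sim_config().species
            ),
            interhost_dispersal=0.0,
        )
        ds, _ = generate_dataset(cfg)
        results = distance_decay_suite(ds, per_species=False, permutations=199, seed=seed)
        row = next(r for r in results if r.abundance_class == "all")
        hits += (row.mantel_r > 0) and (row.p_value < 0.05)
    assert hits >= 7
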