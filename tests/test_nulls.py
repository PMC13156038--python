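"""Spatial statistics and null models: variograms, surrogates, Moran's I,
matched-gene selection, empirical p-values."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from peptidemaps import (
    RegionAtlas,
    RegionalMatrix,
    SAParams,
    ValidationError,
    as_map,
    empirical_pvalue,
    empirical_variogram,
    ks_statistic,
    matched_gene_nulls,
    morans_i,
    pairwise_distances,
    sample_sa_map,
    variogram_surrogates,
)
from peptidemaps.nulls import (
    SurrogateGenerator,
    _VariogramMachine,
    build_weights,
    morans_i_batch,
    pair_semivariances,
)
from peptidemaps.simulate import GRFSampler, atlas_diameter, make_atlas, make_gene_pool


def _line_atlas(coords, structure="cortex"):
    rows = [
        {
            "region_id": i + 1,
            "name": f"r{i}",
            "structure": structure,
            "stratum": "s",
            "hemisphere": "L",
            "x": float(c[0]),
            "y": float(c[1]),
            "z": float(c[2]),
        }
        for i, c in enumerate(coords)
    ]
    return RegionAtlas(pd.DataFrame(rows))


class TestEmpiricalVariogram:
    def test_constant_map_rejected(self, small_dist):
        with pytest.raises(ValidationError):
            empirical_variogram(np.ones(small_dist.n), small_dist)

    def test_raw_semivariances_by_hand(self):
        # three collinear unit-spaced points with values 0, 1, 0
        atlas = _line_atlas([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        dist = pairwise_distances(atlas)
        v, d = pair_semivariances(np.array([0.0, 1.0, 0.0]), dist)
        got = sorted(zip(d, v))
        assert got == [(1.0, 0.5), (1.0, 0.5), (2.0, 0.0)]

    def test_white_noise_semivariance_equals_variance(self, medium_dist, rng):
        # over replicates, gamma(h) at every lag approaches the variance (1)
        draws = rng.standard_normal((medium_dist.n, 200))
        machine = _VariogramMachine(medium_dist)
        gammas = machine.gamma(draws)
        mean = gammas.mean(axis=1)
        se = gammas.std(axis=1, ddof=1) / np.sqrt(gammas.shape[1])
        assert np.all(np.abs(mean - 1.0) < 3 * se)

    def test_lags_increasing_and_bandwidth_recorded(self, small_dist, rng):
        vg = empirical_variogram(rng.standard_normal(small_dist.n), small_dist, n_lags=12)
        assert vg.n_lags == 12 and len(vg.lags) == 12
        assert np.all(np.diff(vg.lags) > 0)


class TestSurrogates:
    def test_marginal_preserved_bit_exactly(self, medium_atlas, medium_dist):
        m = sample_sa_map(medium_atlas, SAParams(corr_range=30), seed=5)
        ens = variogram_surrogates(m, medium_dist, n=20, seed=6)
        target = np.sort(as_map(m))
        for j in range(ens.n):
            np.testing.assert_array_equal(np.sort(ens.members[:, j]), target)

    def test_identical_seed_identical_ensemble(self, medium_atlas, medium_dist):
        m = sample_sa_map(medium_atlas, SAParams(corr_range=30), seed=5)
        a = variogram_surrogates(m, medium_dist, n=10, seed=7)
        b = variogram_surrogates(m, medium_dist, n=10, seed=7)
        np.testing.assert_array_equal(a.members, b.members)

    def test_white_target_indistinguishable_from_permutations(
        self, medium_atlas, medium_dist, rng
    ):
        x = GRFSampler(medium_dist, SAParams(corr_range=0)).sample(rng, 1)[:, 0]
        gen = SurrogateGenerator(x, medium_dist)
        assert gen.scale == 0.0  # no structure detected, plain permutations
        surr = gen.sample(200, rng)
        perms = x[np.argsort(rng.random((200, len(x))), axis=1).T]
        w = build_weights(medium_dist)
        p = stats.ks_2samp(morans_i_batch(surr, w), morans_i_batch(perms, w)).pvalue
        assert p > 0.01

    def test_smooth_target_variogram_match(self, rng):
        atlas = make_atlas(400, 54, True, seed=41)
        dist = pairwise_distances(atlas)
        m = sample_sa_map(atlas, SAParams(corr_range=atlas_diameter(atlas) / 4), seed=42)
        x = as_map(m)
        gen = SurrogateGenerator(x, dist)
        surr = gen.sample(100, rng)
        gt = gen.machine.gamma(x)
        errs = [
            np.linalg.norm(gen.machine.gamma(surr[:, j]) - gt) / np.linalg.norm(gt)
            for j in range(100)
        ]
        assert np.mean(errs) < 0.15


class TestMoransI:
    def test_alternating_ring_is_minus_one(self):
        angles = 2 * np.pi * np.arange(10) / 10
        coords = np.c_[10 * np.cos(angles), 10 * np.sin(angles), np.zeros(10)]
        atlas = _line_atlas(coords)
        dist = pairwise_distances(atlas)
        x = np.tile([1.0, -1.0], 5)
        assert morans_i(x, dist, k=2) == pytest.approx(-1.0)

    def test_permutation_mean_exhaustive_n5(self, rng):
        coords = rng.uniform(0, 10, size=(5, 3))
        atlas = _line_atlas(coords)
        dist = pairwise_distances(atlas)
        w = build_weights(dist, k=2)
        base = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        vals = [morans_i(base[list(p)], w) for p in permutations(range(5))]
        assert np.mean(vals) == pytest.approx(-1 / 4)

    def test_constant_map_rejected(self, small_dist):
        with pytest.raises(ValidationError):
            morans_i(np.ones(small_dist.n), small_dist)


class TestKSStatistic:
    def test_identical_samples_zero(self, rng):
        x = rng.standard_normal(50)
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_statistic([1.0, 2.0], [10.0, 11.0]) == 1.0

    def test_hand_example(self):
        assert ks_statistic([1.0, 2.0], [1.0, 3.0]) == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_statistic([], [1.0])


@pytest.fixture(scope="module")
def pool_setup():
    atlas = make_atlas(60, 20, True, seed=31)
    dist = pairwise_distances(atlas)
    pool, _ = make_gene_pool(atlas, 40, 5, atlas_diameter(atlas) / 2, seed=32)
    return atlas, dist, pool


class TestMatchedGeneNulls:
    def test_exact_duplicate_always_selected(self, pool_setup):
        atlas, dist, pool = pool_setup
        target = pool.column("gene_0005").copy()
        dup = RegionalMatrix(
            atlas, list(pool.columns) + ["dup"], np.c_[pool.values, target]
        )
        ens = matched_gene_nulls(
            target, dup, dist, n_draws=5, candidates_per_draw=41, seed=1
        )
        # the duplicate has rank 1 on both criteria... except the true source
        # column ties it; both are exact matches
        assert set(ens.members) <= {"dup", "gene_0005"}

    def test_selection_matches_brute_force_rerank(self, pool_setup):
        atlas, dist, pool = pool_setup
        cols = pool.columns[:10]
        small = RegionalMatrix(atlas, list(cols), pool.values[:, :10])
        target = pool.column("gene_0020")
        ens = matched_gene_nulls(
            target, small, dist, n_draws=1, candidates_per_draw=10, seed=3
        )
        # independent re-ranking over the full 10-gene candidate set
        w = build_weights(dist)
        z = target - target.mean()
        it = (z @ (w @ z)) / (z @ z)
        di, ks = [], []
        for g in cols:
            gv = small.column(g)
            zg = gv - gv.mean()
            di.append(abs((zg @ (w @ zg)) / (zg @ zg) - it))
            ks.append(stats.ks_2samp(gv, target).statistic)
        avg = 0.5 * (stats.rankdata(di) + stats.rankdata(ks))
        best = sorted(zip(avg, di, cols))[0][2]
        assert ens.members == [best]

    def test_excluded_genes_never_selected(self, pool_setup):
        atlas, dist, pool = pool_setup
        excl = ["gene_0001", "gene_0002"]
        ens = matched_gene_nulls(
            "gene_0000",
            pool,
            dist,
            n_draws=50,
            candidates_per_draw=30,
            exclude=excl,
            seed=4,
        )
        assert not (set(ens.members) & set(excl + ["gene_0000"]))

    def test_pool_too_small_rejected(self, pool_setup):
        _, dist, pool = pool_setup
        with pytest.raises(ValidationError):
            matched_gene_nulls("gene_0000", pool, dist, candidates_per_draw=100)


class TestEmpiricalPvalue:
    def test_more_extreme_than_all_nulls(self, rng):
        nulls = rng.standard_normal(10000)
        p = empirical_pvalue(nulls.max() + 10, nulls, tail="greater")
        assert p == pytest.approx(1 / 10001)

    def test_observed_at_null_center(self, rng):
        nulls = rng.standard_normal(999)
        p = empirical_pvalue(np.median(nulls), nulls, tail="two_sided")
        assert p > 0.9

    def test_add_one_estimator(self):
        nulls = np.linspace(0, 1, 99)
        assert empirical_pvalue(2.0, nulls, tail="greater") == pytest.approx(0.01)

    @given(
        st.floats(-5, 5),
        st.integers(1, 200),
        st.sampled_from(["two_sided", "greater", "less"]),
    )
    def test_bounds(self, obs, m, tail):
        nulls = np.linspace(-1, 1, m)
        p = empirical_pvalue(obs, nulls, tail=tail)
        assert 0 < p <= 1
        assert p >= 1 / (m + 1)
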