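"""QC filtering, robust sigmoid normalization, donor statistics, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peptidemaps import (
    QCThresholds,
    RegionalMatrix,
    ValidationError,
    aggregate_donors,
    differential_stability,
    qc_filter,
    robust_sigmoid_normalize,
    stratified_summary,
)
from peptidemaps.atlas import ReceptorAnnotation
from peptidemaps.datasets import load_receptor_annotation
from peptidemaps.preprocess import filter_probes_by_background, select_probes_by_rnaseq
from peptidemaps.simulate import make_atlas, make_donor_stack


@pytest.fixture(scope="module")
def annotation():
    return load_receptor_annotation()


class TestQCFilter:
    def test_packaged_table_passes_default_thresholds(self, annotation):
        assert len(qc_filter(annotation)) == 38

    def test_strict_stability_cut(self, annotation):
        # brute-force count of table rows with differential stability > 0.50
        expected = [
            g
            for g, ds in zip(
                annotation.table.gene, annotation.table.differential_stability
            )
            if ds > 0.50
        ]
        got = qc_filter(
            annotation, QCThresholds(min_diff_stability=0.5, inclusive=False)
        )
        assert got == expected
        assert len(got) == 11

    def test_impossible_thresholds_empty(self, annotation):
        t = QCThresholds(1.0, 1.0, 1.0, inclusive=False)
        assert qc_filter(annotation, t) == []

    def test_missing_metric_names_gene(self):
        t = pd.DataFrame(
            {
                "gene": ["AAA"],
                "full_name": ["x"],
                "family": ["f"],
                "mean_intensity": [0.5],
                "rnaseq_correlation": [np.nan],
                "differential_stability": [0.5],
                "mean_expr_cortex": [0.5],
                "mean_expr_hypothalamus": [0.5],
                "mean_expr_subcortex": [0.5],
            }
        )
        with pytest.raises(ValidationError, match="AAA"):
            qc_filter(ReceptorAnnotation(t))

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_monotone_in_thresholds(self, a, b, c):
        annotation = load_receptor_annotation()
        base = set(qc_filter(annotation))
        raised = set(qc_filter(annotation, QCThresholds(a, b, c)))
        if a >= 0.2 and b >= 0.2 and c >= 0.1:
            assert raised <= base


def _one_gene(atlas, values):
    return RegionalMatrix(atlas, ["g"], np.asarray(values, float))


@pytest.fixture(scope="module")
def atlas3():
    return make_atlas(3, 0, False, seed=2)


class TestRobustSigmoid:

    def test_direct_evaluation_on_three_values(self, atlas3):
        out = robust_sigmoid_normalize(_one_gene(atlas3, [1.0, 2.0, 3.0]))
        v = out.values[:, 0]
        assert v[0] == 0.0 and v[2] == 1.0
        assert 0 < v[1] < 1
        # the median input sits at the sigmoid midpoint, hence exactly the
        # middle after symmetric min-max rescaling
        assert v[1] == pytest.approx(0.5)

    def test_affine_invariance(self, atlas3):
        x = np.array([0.3, 1.9, 0.7])
        a = robust_sigmoid_normalize(_one_gene(atlas3, x)).values
        b = robust_sigmoid_normalize(_one_gene(atlas3, 5.0 * x + 11.0)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_order_preserving(self, small_atlas, rng):
        x = rng.standard_normal(small_atlas.n_regions)
        out = robust_sigmoid_normalize(_one_gene(small_atlas, x)).values[:, 0]
        np.testing.assert_array_equal(np.argsort(x), np.argsort(out))

    def test_zero_iqr_policies(self, atlas3):
        flat = _one_gene(atlas3, [2.0, 2.0, 2.0])
        with pytest.raises(ValidationError, match="IQR"):
            robust_sigmoid_normalize(flat)
        out = robust_sigmoid_normalize(flat, zero_iqr="constant")
        np.testing.assert_array_equal(out.values[:, 0], [0.5, 0.5, 0.5])

    def test_output_bounded(self, small_atlas, rng):
        m = RegionalMatrix(
            small_atlas, ["a", "b"], rng.standard_normal((small_atlas.n_regions, 2))
        )
        out = robust_sigmoid_normalize(m).values
        assert out.min() >= 0 and out.max() <= 1


class TestDifferentialStability:
    def test_identical_donors_give_one(self, small_atlas):
        donors = make_donor_stack(small_atlas, 3, 4, reliability=1.0, seed=1)
        ds = differential_stability(donors)
        np.testing.assert_allclose(ds.to_numpy(), 1.0, atol=1e-9)

    def test_two_donors_equal_single_correlation(self, small_atlas, rng):
        a = RegionalMatrix(small_atlas, ["g"], rng.standard_normal(small_atlas.n_regions))
        b = RegionalMatrix(small_atlas, ["g"], rng.standard_normal(small_atlas.n_regions))
        ds = differential_stability([a, b])
        expected = np.corrcoef(a.values[:, 0], b.values[:, 0])[0, 1]
        assert ds["g"] == pytest.approx(expected)

    def test_three_donors_mean_of_pairwise(self, small_atlas, rng):
        donors = [
            RegionalMatrix(small_atlas, ["g"], rng.standard_normal(small_atlas.n_regions))
            for _ in range(3)
        ]
        ds = differential_stability(donors)
        cols = [d.values[:, 0] for d in donors]
        pairwise = [
            np.corrcoef(cols[i], cols[j])[0, 1]
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert ds["g"] == pytest.approx(np.mean(pairwise))

    @pytest.mark.parametrize("reliability", [0.0, 0.5, 1.0])
    def test_recovers_planted_reliability(self, reliability):
        atlas = make_atlas(120, 30, True, seed=77)
        donors = make_donor_stack(atlas, 6, 150, reliability=reliability, seed=78)
        ds = differential_stability(donors).to_numpy()
        se = ds.std(ddof=1) / np.sqrt(len(ds)) if reliability < 1 else 1e-12
        assert abs(ds.mean() - reliability) < max(3 * se, 1e-9)


class TestAggregateDonors:
    def test_mean_of_two(self, small_atlas):
        zeros = RegionalMatrix(small_atlas, ["g"], np.zeros(small_atlas.n_regions))
        ones = RegionalMatrix(small_atlas, ["g"], np.ones(small_atlas.n_regions))
        out = aggregate_donors([zeros, ones])
        np.testing.assert_array_equal(out.values[:, 0], 0.5)

    def test_single_donor_identity(self, small_atlas, rng):
        d = RegionalMatrix(small_atlas, ["g"], rng.standard_normal(small_atlas.n_regions))
        np.testing.assert_array_equal(aggregate_donors([d]).values, d.values)

    def test_missing_cell_ignored(self, small_atlas):
        vals = np.ones(small_atlas.n_regions)
        d1 = RegionalMatrix(small_atlas, ["g"], vals * 1.0)
        d2 = RegionalMatrix(small_atlas, ["g"], vals * 3.0)
        v3 = vals * 100.0
        v3[0] = np.nan
        d3 = RegionalMatrix(small_atlas, ["g"], v3)
        out = aggregate_donors([d1, d2, d3])
        assert out.values[0, 0] == pytest.approx(2.0)  # mean of the 2 observed
        assert out.mask[0, 0]


class TestStratifiedSummary:
    def test_constant_map(self, small_atlas):
        m = RegionalMatrix(small_atlas, ["g"], np.full(small_atlas.n_regions, 7.0))
        s = stratified_summary(m)
        assert np.allclose(s.stratum_means.to_numpy(), 7.0)
        assert np.allclose(s.structure_medians.to_numpy(), 7.0)

    def test_hand_built_two_strata(self):
        atlas = make_atlas(3, 0, False, seed=2)
        # strata cycle through the 7 networks: visual, somatomotor, dorsal_attention
        m = RegionalMatrix(atlas, ["g"], np.array([1.0, 5.0, 9.0]))
        s = stratified_summary(m)
        assert s.stratum_means.loc["visual", "g"] == 1.0
        assert s.stratum_means.loc["somatomotor", "g"] == 5.0
        assert s.structure_medians.loc["cortex", "g"] == 5.0

    def test_ordering_covers_all_columns(self, small_atlas, rng):
        m = RegionalMatrix(
            small_atlas, list("abcde"), rng.standard_normal((small_atlas.n_regions, 5))
        )
        s = stratified_summary(m)
        assert sorted(s.ordering) == list("abcde")


class TestProbeContract:
    def test_background_filter_both_readings(self):
        intensity = pd.DataFrame(
            np.arange(12.0).reshape(3, 4),
            index=["p1", "p2", "p3"],
            columns=list("abcd"),
        )
        above = pd.DataFrame(
            [[True] * 4, [True, True, True, False], [False, False, True, True]],
            index=intensity.index,
            columns=intensity.columns,
        )
        kept = filter_probes_by_background(intensity, above, fraction=0.2)
        assert list(kept.index) == ["p1"]  # p2 below in 25%, p3 in 50%
        kept_lit = filter_probes_by_background(intensity, above, fraction=0.2, literal=True)
        assert list(kept_lit.index) == ["p2", "p3"]

    def test_probe_selection_maximizes_rnaseq_correlation(self):
        samples = list("abcde")
        ref = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["G1"], columns=samples)
        probes = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [5, 3, 4, 1, 2]],
            index=["pA", "pB"],
            columns=samples,
        )
        mapping = pd.Series({"pA": "G1", "pB": "G1"})
        chosen = select_probes_by_rnaseq(probes, mapping, ref)
        assert chosen["G1"] == "pA"
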