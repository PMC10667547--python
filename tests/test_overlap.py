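"""Normalization, Dice scoring and optimal-threshold area-of-interest extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import brute_force_optimal_threshold, random_instance
from salovlap import (
    ConsistencyError,
    DegenerateInputError,
    LesionMask,
    SaliencyLocalization,
    SaliencyMap,
    ValidationError,
    dsc_of,
    include_image,
    normalize,
    optimal_aoi,
    summarize,
)

bool_masks = hnp.arrays(bool, (4, 4))


class TestNormalize:
    def test_minmax_rescaling(self):
        out = normalize(SaliencyMap(np.array([[0.0, 5.0], [10.0, 5.0]])))
        np.testing.assert_allclose(out.values, [[0.0, 0.5], [1.0, 0.5]])
        assert out.normalized and not out.degenerate

    def test_idempotent(self):
        m = normalize(SaliencyMap(np.array([[0.3, 0.9], [0.1, 0.6]])))
        np.testing.assert_array_equal(normalize(m).values, m.values)

    def test_constant_map_degenerate(self):
        out = normalize(SaliencyMap(np.full((2, 2), 3.0)))
        assert out.degenerate
        np.testing.assert_array_equal(out.values, np.zeros((2, 2)))

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            SaliencyMap(np.array([[np.nan, 1.0], [0.0, 0.5]]))

    @given(hnp.arrays(float, (3, 5), elements=st.floats(-50, 50)))
    def test_output_in_unit_interval_with_max_one(self, values):
        out = normalize(SaliencyMap(values))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        if not out.degenerate:
            assert out.values.max() == 1.0 and out.values.min() == 0.0


class TestDice:
    def test_identical_nonempty_is_one(self):
        a = np.eye(3, dtype=bool)
        assert dsc_of(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((2, 2), bool)
        b = np.zeros((2, 2), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert dsc_of(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 4 with overlap 2: 2*2/(4+4) = 0.5
        a = np.zeros((3, 3), bool)
        b = np.zeros((3, 3), bool)
        a.ravel()[:4] = True
        b.ravel()[2:6] = True
        assert dsc_of(a, b) == 0.5

    def test_both_empty_undefined(self):
        z = np.zeros((2, 2), bool)
        with pytest.raises(DegenerateInputError):
            dsc_of(z, z)

    def test_shape_mismatch(self):
        with pytest.raises(ConsistencyError):
            dsc_of(np.ones((2, 2), bool), np.ones((2, 3), bool))

    @given(bool_masks, bool_masks)
    def test_symmetry_and_range(self, a, b):
        if not (a.any() or b.any()):
            return
        d = dsc_of(a, b)
        assert d == dsc_of(b, a)
        assert 0.0 <= d <= 1.0
        if a.any() and b.any():
            assert (d == 1.0) == bool((a == b).all())


class TestOptimalAoi:
    def test_perfect_saliency(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        smap = SaliencyMap(mask.astype(float), normalized=True)
        aoi = optimal_aoi(smap, LesionMask(mask))
        assert aoi.threshold == 1.0 and aoi.dsc == 1.0

    def test_worked_three_by_three(self):
        # DSC by prefix is 0.4, 0.667, 0.857, 1.0, then decreasing
        smap = SaliencyMap(
            np.array([[0.9, 0.8, 0.1], [0.7, 0.2, 0.1], [0.1, 0.1, 0.1]]),
            normalized=True,
        )
        mask = LesionMask(np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], bool))
        aoi = optimal_aoi(smap, mask)
        assert aoi.threshold == pytest.approx(0.2)
        assert aoi.dsc == 1.0

    def test_empty_mask_rejected(self):
        smap = SaliencyMap(np.random.default_rng(0).random((3, 3)), normalized=True)
        with pytest.raises(DegenerateInputError):
            optimal_aoi(smap, LesionMask(np.zeros((3, 3), bool)))

    def test_shape_mismatch(self):
        smap = SaliencyMap(np.zeros((3, 3)), normalized=True)
        with pytest.raises(ConsistencyError):
            optimal_aoi(smap, LesionMask(np.ones((2, 3), bool)))

    @pytest.mark.parametrize("tie_prone", [False, True])
    def test_matches_exhaustive_search(self, tie_prone):
        rng = np.random.default_rng(42 if tie_prone else 43)
        for _ in range(50):
            s, mask = random_instance(rng, tie_prone=tie_prone)
            aoi = optimal_aoi(SaliencyMap(s, normalized=True), LesionMask(mask))
            tau, dsc = brute_force_optimal_threshold(s, mask)
            assert aoi.threshold == tau
            assert aoi.dsc == dsc

    def test_beats_any_fixed_threshold(self):
        rng = np.random.default_rng(7)
        s, mask = random_instance(rng)
        aoi = optimal_aoi(SaliencyMap(s, normalized=True), LesionMask(mask))
        lm = LesionMask(mask)
        for tau in np.linspace(0, 1, 101):
            a = s >= tau
            if a.any() or lm.count:
                assert aoi.dsc >= dsc_of(a, mask) - 1e-15

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        s, mask = random_instance(rng)
        aoi = optimal_aoi(SaliencyMap(s, normalized=True), LesionMask(mask))
        transformed = normalize(SaliencyMap(np.expm1(3.0 * s)))
        aoi2 = optimal_aoi(transformed, LesionMask(mask))
        assert aoi2.dsc == aoi.dsc
        np.testing.assert_array_equal(aoi2.pixels, aoi.pixels)


class TestInclusionAndSummary:
    def test_inclusion_rule(self):
        assert not include_image(None)
        assert not include_image(LesionMask(np.zeros((2, 2), bool)))
        assert include_image(LesionMask(np.ones((2, 2), bool)))

    def test_singleton_and_symmetric(self):
        s = summarize([0.5])
        assert s.median_dsc == 0.5 and s.iqr_dsc == 0.0
        assert summarize([0.0, 1.0]).median_dsc == 0.5

    def test_quantile_rule_against_statistics_module(self):
        import statistics

        values = [0.1, 0.2, 0.3, 0.4]
        s = summarize(values)
        q1, med, q3 = statistics.quantiles(values, n=4, method="inclusive")
        assert s.median_dsc == pytest.approx(med)
        assert s.median_dsc == pytest.approx(0.25)
        assert s.iqr_dsc == pytest.approx(q3 - q1)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])

    def test_localization_model_counts_exclusions(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        smap = SaliencyMap(mask.astype(float))
        model = SaliencyLocalization(
            [smap, None, smap],
            [LesionMask(mask), None, LesionMask(np.zeros((8, 8), bool))],
            image_ids=["a", "b", "c"],
        )
        res = model.fit()
        assert res.n_images == 1 and res.n_excluded == 2
        assert res.excluded_ids == ["b", "c"]
        assert res.median_dsc == 1.0

    def test_all_excluded_raises(self):
        with pytest.raises(DegenerateInputError):
            SaliencyLocalization([None], [None], image_ids=["a"]).fit()
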