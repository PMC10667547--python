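"""Phantom, saliency-field, score and cohort generators."""

import math

import numpy as np
import pytest

from salovlap import (
    LesionMask,
    ParameterError,
    PhantomParams,
    SaliencyGenParams,
    ScoreGenParams,
    auc,
    binormal_true_auc,
    make_cohort,
    make_phantom,
    make_saliency,
    make_scores,
    match_cases,
    optimal_aoi,
)


class TestPhantom:
    def test_mask_independent_of_contrast(self):
        p0 = PhantomParams(lesion_contrast=0.0, seed=4)
        p1 = PhantomParams(lesion_contrast=0.8, seed=4)
        img0, m0 = make_phantom(p0)
        img1, m1 = make_phantom(p1)
        np.testing.assert_array_equal(m0.pixels, m1.pixels)
        assert m0.count > 0
        # contrast is purely additive on the lesion pixels
        np.testing.assert_allclose(img1 - img0, 0.8 * m0.pixels)

    def test_lesion_pixel_count_matches_point_in_ellipse_oracle(self):
        params = PhantomParams(height=64, width=64, breast_semiaxes=(28, 50),
                               lesion_center=(32.0, 20.0), lesion_axes=(5.0, 3.0))
        _, mask = make_phantom(params)
        count = 0
        for r in range(64):
            for c in range(64):
                if ((r - 32.0) / 5.0) ** 2 + ((c - 20.0) / 3.0) ** 2 <= 1.0:
                    count += 1
        assert mask.count == count

    def test_deterministic(self):
        a_img, a_mask = make_phantom(PhantomParams(seed=9))
        b_img, b_mask = make_phantom(PhantomParams(seed=9))
        np.testing.assert_array_equal(a_img, b_img)
        np.testing.assert_array_equal(a_mask.pixels, b_mask.pixels)

    def test_lesion_outside_breast_rejected(self):
        with pytest.raises(ParameterError):
            make_phantom(PhantomParams(lesion_center=(5.0, 120.0)))


class TestSaliencyField:
    def _mask(self, seed=0):
        _, mask = make_phantom(PhantomParams(seed=seed))
        return mask

    def test_localized_peak_near_lesion(self):
        mask = self._mask()
        smap = make_saliency(
            mask, SaliencyGenParams(localization=1.0, noise_amplitude=0.0, seed=1)
        )
        r, c = np.unravel_index(np.argmax(smap.values), smap.shape)
        rr, cc = np.nonzero(mask.pixels)
        d = math.hypot(r - rr.mean(), c - cc.mean())
        assert d <= SaliencyGenParams().lesion_kernel_width

    def test_normalized_unit_interval(self):
        smap = make_saliency(self._mask(), SaliencyGenParams(localization=0.4, seed=2))
        assert smap.values.min() >= 0.0 and smap.values.max() == 1.0

    def test_deterministic(self):
        mask = self._mask()
        a = make_saliency(mask, SaliencyGenParams(seed=3))
        b = make_saliency(mask, SaliencyGenParams(seed=3))
        np.testing.assert_array_equal(a.values, b.values)

    def test_diffuse_field_ignores_small_lesions(self):
        # lambda = 0: saliency independent of lesion placement, so the optimal
        # DSC stays low for lesions occupying < 2% of the image
        dscs = []
        for seed in range(100):
            _, mask = make_phantom(PhantomParams(seed=seed))
            assert mask.count < 0.02 * 128 * 128
            smap = make_saliency(
                mask, SaliencyGenParams(localization=0.0, seed=10_000 + seed)
            )
            dscs.append(optimal_aoi(smap, mask).dsc)
        assert np.mean(dscs) < 0.2

    def test_localized_beats_diffuse_paired(self):
        diffs = []
        for seed in range(50):
            _, mask = make_phantom(PhantomParams(seed=seed))
            high = make_saliency(
                mask, SaliencyGenParams(localization=1.0, seed=20_000 + seed)
            )
            low = make_saliency(
                mask, SaliencyGenParams(localization=0.0, seed=20_000 + seed)
            )
            diffs.append(optimal_aoi(high, mask).dsc - optimal_aoi(low, mask).dsc)
        assert np.median(diffs) > 0


class TestScoresGen:
    def test_null_effect_auc_near_half(self):
        recs = make_scores(ScoreGenParams(1000, 1000, 0.0, seed=5))
        assert abs(auc(recs) - 0.5) <= 0.03

    def test_binormal_closed_form(self):
        recs = make_scores(ScoreGenParams(2000, 2000, 1.0, seed=6))
        truth = 0.5 * (1.0 + math.erf(0.5))  # Phi(1/sqrt 2), via erf
        assert binormal_true_auc(1.0) == pytest.approx(truth, abs=1e-12)
        assert abs(auc(recs) - truth) <= 0.02

    def test_deterministic(self):
        a = make_scores(ScoreGenParams(10, 10, 1.0, seed=7))
        b = make_scores(ScoreGenParams(10, 10, 1.0, seed=7))
        assert a == b


class TestCohortGen:
    def test_full_matching_guaranteed(self):
        recs = make_cohort(5, 8, seed=8)
        cases = [r for r in recs if r.status == "case"]
        pool = [r for r in recs if r.status == "control"]
        pairs, unmatched = match_cases(cases, pool, seed=0)
        assert len(pairs) == 5 and not unmatched

    def test_ages_and_years_in_screening_range(self):
        recs = make_cohort(40, 60, seed=9)
        for r in recs:
            assert 50 <= r.age <= 69
            assert r.screening_year in (2015, 2016, 2017)
            assert 1946 <= r.birth_year <= 1967
            assert r.system in ("PH", "GE")

    def test_deterministic(self):
        assert make_cohort(6, 9, seed=10) == make_cohort(6, 9, seed=10)

    def test_infeasible_pool_rejected(self):
        with pytest.raises(ParameterError):
            make_cohort(5, 4, seed=0)
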