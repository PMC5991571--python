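import numpy as np
import pytest

from taskpca.classify import (
    NullVccCalibration,
    ComponentRecord,
    calibrate_null_vcc,
    classify_components,
    mean_component_image,
    vcc_pvalue,
    volume_correlation,
)
from taskpca.pca import AcquisitionId
from taskpca.selection import critical_r
from taskpca.simulate import VolumeGeometry, ellipsoid_mask


class TestVolumeCorrelation:
    def test_self_and_negation(self, rng):
        img = rng.standard_normal(500)
        assert volume_correlation(img, img) == pytest.approx(1.0)
        assert volume_correlation(img, -img) == pytest.approx(-1.0)

    def test_masked_3d_inputs(self, rng):
        mask = rng.random((6, 5, 4)) > 0.3
        a = rng.standard_normal(mask.shape)
        b = a + 0.1 * rng.standard_normal(mask.shape)
        r = volume_correlation(a, b, mask)
        assert r == pytest.approx(np.corrcoef(a[mask], b[mask])[0, 1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            volume_correlation(np.zeros(10), np.arange(10.0))


class TestVccPvalue:
    def test_threshold_009_sits_at_alpha_005(self):
        assert vcc_pvalue(0.09, 1660, 240) == pytest.approx(0.05, abs=0.01)

    def test_threshold_014_is_very_significant(self):
        assert vcc_pvalue(0.14, 1660, 240) < 3e-6

    def test_zero_vcc_capped_at_one(self):
        assert vcc_pvalue(0.0, 1660, 240) == 1.0
        assert vcc_pvalue(0.0, 50, 1) == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            vcc_pvalue(1.0, 1660, 240)


class TestCalibrateNullVcc:
    def test_unsmoothed_limit_matches_independent_voxels(self):
        geo = VolumeGeometry(dims=(30, 36, 26))
        mask = ellipsoid_mask(geo)
        cal = calibrate_null_vcc(
            geo.dims, mask, voxel_size_mm=2.0, smoothing_fwhm_mm=0.0, n_images=30, seed=0
        )
        v = int(mask.sum())
        assert np.std(cal.vccs) == pytest.approx(1 / np.sqrt(v), rel=0.15)
        assert cal.suggested_threshold >= cal.theoretical_threshold

    def test_smoothing_reduces_effective_df_toward_resel_count(self):
        geo = VolumeGeometry(dims=(30, 36, 26))
        mask = ellipsoid_mask(geo)
        cal = calibrate_null_vcc(
            geo.dims, mask, voxel_size_mm=2.0, smoothing_fwhm_mm=6.0, n_images=30, seed=0
        )
        v = int(mask.sum())
        resels = v * 2.0**3 / 6.0**3
        assert cal.implied_effective_df < v / 5
        assert resels / 2 < cal.implied_effective_df < resels * 2

    def test_deterministic_given_seed(self):
        geo = VolumeGeometry(dims=(12, 12, 10))
        mask = ellipsoid_mask(geo)
        a = calibrate_null_vcc(geo.dims, mask, n_images=20, seed=3)
        b = calibrate_null_vcc(geo.dims, mask, n_images=20, seed=3)
        np.testing.assert_array_equal(a.vccs, b.vccs)

    def test_most_null_vccs_below_theoretical_threshold(self):
        # unsmoothed images at high voxel count: >=95% of pairwise |vcc|
        # below the Bonferroni-corrected critical value for that df
        geo = VolumeGeometry(dims=(20, 24, 17))
        mask = ellipsoid_mask(geo)
        cal = calibrate_null_vcc(
            geo.dims, mask, smoothing_fwhm_mm=0.0, n_images=40, seed=1
        )
        thr = critical_r(0.05, 240, int(mask.sum()))
        assert np.mean(np.abs(cal.vccs) < thr) >= 0.95


def _record(subject, condition, run, component, ecc, image):
    return ComponentRecord(
        acquisition=AcquisitionId(subject=subject, condition=condition, run=run),
        component=component,
        ecc=ecc,
        eigenimage=image,
        eigenvariate=np.zeros(8),
    )


@pytest.fixture(scope="module")
def reference_pair():
    rng = np.random.default_rng(7)
    ref1 = rng.standard_normal(600)
    q = rng.standard_normal(600)
    q -= (q @ ref1) / (ref1 @ ref1) * ref1
    ref2 = -0.5 * ref1 / np.linalg.norm(ref1) + np.sqrt(1 - 0.25) * q / np.linalg.norm(q)
    return ref1 / np.linalg.norm(ref1), ref2 / np.linalg.norm(ref2)


def mix(ref1, ref2, a, b, noise_seed=None, noise=0.0):
    img = a * ref1 + b * ref2
    if noise:
        g = np.random.default_rng(noise_seed).standard_normal(ref1.size)
        img = img + noise * g / np.linalg.norm(g)
    return img


class TestClassifyComponents:
    def test_below_threshold(self, reference_pair, rng):
        ref1, ref2 = reference_pair
        noise = rng.standard_normal(600)
        noise -= (noise @ ref1) * ref1 + (noise @ ref2) * ref2  # mostly uncorrelated
        rec = _record("s1", "placebo", 1, 0, 0.5, noise)
        (res,) = classify_components([rec], ref1, ref2, threshold=0.14)
        assert res.exclusion_reason == "below_threshold"
        assert res.assigned_pattern == "none"

    def test_clear_pattern_assignment_and_rule_order(self, reference_pair):
        ref1, ref2 = reference_pair
        rec = _record("s1", "placebo", 1, 0, 0.5, mix(ref1, ref2, 1.0, 0.0))
        (res,) = classify_components([rec], ref1, ref2)
        assert res.assigned_pattern == "I"
        assert res.exclusion_reason == "retained"
        assert res.vcc_ref1 > 0.9

    def test_comparable_vccs_are_ambiguous(self, reference_pair):
        ref1, ref2 = reference_pair
        # equal |vcc| with both references
        img = mix(ref1, ref2, 1.0, -1.0)
        rec = _record("s1", "placebo", 1, 0, 0.5, img)
        (res,) = classify_components([rec], ref1, ref2, ambiguity_delta=0.05)
        assert res.exclusion_reason == "ambiguous"
        # a near-tie still counts as comparable at a smaller delta
        (res2,) = classify_components([rec], ref1, ref2, ambiguity_delta=0.01)
        assert res2.exclusion_reason == "ambiguous"

    def test_within_acquisition_redundancy(self, reference_pair):
        ref1, ref2 = reference_pair
        strong = _record("s1", "placebo", 1, 0, 0.6, mix(ref1, ref2, 1.0, 0.0, 1, 0.4))
        weak = _record("s1", "placebo", 1, 3, 0.4, mix(ref1, ref2, 1.0, 0.0, 2, 0.9))
        results = classify_components([weak, strong], ref1, ref2)
        by_comp = {r.record.component: r for r in results}
        assert by_comp[0].exclusion_reason == "retained"
        assert by_comp[3].exclusion_reason == "redundant_within_acquisition"

    def test_cross_acquisition_sign_inconsistency(self, reference_pair):
        ref1, ref2 = reference_pair
        run1 = _record("s1", "placebo", 1, 0, 0.5, mix(ref1, ref2, 1.0, 0.0))
        run2 = _record("s1", "placebo", 2, 0, 0.5, mix(ref1, ref2, -0.8, 0.0))
        results = classify_components([run1, run2], ref1, ref2)
        reasons = {r.record.acquisition.run: r.exclusion_reason for r in results}
        assert reasons[1] == "retained"
        assert reasons[2] == "inconsistent_across_acquisitions"

    def test_order_invariance(self, reference_pair, rng):
        ref1, ref2 = reference_pair
        records = [
            _record(f"s{i % 3}", "verum", i % 2 + 1, i, 0.3 + 0.05 * i,
                    mix(ref1, ref2, rng.normal(), rng.normal(), i, 0.5))
            for i in range(8)
        ]
        res_a = classify_components(records, ref1, ref2)
        perm = rng.permutation(8)
        res_b = classify_components([records[i] for i in perm], ref1, ref2)
        key = lambda r: (r.record.acquisition.subject, r.record.acquisition.run, r.record.component)
        a = {key(r): (r.assigned_pattern, r.exclusion_reason) for r in res_a}
        b = {key(r): (r.assigned_pattern, r.exclusion_reason) for r in res_b}
        assert a == b


class TestMeanComponentImage:
    def test_single_contributor_is_identity(self, reference_pair):
        ref1, ref2 = reference_pair
        rec = _record("s1", "verum", 1, 0, 0.4, mix(ref1, ref2, 1.0, 0.0))
        results = classify_components([rec], ref1, ref2)
        mci = mean_component_image(results, "I", "verum")
        np.testing.assert_allclose(mci.image, rec.eigenimage)
        assert mci.weights == pytest.approx([1.0])
        assert mci.label == "MCI_V1"

    def test_two_identical_contributors(self, reference_pair):
        ref1, ref2 = reference_pair
        img = mix(ref1, ref2, 1.0, 0.0)
        recs = [
            _record("s1", "placebo", 1, 0, 0.5, img),
            _record("s2", "placebo", 1, 0, 0.3, img),
        ]
        results = classify_components(recs, ref1, ref2)
        mci = mean_component_image(results, "I", "placebo")
        np.testing.assert_allclose(mci.image, img)
        np.testing.assert_allclose(sorted(mci.weights), [0.375, 0.625])

    def test_sign_alignment_improves_on_worst_contributor(self, reference_pair):
        ref1, ref2 = reference_pair
        recs = [
            _record("s1", "placebo", 1, 0, 0.5, mix(ref1, ref2, 1.0, 0.0, 11, 0.6)),
            _record("s2", "placebo", 1, 0, 0.5, mix(ref1, ref2, -1.0, 0.0, 12, 0.6)),
            _record("s3", "placebo", 1, 0, 0.5, mix(ref1, ref2, 1.0, 0.0, 13, 0.6)),
        ]
        results = classify_components(recs, ref1, ref2)
        mci = mean_component_image(results, "I", "placebo")
        contributor_vccs = [abs(r.vcc_ref1) for r in results if r.retained]
        assert volume_correlation(mci.image, ref1) >= min(contributor_vccs) - 1e-6
        assert volume_correlation(mci.image, ref1) > 0

    def test_empty_cell_rejected(self, reference_pair):
        ref1, ref2 = reference_pair
        rec = _record("s1", "verum", 1, 0, 0.4, mix(ref1, ref2, 1.0, 0.0))
        results = classify_components([rec], ref1, ref2)
        with pytest.raises(ValueError, match="no retained"):
            mean_component_image(results, "II", "verum")
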