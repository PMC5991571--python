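import json

import numpy as np
import pytest

import nibabel as nib

from taskpca.classify import volume_correlation
from taskpca.design import generate_task_design
from taskpca.hrf import modeled_response
from taskpca.io import load_image4d, load_mask, save_image
from taskpca.pca import DataMatrix, decompose, residualize
from taskpca.selection import expression_correlation
from taskpca.simulate import (
    DatasetConfig,
    GroundTruth,
    VolumeGeometry,
    acquisition_seed,
    ellipsoid_mask,
    generate_pattern_templates,
    simulate_acquisition,
    simulate_acquisition_matrix,
    simulate_dataset,
    write_ground_truth_sidecar,
)


@pytest.fixture(scope="module")
def geo():
    return VolumeGeometry(dims=(14, 16, 12))


@pytest.fixture(scope="module")
def mask(geo):
    return ellipsoid_mask(geo)


def single_pattern_truth(patterns, gain=1.0, sigma=0.0):
    return GroundTruth(
        pattern_images=patterns,
        condition_gains={"c": (gain, 0.0)},
        noise_sigma=sigma,
        gain_cv=0.0,
        distraction_prob={},
    )


class TestPatternTemplates:
    def test_unit_norm_and_default_anticorrelation(self, geo, mask):
        p1, p2 = generate_pattern_templates(geo, mask, seed=0)
        assert np.linalg.norm(p1) == pytest.approx(1.0)
        assert np.linalg.norm(p2) == pytest.approx(1.0)
        assert volume_correlation(p1, p2) < 0

    def test_identical_blob_config_gives_perfect_correlation(self, geo, mask):
        blobs = [((0.5, 0.5, 0.5), 1.0)]
        p1, p2 = generate_pattern_templates(
            geo, mask, seed=0, blobs_i=blobs, blobs_ii=blobs, anticorrelation=0.0
        )
        assert volume_correlation(p1, p2) == pytest.approx(1.0)

    def test_disjoint_small_blobs_nearly_uncorrelated(self):
        geo = VolumeGeometry(dims=(40, 48, 34))
        mask = ellipsoid_mask(geo)
        p1, p2 = generate_pattern_templates(
            geo,
            mask,
            seed=5,
            anticorrelation=0.0,
            blobs_i=[((0.25, 0.25, 0.7), 1.0)],
            blobs_ii=[((0.7, 0.75, 0.3), 1.0)],
            blob_fwhm_mm=6.0,
        )
        assert abs(volume_correlation(p1, p2)) < 0.05

    def test_blob_outside_mask_warns_and_clips(self, geo, mask):
        with pytest.warns(UserWarning, match="outside the mask"):
            p1, _ = generate_pattern_templates(
                geo, mask, seed=0, blobs_i=[((0.0, 0.0, 0.0), 1.0)]
            )
        assert np.isfinite(p1).all()


class TestSimulateAcquisition:
    def test_noiseless_single_source_recovers_pattern_exactly(self, geo, mask):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=96, tr=2.0, seed=2)
        truth = single_pattern_truth(patterns)
        matrix, meta = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=0)
        components = decompose(residualize(matrix))
        # exactly one nonzero singular value
        assert len(components) == 1
        assert abs(volume_correlation(components.eigenimages[0], patterns[0])) > 1 - 1e-8
        ecc = expression_correlation(
            components.eigenvariates[:, 0], modeled_response(design)
        )
        assert abs(ecc) > 0.999

    def test_gain_scales_first_singular_value_linearly(self, geo, mask):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=96, tr=2.0, seed=2)
        s = []
        for gain in (1.0, 2.5):
            truth = single_pattern_truth(patterns, gain=gain)
            matrix, _ = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=0)
            s.append(decompose(residualize(matrix)).singular_values[0])
        assert s[1] / s[0] == pytest.approx(2.5, rel=1e-9)

    def test_deterministic_given_seed(self, geo, mask):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=64, tr=2.0, seed=2)
        truth = GroundTruth(
            pattern_images=patterns, condition_gains={"c": (1.0, 0.5)}, noise_sigma=0.01
        )
        m1, _ = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=9)
        m2, _ = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=9)
        m3, _ = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=10)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert not np.array_equal(m1.values, m3.values)

    def test_unknown_condition_rejected(self, geo, mask):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=64, tr=2.0, seed=2)
        truth = single_pattern_truth(patterns)
        with pytest.raises(ValueError, match="no gains"):
            simulate_acquisition_matrix(design, truth, "nope", geo, mask, seed=0)

    def test_metadata_records_parameters(self, geo, mask):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=64, tr=2.0, seed=2)
        truth = GroundTruth(
            pattern_images=patterns, condition_gains={"c": (1.0, 0.5)}, noise_sigma=0.01
        )
        _, meta = simulate_acquisition_matrix(design, truth, "c", geo, mask, seed=4)
        for key in ("condition", "gain_I", "gain_II", "noise_sigma", "noise_ar1",
                    "smoothing_fwhm_mm", "distracted", "tr", "n_frames", "seed"):
            assert key in meta


class TestNiftiRoundTrip:
    def test_bit_exact_data_and_affine(self, geo, mask, tmp_path):
        patterns = generate_pattern_templates(geo, mask, seed=1)
        design = generate_task_design(n_frames=16, tr=2.0, seed=2)
        truth = GroundTruth(
            pattern_images=patterns, condition_gains={"c": (1.0, 0.3)}, noise_sigma=0.01
        )
        vol4, _ = simulate_acquisition(design, truth, "c", geo, mask, seed=0)
        path = tmp_path / "bold.nii.gz"
        save_image(vol4, geo.affine, path)
        data, affine = load_image4d(path)
        np.testing.assert_array_equal(data, vol4)
        np.testing.assert_array_equal(affine, geo.affine)
        mpath = tmp_path / "mask.nii.gz"
        save_image(mask, geo.affine, mpath)
        mdata, _ = load_mask(mpath)
        np.testing.assert_array_equal(mdata, mask)

    def test_dtype_preserved(self, tmp_path):
        img = np.arange(8, dtype=np.float64).reshape(2, 2, 2)
        save_image(img, np.eye(4), tmp_path / "x.nii.gz")
        assert nib.load(str(tmp_path / "x.nii.gz")).get_data_dtype() == np.float64


class TestSimulateDataset:
    def test_seed_derivation_is_unique_per_acquisition(self):
        seen = set()
        for s in range(3):
            for c in range(2):
                for r in range(2):
                    seen.add(tuple(acquisition_seed(7, s, c, r).entropy))
        assert len(seen) == 12

    def test_dataset_structure_and_determinism(self, geo):
        cfg = DatasetConfig(n_subjects=2, n_runs=1, n_frames=48)

        def collect():
            mask, truth, designs, acqs = simulate_dataset(cfg, geo, master_seed=5)
            return truth, [(str(a), m.values.copy()) for a, d, m, meta in acqs]

        truth1, run1 = collect()
        truth2, run2 = collect()
        assert len(run1) == 2 * 2 * 1
        assert truth1.noise_sigma == truth2.noise_sigma
        for (id1, v1), (id2, v2) in zip(run1, run2):
            assert id1 == id2
            np.testing.assert_array_equal(v1, v2)

    def test_noise_calibration_sets_component_snr(self, geo):
        # placebo pattern-I singular value ~= top singular value of the
        # double-centered pure-noise matrix (component SNR ~= 1)
        cfg = DatasetConfig(n_subjects=1, n_runs=1, n_frames=64)
        mask, truth, designs, acqs = simulate_dataset(cfg, geo, master_seed=3)
        from taskpca.simulate import calibrate_noise_sigma

        sigma = truth.noise_sigma
        resigma = calibrate_noise_sigma(
            generate_task_design(n_frames=64, tr=2.0, seed=3),
            geo, mask, truth, reference_gain=1.0, target_snr=1.0, seed=3,
        )
        assert sigma == pytest.approx(resigma, rel=1e-9)

    def test_sidecar_round_trips_parameters(self, geo, tmp_path):
        cfg = DatasetConfig(n_subjects=1, n_runs=1, n_frames=48)
        mask, truth, designs, acqs = simulate_dataset(cfg, geo, master_seed=5)
        list(acqs)
        path = tmp_path / "ground_truth.json"
        write_ground_truth_sidecar(truth, cfg, path)
        payload = json.loads(path.read_text())
        assert payload["condition_gains"]["placebo"] == [1.0, 0.35]
        assert payload["noise_sigma"] == truth.noise_sigma
        assert payload["distraction_prob"]["placebo"] == 0.35
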