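"""Bias correction, brain extraction, tissue classification, PVE, ICV,
and affine registration."""

import numpy as np
import pytest

from csfspace import preprocess as pp
from csfspace.grid import VolumeGrid
from csfspace.labels import Tissue
from csfspace.phantom import PhantomSpec, make_phantom


def dice(a, b):
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())


class TestCorrectBias:
    def test_unbiased_input_returned_unchanged(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        mask = intensity.like(truth.label_volume.data != 0)
        out = pp.correct_bias(intensity, mask)
        inside = mask.data.astype(bool)
        rel = np.abs(out.data[inside] - intensity.data[inside]) / intensity.data[inside]
        assert rel.max() < 1e-6

    def test_known_quadratic_field_removed(self):
        biased, truth = make_phantom(PhantomSpec(bias_amplitude=0.2, seed=1))
        unbiased, _ = make_phantom(PhantomSpec(bias_amplitude=0.0, seed=1))
        m = truth.label_volume.data != 0
        corrected = pp.correct_bias(biased, biased.like(m))
        rms_before = np.sqrt(np.mean(
            ((biased.data[m] - unbiased.data[m]) / unbiased.data[m]) ** 2))
        rms_after = np.sqrt(np.mean(
            ((corrected.data[m] - unbiased.data[m]) / unbiased.data[m]) ** 2))
        assert rms_after <= 0.2 * rms_before

    def test_mean_intensity_preserved(self):
        biased, truth = make_phantom(PhantomSpec(bias_amplitude=0.2, seed=2))
        m = truth.label_volume.data != 0
        corrected = pp.correct_bias(biased, biased.like(m))
        assert corrected.data[m].mean() == pytest.approx(biased.data[m].mean(), rel=1e-9)

    def test_degenerate_single_voxel_mask_rejected(self, noiseless_phantom):
        intensity, _ = noiseless_phantom
        m = np.zeros(intensity.shape, dtype=bool)
        m[48, 48, 48] = True
        with pytest.raises(pp.PreprocessError):
            pp.correct_bias(intensity, intensity.like(m))

    def test_nonpositive_intensity_rejected(self):
        vol = VolumeGrid(np.full((8, 8, 8), -1.0))
        mask = vol.like(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(pp.PreprocessError, match="non-positive"):
            pp.correct_bias(vol, mask)

    def test_degree_out_of_range_rejected(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        mask = intensity.like(truth.label_volume.data != 0)
        with pytest.raises(ValueError, match="degree"):
            pp.correct_bias(intensity, mask, degree=5)


class TestExtractBrain:
    def test_noiseless_mask_is_exact(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        mask = pp.extract_brain(intensity)
        assert np.array_equal(mask.data.astype(bool), truth.label_volume.data != 0)

    def test_single_component_no_cavities(self, noisy_phantom):
        from scipy import ndimage

        intensity, _ = noisy_phantom
        mask = pp.extract_brain(intensity)
        _, n = ndimage.label(mask.data, ndimage.generate_binary_structure(3, 1))
        assert n == 1
        filled = ndimage.binary_fill_holes(mask.data)
        assert np.array_equal(filled, mask.data.astype(bool))

    def test_dice_against_truth_under_cohort_noise(self, noisy_phantom):
        intensity, truth = noisy_phantom
        mask = pp.extract_brain(intensity)
        assert dice(mask.data.astype(bool), truth.label_volume.data != 0) >= 0.98

    def test_flat_volume_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.extract_brain(VolumeGrid(np.zeros((8, 8, 8))))


class TestClassifyTissues:
    def test_noiseless_labels_exact(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        mask = pp.extract_brain(intensity)
        maps = pp.classify_tissues(intensity, mask)
        assert np.array_equal(maps.hard_labels.data, truth.label_volume.data)

    def test_accuracy_and_mean_recovery_under_cohort_noise(self, noisy_phantom):
        intensity, truth = noisy_phantom
        mask = pp.extract_brain(intensity)
        maps = pp.classify_tissues(intensity, mask)
        inside = mask.data.astype(bool) & (truth.label_volume.data != 0)
        acc = np.mean(maps.hard_labels.data[inside] == truth.label_volume.data[inside])
        assert acc >= 0.95
        for est, true in zip(maps.class_means, PhantomSpec().class_means):
            assert est == pytest.approx(true, rel=0.02)

    def test_collapsed_modes_rejected(self):
        vol = VolumeGrid(np.full((8, 8, 8), 7.0))
        mask = vol.like(np.ones(vol.shape, dtype=bool))
        with pytest.raises(pp.PreprocessError):
            pp.classify_tissues(vol, mask)

    def test_empty_mask_rejected(self, noiseless_phantom):
        intensity, _ = noiseless_phantom
        with pytest.raises(pp.PreprocessError, match="empty"):
            pp.classify_tissues(intensity, intensity.like(np.zeros(intensity.shape, bool)))


def _two_region_fixture(probe_value):
    """A CSF|GM|WM slab volume with known class means (30/80/120) and one
    probe voxel at the CSF-GM interface; exercises the mixing rule alone."""
    data = np.full((6, 6, 9), 30.0)
    data[:, :, 3:6] = 80.0
    data[:, :, 6:] = 120.0
    data[3, 3, 2] = probe_value  # CSF-side interface voxel
    vol = VolumeGrid(data)
    labels = np.full(vol.shape, int(Tissue.CSF), dtype=np.uint8)
    labels[:, :, 3:6] = Tissue.GM
    labels[:, :, 6:] = Tissue.WM
    fractions = np.zeros((*vol.shape, 3))
    for k in range(3):
        fractions[..., k] = labels == (k + int(Tissue.CSF))
    maps = pp.TissueMaps(
        hard_labels=vol.like(labels),
        fractions=fractions,
        class_means=np.array([30.0, 80.0, 120.0]),
        brain_mask=vol.like(np.ones(vol.shape, dtype=bool)),
    )
    return vol, pp.estimate_partial_volume(vol, maps)


class TestEstimatePartialVolume:
    def test_pure_voxel_at_class_mean_has_fraction_one(self):
        _, maps = _two_region_fixture(30.0)
        assert maps.fractions[0, 0, 0, 0] == 1.0  # CSF fraction

    def test_midway_voxel_splits_half_half(self):
        _, maps = _two_region_fixture(55.0)
        csf, gm, wm = maps.fractions[3, 3, 2]
        assert (csf, gm, wm) == pytest.approx((0.5, 0.5, 0.0))

    def test_fractions_partition_of_unity(self, noisy_phantom):
        intensity, _ = noisy_phantom
        mask = pp.extract_brain(intensity)
        maps = pp.estimate_partial_volume(intensity, pp.classify_tissues(intensity, mask))
        sums = maps.fractions.sum(axis=-1)
        inside = mask.data.astype(bool)
        assert np.allclose(sums[inside], 1.0, atol=1e-6)
        assert np.all(sums[~inside] == 0)

    def test_noiseless_fraction_volume_equals_hard_volume(self, noiseless_phantom):
        intensity, _ = noiseless_phantom
        mask = pp.extract_brain(intensity)
        maps = pp.estimate_partial_volume(intensity, pp.classify_tissues(intensity, mask))
        hard_csf = np.sum(maps.hard_labels.data == Tissue.CSF)
        assert maps.csf_fraction().sum() == pytest.approx(hard_csf, abs=1e-9)

    def test_equal_class_means_rejected(self):
        vol = VolumeGrid(np.full((4, 4, 4), 10.0))
        maps = pp.TissueMaps(
            hard_labels=vol.like(np.full(vol.shape, int(Tissue.CSF), dtype=np.uint8)),
            fractions=np.zeros((*vol.shape, 3)),
            class_means=np.array([10.0, 10.0, 20.0]),
            brain_mask=vol.like(np.ones(vol.shape, dtype=bool)),
        )
        with pytest.raises(pp.PreprocessError, match="increasing"):
            pp.estimate_partial_volume(vol, maps)


class TestComputeIcv:
    @pytest.mark.parametrize(
        "shape,spacing,expected",
        [((10, 10, 10), (1, 1, 1), 1000.0), ((10, 10, 1), (1, 1, 2), 200.0)],
    )
    def test_count_times_voxel_volume(self, shape, spacing, expected):
        mask = VolumeGrid(np.ones(shape, dtype=bool), spacing)
        assert pp.compute_icv(mask) == expected

    def test_matches_phantom_truth_with_exact_extraction(self, noiseless_phantom):
        intensity, truth = noiseless_phantom
        assert pp.compute_icv(pp.extract_brain(intensity)) == truth.true_icv


@pytest.fixture(scope="module")
def reg_phantom():
    vol, _ = make_phantom(PhantomSpec(shape=(64, 64, 64), noise_sd=4.0, seed=3))
    return vol


class TestRegisterAffine:
    def test_self_registration_is_identity(self, reg_phantom):
        tr = pp.register_affine(reg_phantom, reg_phantom)
        assert np.abs(tr.translation).max() < 0.1
        assert np.abs(np.diag(tr.matrix) - 1).max() < 0.005

    def test_known_translation_recovered(self, reg_phantom):
        moving = reg_phantom.like(np.roll(reg_phantom.data, (5, -3, 2), (0, 1, 2)))
        tr = pp.register_affine(moving, reg_phantom)
        assert np.abs(tr.translation - [5, -3, 2]).max() < 0.5

    def test_known_isotropic_scale_recovered(self, reg_phantom):
        from scipy import ndimage

        c = (np.array(reg_phantom.shape) - 1) / 2.0
        scaled = ndimage.affine_transform(
            reg_phantom.data.astype(float), np.eye(3) * 1.1, offset=c - 1.1 * c, order=1
        )
        tr = pp.register_affine(reg_phantom.like(scaled), reg_phantom)
        assert np.abs(np.diag(tr.matrix) - 1 / 1.1).max() < 0.01

    def test_flat_input_rejected(self):
        flat = VolumeGrid(np.zeros((16, 16, 16)))
        with pytest.raises(pp.RegistrationError):
            pp.register_affine(flat, flat)
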