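"""Tests of surface delineation, HRF segmentation and evaluation metrics."""

import numpy as np
import pytest

from hefq.core import HRFMask, OCTVolume, ScanGeometry, SurfacePair
from hefq.segment import (
    SegMetrics,
    crossval_evaluate,
    delineate_surfaces,
    dice_coefficient,
    segment_hrf_reference,
    train_learned_segmenter,
    voxel_accuracy,
)
from hefq.synth import VolumeParams, generate_volume


class TestDelineateSurfaces:
    def test_supplied_is_identity(self, default_volume):
        volume, surfaces, _ = default_volume
        assert delineate_surfaces(volume, "supplied", truth=surfaces) is surfaces

    def test_supplied_requires_truth(self, default_volume):
        with pytest.raises(ValueError, match="supplied"):
            delineate_surfaces(default_volume[0], "supplied")

    def test_gradient_recovers_clean_surfaces(self, clean_volume):
        volume, truth, _ = clean_volume
        est = delineate_surfaces(volume, "gradient")
        ilm_ok = (np.abs(est.ilm - truth.ilm) <= 1).mean()
        rpe_ok = (np.abs(est.rpe - truth.rpe) <= 1).mean()
        assert ilm_ok >= 0.99
        assert rpe_ok >= 0.99

    def test_all_zero_volume_errors(self, small_geom):
        volume = OCTVolume(
            geometry=small_geom,
            intensities=np.zeros(small_geom.shape, dtype=np.float32),
        )
        with pytest.raises(ValueError, match="supra-threshold"):
            delineate_surfaces(volume, "gradient")


class TestReferenceSegmenter:
    def test_band_restriction(self, default_volume):
        volume, surfaces, _ = default_volume
        mask = segment_hrf_reference(volume, surfaces, k_sd=2.0)
        b, z, a = np.nonzero(mask.mask)
        assert np.all(z >= surfaces.ilm[b, a])
        assert np.all(z <= surfaces.rpe[b, a])

    def test_false_positive_rate_without_blobs(self, small_geom):
        """At k_sd=4 the Gaussian tail keeps FP voxels below 0.1% of the band."""
        params = VolumeParams(n_blobs=0, n_fluid=0)
        volume, surfaces, _ = generate_volume(small_geom, params, seed=21)
        mask = segment_hrf_reference(volume, surfaces, k_sd=4.0)
        band_voxels = int((surfaces.rpe - surfaces.ilm).sum())
        assert mask.n_voxels / band_voxels < 1e-3

    def test_high_contrast_dice(self, small_geom):
        params = VolumeParams(n_blobs=8, blob_contrast_sd=8.0, n_fluid=0)
        volume, surfaces, truth = generate_volume(small_geom, params, seed=13)
        mask = segment_hrf_reference(volume, surfaces, k_sd=3.0)
        assert dice_coefficient(mask.mask, truth.hrf_mask) >= 0.8

    def test_monotone_in_threshold(self, default_volume):
        volume, surfaces, _ = default_volume
        m_lo = segment_hrf_reference(volume, surfaces, k_sd=2.0).mask
        m_hi = segment_hrf_reference(volume, surfaces, k_sd=3.5).mask
        assert np.all(m_hi <= m_lo)  # raising k_sd never adds voxels

    def test_degenerate_k_rejected(self, default_volume):
        volume, surfaces, _ = default_volume
        with pytest.raises(ValueError, match="k_sd"):
            segment_hrf_reference(volume, surfaces, k_sd=0.0)

    def test_thin_band_rejected(self, default_volume):
        volume, _, _ = default_volume
        g = volume.geometry
        ilm = np.full((g.n_bscans, g.n_ascans), 10, dtype=np.int32)
        rpe = ilm + 1
        with pytest.raises(ValueError, match="thinner"):
            segment_hrf_reference(volume, SurfacePair(ilm=ilm, rpe=rpe), k_sd=3.0)


class TestDice:
    def test_identity_nonempty(self):
        a = np.zeros((4, 4), bool)
        a[1, 1] = a[2, 2] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, a) == dice_coefficient(a.copy(), a)

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_coefficient(a, b) == 0.0

    def test_hand_computed_half(self):
        # |A| = |B| = 4, |A n B| = 2 -> 2*2 / 8 = 0.5 on a 4x4 toy grid
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0:4] = True
        b[0, 2:4] = True
        b[1, 0:2] = True
        assert dice_coefficient(a, b) == 0.5
        assert dice_coefficient(b, a) == 0.5  # symmetry

    def test_both_empty_is_one(self):
        a = np.zeros((3, 3), bool)
        assert dice_coefficient(a, a) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice_coefficient(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_accuracy_bound(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8)) < 0.2
        b = rng.random((8, 8)) < 0.2
        acc = voxel_accuracy(a, b)
        assert acc >= 1 - (a.sum() + b.sum()) / a.size


def _training_pairs(small_geom, n_volumes=3, seed0=30, **params_kw):
    pairs = []
    for s in range(n_volumes):
        params = VolumeParams(n_blobs=8, **params_kw)
        volume, surfaces, truth = generate_volume(small_geom, params, seed=seed0 + s)
        for b in range(small_geom.n_bscans):
            pairs.append((volume.intensities[b], truth.hrf_mask[b]))
    return pairs


@pytest.fixture(scope="module")
def pairs(small_geom):
    return _training_pairs(small_geom)


@pytest.fixture(scope="module")
def toy_pairs():
    rng = np.random.default_rng(1)
    out = []
    for _ in range(10):
        img = rng.random((16, 16))
        out.append((img, img > 0.8))
    return out


class TestLearnedSegmenter:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_learned_segmenter([])

    def test_determinism(self, pairs):
        m1 = train_learned_segmenter(pairs[:24], seed=5)
        m2 = train_learned_segmenter(pairs[:24], seed=5)
        pred1 = m1.predict(pairs[30][0])
        pred2 = m2.predict(pairs[30][0])
        assert np.array_equal(pred1, pred2)

    def test_blank_bscan_prediction_is_sparse(self, pairs, small_geom):
        model = train_learned_segmenter(pairs[:32], seed=5)
        params = VolumeParams(n_blobs=0, n_fluid=0)
        volume, _, _ = generate_volume(small_geom, params, seed=99)
        pred = model.predict(volume.intensities[0])
        assert pred.mean() < 0.01

    def test_parity_with_reference_on_held_out(self, small_geom):
        """The trained classifier should match or beat band thresholding."""
        train = _training_pairs(small_geom, n_volumes=3, seed0=40)
        model = train_learned_segmenter(train, seed=5)
        volume, surfaces, truth = generate_volume(
            small_geom, VolumeParams(n_blobs=8), seed=77
        )
        ref = segment_hrf_reference(volume, surfaces, k_sd=3.0)
        learned = model.predict_volume(volume, surfaces)
        d_ref = dice_coefficient(ref.mask, truth.hrf_mask)
        d_learned = dice_coefficient(learned.mask, truth.hrf_mask)
        assert d_learned >= d_ref


class TestCrossval:
    def test_partition_is_disjoint_and_complete(self, toy_pairs):
        seen = []

        def trainer(train_pairs, seed):
            class Stub:
                def predict(self, image):
                    return np.zeros_like(image, dtype=bool)

            return Stub()

        metrics = crossval_evaluate(toy_pairs, n_folds=5, seed=0, trainer=trainer)
        assert sum(f["n_test"] for f in metrics.per_fold) == len(toy_pairs)
        assert len(metrics.per_fold) == 5

    def test_perfect_stub_scores_one(self, toy_pairs):
        lookup = {id(img): mask for img, mask in toy_pairs}

        def trainer(train_pairs, seed):
            class Oracle:
                def predict(self, image):
                    return lookup[id(image)]

            return Oracle()

        metrics = crossval_evaluate(toy_pairs, n_folds=5, seed=0, trainer=trainer)
        assert all(f["dice"] == 1.0 for f in metrics.per_fold)
        assert metrics.accuracy == 1.0

    def test_empty_stub_scores_zero_dice(self, toy_pairs):
        def trainer(train_pairs, seed):
            class Empty:
                def predict(self, image):
                    return np.zeros_like(image, dtype=bool)

            return Empty()

        metrics = crossval_evaluate(toy_pairs, n_folds=5, seed=0, trainer=trainer)
        assert metrics.dice == 0.0

    def test_too_many_folds_rejected(self, toy_pairs):
        with pytest.raises(ValueError, match="n_folds"):
            crossval_evaluate(toy_pairs, n_folds=11, seed=0)
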