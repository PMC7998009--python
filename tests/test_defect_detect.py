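import numpy as np
import pytest

from ezquant.defect_detect import (
    FeatureConfig,
    ModelMismatchError,
    TrainingError,
    classify,
    compute_features,
    load_model,
    save_model,
    train_classifier,
)
from ezquant.enface import EnFaceMap, csf_mask
from ezquant.geometry import make_geometry
from ezquant.pipeline import make_eye_volume, train_default_classifier
from ezquant.layer_seg import segment_volume
from ezquant.enface import thickness_map


def _map_from(arr, geometry):
    return EnFaceMap(
        thickness_um=np.asarray(arr, float),
        valid_mask=np.ones_like(arr, bool),
        pixel_dims_mm=(geometry.ascan_pitch_mm, geometry.bscan_pitch_mm),
        fovea_center=geometry.center_grid,
        geometry=geometry,
    )


class TestFeatures:
    def test_constant_map_features(self, cirrus):
        emap = _map_from(np.full(cirrus.en_face_shape, 117.0), cirrus)
        stack = compute_features(emap)
        cfg = FeatureConfig()
        n_sig = len(cfg.smooth_sigmas)
        assert np.allclose(stack[..., 0], 117.0)
        for k in range(1, 1 + n_sig):  # smoothed copies of a constant
            assert np.allclose(stack[..., k], 117.0)
        assert np.allclose(stack[..., 1 + n_sig], 0.0)  # gradient magnitude
        assert np.allclose(stack[..., 2 + n_sig], 0.0, atol=1e-8)  # variance

    def test_step_edge_gradient_peaks_on_edge(self, cirrus):
        arr = np.zeros((12, 12))
        arr[:, 6:] = 100.0
        emap = _map_from(arr, cirrus)
        # finite-difference oracle: the step column pair has the max |d/dx|
        grad = compute_features(emap)[..., 1 + len(FeatureConfig().smooth_sigmas)]
        assert set(np.argmax(grad, axis=1)) <= {5, 6}

    def test_translation_equivariance(self, cirrus):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 120, size=(90, 90))
        shifted = np.roll(arr, (3, 5), axis=(0, 1))
        f1 = compute_features(_map_from(arr, cirrus))
        f2 = compute_features(_map_from(shifted, cirrus))
        # deep-interior pixels, clear of filter boundary effects
        assert np.allclose(f1[30:55, 30:55], f2[33:58, 35:60], atol=1e-6)


class TestTraining:
    def test_oob_accuracy_on_phantoms(self, trained_model):
        assert trained_model.oob_accuracy >= 0.95

    def test_single_class_labels_rejected(self, cirrus):
        emap = _map_from(np.full(cirrus.en_face_shape, 117.0), cirrus)
        labels = np.zeros(cirrus.en_face_shape, bool)
        with pytest.raises(TrainingError):
            train_classifier([(emap, labels)])

    def test_deterministic_model_hash(self, cirrus):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 120, size=cirrus.en_face_shape)
        labels = arr < 30
        emap = _map_from(arr, cirrus)
        kwargs = dict(seed=7, n_estimators=8, max_depth=6, max_train_pixels=20000)
        m1 = train_classifier([(emap, labels)], **kwargs)
        m2 = train_classifier([(emap, labels)], **kwargs)
        assert m1.model_hash() == m2.model_hash()

    def test_label_inversion_symmetry(self, cirrus):
        """Swapping the training labels swaps the decisions."""
        rng = np.random.default_rng(2)
        arr = np.where(rng.random(cirrus.en_face_shape) < 0.3, 0.0, 117.0)
        arr += rng.normal(0, 5, arr.shape)
        truth = arr < 58.0
        emap = _map_from(arr, cirrus)
        kwargs = dict(seed=3, n_estimators=10, max_depth=8, max_train_pixels=30000)
        m_fwd = train_classifier([(emap, truth)], **kwargs)
        m_inv = train_classifier([(emap, ~truth)], **kwargs)
        csf = csf_mask(cirrus)
        fwd = classify(emap, m_fwd, csf).mask
        inv = classify(emap, m_inv, csf).mask
        agree = (fwd == ~inv)[csf.mask].mean()
        assert agree >= 0.95


class TestClassify:
    def test_dark_csf_is_full_defect(self, cirrus, trained_model, cirrus_csf):
        emap = _map_from(np.zeros(cirrus.en_face_shape), cirrus)
        mask = classify(emap, trained_model, cirrus_csf).mask
        assert (mask & cirrus_csf.mask).sum() == cirrus_csf.mask.sum()

    def test_uniform_normal_thickness_is_empty(self, cirrus, trained_model, cirrus_csf):
        emap = _map_from(np.full(cirrus.en_face_shape, 117.0), cirrus)
        res = classify(emap, trained_model, cirrus_csf)
        assert not res.mask.any()
        assert res.probability.min() >= 0.0 and res.probability.max() <= 1.0

    def test_mask_restricted_to_csf(self, cirrus, trained_model, cirrus_csf):
        emap = _map_from(np.zeros(cirrus.en_face_shape), cirrus)
        res = classify(emap, trained_model, cirrus_csf)
        assert not (res.mask & ~cirrus_csf.mask).any()
        assert np.all(res.probability[~cirrus_csf.mask] == 0.0)

    def test_feature_config_hash_mismatch_rejected(
        self, cirrus, trained_model, cirrus_csf
    ):
        emap = _map_from(np.zeros(cirrus.en_face_shape), cirrus)
        other = FeatureConfig(smooth_sigmas=(1.0, 3.0))
        with pytest.raises(ModelMismatchError):
            classify(emap, trained_model, cirrus_csf, feature_config=other)

    def test_heldout_phantom_dice(self, cirrus, trained_model, cirrus_csf):
        dices = []
        for seed, area in [(101, 0.02), (102, 0.08), (103, 0.2)]:
            vol, truth = make_eye_volume(cirrus, area, False, seed=seed, noise_sd=0.1)
            emap = thickness_map(segment_volume(vol), cirrus)
            mask = classify(emap, trained_model, cirrus_csf).mask
            t = truth.defect_mask & cirrus_csf.mask
            dices.append(2 * (mask & t).sum() / (mask.sum() + t.sum()))
        assert min(dices) >= 0.85

    def test_model_round_trip(self, cirrus, trained_model, tmp_path):
        path = tmp_path / "model.pkl"
        save_model(trained_model, path)
        loaded = load_model(path)
        assert loaded.model_hash() == trained_model.model_hash()
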