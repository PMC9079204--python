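"""Preprocessing: view selection, crop geometry, log transform, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scintigrade as sg
from scintigrade.phantom import ScintigraphyStudy
from scintigrade.preprocess import (
    CropWindow,
    apply_window,
    whole_body_window,
)


def _study(view="AP", protocol="whole_body", pixels=None):
    if pixels is None:
        pixels = np.ones((200, 140))
    return ScintigraphyStudy(pixels=pixels, view=view, protocol=protocol)


class TestSelectAnterior:
    def test_keeps_only_ap_in_order(self):
        studies = [_study("AP"), _study("PA"), _study("AP")]
        kept = sg.select_anterior(studies)
        assert kept == [studies[0], studies[2]]

    def test_empty_input(self):
        assert sg.select_anterior([]) == []

    def test_all_pa_yields_empty(self):
        assert sg.select_anterior([_study("PA")] * 5) == []


class TestPatientExtent:
    def test_matches_brute_force_row_scan(self):
        img = np.zeros((10, 10))
        img[2:8] = 1.0
        assert sg.locate_patient_extent(img) == (2, 7)

    def test_single_nonzero_pixel(self):
        img = np.zeros((10, 10))
        img[5, 3] = 2.0
        assert sg.locate_patient_extent(img) == (5, 5)

    def test_all_zero_raises_no_patient(self):
        with pytest.raises(ValueError, match="no patient"):
            sg.locate_patient_extent(np.zeros((4, 4)))


class TestWholeBodyCrop:
    def test_window_arithmetic_on_a_standard_acquisition(self):
        img = np.zeros((1024, 256))
        img[24:984, 100:150] = 1.0  # patient rows 24..983, H = 960
        win = whole_body_window(img)
        assert (win.top_row, win.left_col) == (167, 64)
        out = apply_window(img, win)
        assert out.shape == (128, 128)

    def test_full_height_patient_clamps_to_the_image(self):
        img = np.ones((128, 130))
        win = whole_body_window(img)
        # unclamped top would be round(127 - 0.85*128) = 18; clamped to fit
        assert win.top_row == 0
        assert sg.crop_whole_body(img).shape == (128, 128)

    def test_narrow_image_is_zero_padded_symmetrically(self):
        img = np.ones((300, 100))
        out = sg.crop_whole_body(img)
        assert out.shape == (128, 128)
        assert (out[:, :13] == 0).all() and (out[:, -13:] == 0).all()

    def test_patient_column_center_option(self):
        img = np.zeros((400, 256))
        img[50:350, 10:80] = 1.0  # patient far left of frame
        win = whole_body_window(img, column_center="patient")
        assert win.left_col < 256 // 2 - 64

    def test_oracle_on_phantoms(self):
        """Implementation equals an independent reading of the crop rules."""
        for i in range(10):
            cfg = sg.PhantomConfig(patient_height_fraction=0.8 + 0.018 * i,
                                   seed=50 + i)
            img = sg.generate_whole_body(cfg, grade=1).pixels
            rows = np.nonzero(img.sum(axis=1) > 0)[0]
            top, bottom = rows[0], rows[-1]
            expect_top = int(np.floor(bottom - 0.85 * (bottom - top + 1) + 0.5))
            expect_top = min(max(expect_top, 0), img.shape[0] - 128)
            win = whole_body_window(img)
            assert win.top_row == expect_top
            assert win.left_col == img.shape[1] // 2 - 64


class TestPlanarCrop:
    def test_center_window_of_a_256_matrix(self):
        img = np.arange(256 * 256, dtype=float).reshape(256, 256)
        out = sg.crop_planar(img)
        assert np.array_equal(out, img[64:192, 64:192])

    def test_large_matrix_is_downsampled_then_cropped(self):
        out = sg.crop_planar(np.ones((512, 512)))
        assert out.shape == (128, 128)

    def test_constant_input_stays_constant(self):
        out = sg.crop_planar(np.full((512, 512), 3.5))
        assert np.allclose(out, 3.5)

    def test_small_image_zero_padded(self):
        out = sg.crop_planar(np.ones((100, 100)))
        assert out.shape == (128, 128)
        assert out.sum() == pytest.approx(100 * 100)


class TestLogTransform:
    def test_closed_form_values(self):
        assert sg.log_transform(np.array([0.0]))[0] == 0.0
        assert sg.log_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    def test_hot_spot_compression(self):
        """A hot spot 100x brighter than bone at 10 counts shrinks to
        ln(1001)/ln(11) ~ 2.88x in the transformed image."""
        ratio = sg.log_transform(np.array([1000.0]))[0] / \
            sg.log_transform(np.array([10.0]))[0]
        assert ratio == pytest.approx(np.log(1001) / np.log(11), abs=1e-12)
        assert ratio < 3

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            sg.log_transform(np.array([-1.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_order_preserving(self, a, b):
        fa = sg.log_transform(np.array([a]))[0]
        fb = sg.log_transform(np.array([b]))[0]
        if a < b:
            assert fa < fb
        elif a == b:
            assert fa == fb


class TestNormalization:
    def test_identical_images_give_zero_std(self):
        img = np.random.default_rng(0).random((128, 128))
        stats = sg.compute_norm_stats([img, img])
        assert np.array_equal(stats.mean_image, img)
        assert (stats.std_image == 0).all()

    def test_hand_computed_mean_and_std(self):
        stats = sg.compute_norm_stats([np.zeros((128, 128)),
                                       np.full((128, 128), 2.0)])
        assert (stats.mean_image == 1.0).all() and (stats.std_image == 1.0).all()

    def test_fewer_than_two_images_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            sg.compute_norm_stats([np.zeros((128, 128))])

    def test_mean_image_maps_to_zero(self):
        rng = np.random.default_rng(1)
        imgs = [rng.random((128, 128)) for _ in range(5)]
        stats = sg.compute_norm_stats(imgs)
        assert np.allclose(sg.zscore_apply(stats.mean_image, stats), 0.0)

    def test_epsilon_guard_keeps_values_finite(self):
        img = np.random.default_rng(2).random((128, 128))
        stats = sg.compute_norm_stats([img, img])  # std all zero
        z = sg.zscore_apply(img + 1e-3, stats)
        assert np.isfinite(z).all()

    def test_shape_mismatch_raises(self):
        stats = sg.compute_norm_stats([np.zeros((128, 128))] * 2)
        with pytest.raises(ValueError, match="mismatch"):
            sg.zscore_apply(np.zeros((64, 64)), stats)

    def test_stats_ignore_anything_outside_the_training_set(self):
        rng = np.random.default_rng(3)
        train = [rng.random((128, 128)) for _ in range(4)]
        s1 = sg.compute_norm_stats(train)
        s2 = sg.compute_norm_stats(train)  # test images never enter
        assert np.array_equal(s1.mean_image, s2.mean_image)


class TestZScoreNormalizerEstimator:
    def test_sklearn_clone_compatibility(self):
        from sklearn.base import clone

        norm = sg.ZScoreNormalizer(epsilon=1e-6)
        assert clone(norm).get_params() == {"epsilon": 1e-6}

    def test_fit_transform_standardises_training_data(self):
        X = np.random.default_rng(4).random((6, 16, 16))
        z = sg.ZScoreNormalizer().fit_transform(X)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)


def test_preprocessing_is_deterministic(small_preprocessed_set):
    ids = [im.source_id for im in small_preprocessed_set]
    assert len(set(ids)) == len(ids)
    for im in small_preprocessed_set:
        assert im.pixels.shape == (128, 128)
        assert (im.pixels >= 0).all()


def test_apply_window_zero_pads_out_of_bounds_regions():
    img = np.ones((100, 100))
    out = apply_window(img, CropWindow(-20, -20))
    assert out.shape == (128, 128)
    assert out[:20].sum() == 0 and out[20:120, 20:120].sum() == 100 * 100
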