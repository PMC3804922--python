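"""ROI grid construction, plane-fit features, and signal conditioning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

import echoforce as ef
from echoforce.errors import (GeometryError, InvalidInputError,
                              InvalidParameterError)
from echoforce.features import features_from_csv, features_to_csv


def brute_force_plane_fit(patch, cx, cy, radius):
    """Independent oracle: general 3-parameter linear least squares."""
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    design = np.column_stack([cx - xx[inside], cy - yy[inside],
                              np.ones(inside.sum())])
    coef, *_ = np.linalg.lstsq(design, patch[inside], rcond=None)
    return coef


class TestBuildRoiGrid:
    def test_small_full_mask_enumeration(self):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        expected = {(25, 25), (25, 75), (75, 25), (75, 75)}
        assert {tuple(c) for c in grid.centers} == expected

    def test_no_fitting_disc_raises(self):
        with pytest.raises(GeometryError):
            ef.build_roi_grid(np.ones((100, 100), dtype=bool), radius=60)

    def test_empty_mask_raises(self):
        with pytest.raises(GeometryError):
            ef.build_roi_grid(np.zeros((100, 100), dtype=bool))

    def test_all_discs_inside_mask(self):
        mask = ef.default_content_mask(300, 260)
        grid = ef.build_roi_grid(mask)
        for cx, cy in grid.centers:
            yy, xx = np.mgrid[cy - 20:cy + 21, cx - 20:cx + 21]
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= 400
            assert mask[yy[disc], xx[disc]].all()

    def test_invariant_to_padding_that_changes_nothing(self):
        mask = ef.default_content_mask(300, 260)
        padded = mask.copy()
        padded[:2, :] = False  # strip no disc reaches (lattice starts at 25)
        g1 = ef.build_roi_grid(mask)
        g2 = ef.build_roi_grid(padded)
        np.testing.assert_array_equal(g1.centers, g2.centers)

    def test_json_round_trip(self, tmp_path):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        path = tmp_path / "grid.json"
        grid.to_json(path)
        back = ef.ROIGrid.from_json(path)
        np.testing.assert_array_equal(back.centers, grid.centers)
        assert back.radius == grid.radius


class TestFitRoiPlane:
    def test_constant_image(self):
        img = np.full((60, 60), 42.0)
        a, b, c = ef.fit_roi_plane(img, (30, 30), 20)
        assert (a, b) == (0.0, 0.0)
        assert c == pytest.approx(42.0)

    def test_horizontal_ramp(self):
        # g(x, y) = x solves alpha (x_i - x) + gamma = x with alpha=-1, gamma=x_i
        yy, xx = np.mgrid[0:60, 0:60]
        a, b, c = ef.fit_roi_plane(xx.astype(float), (31, 28), 20)
        assert a == pytest.approx(-1.0)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(31.0)

    def test_matches_least_squares_oracle_on_random_patches(self, rng):
        for _ in range(100):
            patch = rng.uniform(0, 255, size=(41, 41))
            got = np.array(ef.fit_roi_plane(patch, (20, 20), 20))
            want = brute_force_plane_fit(patch, 20, 20, 20)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_disc_outside_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            ef.fit_roi_plane(np.zeros((30, 30)), (5, 5), 20)


class TestExtractFeatures:
    def test_vector_length_and_order(self):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        img = np.full((100, 100), 7.0)
        v = ef.extract_features(img, grid)
        assert v.shape == (grid.feature_dim,) == (12,)
        np.testing.assert_allclose(v.reshape(-1, 3)[:, :2], 0.0, atol=1e-12)
        np.testing.assert_allclose(v.reshape(-1, 3)[:, 2], 7.0)

    def test_matches_per_roi_plane_fits(self, rng):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        img = rng.uniform(0, 255, size=(100, 100))
        v = ef.extract_features(img, grid).reshape(-1, 3)
        for i, center in enumerate(grid.centers):
            np.testing.assert_allclose(
                v[i], ef.fit_roi_plane(img, center, grid.radius), rtol=1e-12)

    def test_linearity_in_pixel_intensities(self, rng):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        img1 = rng.uniform(0, 255, size=(100, 100))
        img2 = rng.uniform(0, 255, size=(100, 100))
        lhs = ef.extract_features(0.3 * img1 + 1.7 * img2, grid)
        rhs = (0.3 * ef.extract_features(img1, grid)
               + 1.7 * ef.extract_features(img2, grid))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-10)

    def test_linear_in_rendered_forces(self, clean_scene, rng):
        # features of rendered frames follow the map built from unit renders
        grid = ef.build_roi_grid(
            ef.default_content_mask(clean_scene.width, clean_scene.height))
        base = ef.extract_features(
            ef.render_frame(clean_scene, np.zeros(5)), grid)
        M = np.stack([
            ef.extract_features(ef.render_frame(clean_scene, np.eye(5)[i]),
                                grid) - base
            for i in range(5)], axis=1)
        f = rng.uniform(0, 0.8, size=5)
        got = ef.extract_features(ef.render_frame(clean_scene, f), grid)
        np.testing.assert_allclose(got, base + M @ f, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        grid = ef.build_roi_grid(np.ones((100, 100), dtype=bool))
        with pytest.raises(InvalidInputError):
            ef.extract_features(np.zeros((90, 100)), grid)

    def test_csv_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(4, 9))
        path = tmp_path / "feats.csv"
        features_to_csv(X, path)
        np.testing.assert_allclose(features_from_csv(path), X)


@given(st.integers(0, 2 ** 31 - 1))
def test_plane_fit_equals_oracle_property(seed):
    """Decoupled plane fit == generic least squares on any patch."""
    patch = np.random.default_rng(seed).uniform(0, 255, size=(31, 31))
    got = np.array(ef.fit_roi_plane(patch, (15, 15), 15))
    want = brute_force_plane_fit(patch, 15, 15, 15)
    np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.5)
        np.testing.assert_allclose(ef.lowpass_filter(x), x, rtol=1e-12)

    def test_minus_3db_at_cutoff(self):
        fs, f0 = 30.0, 1.0
        t = np.arange(6000) / fs
        y = ef.lowpass_filter(np.sin(2 * np.pi * f0 * t), cutoff=f0, fs=fs)
        tail = y[3000:]
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean((tail - tail.mean()) ** 2))
        assert amplitude == pytest.approx(1.0 / np.sqrt(2.0), rel=0.01)

    def test_impulse_tail_decays_monotonically(self):
        x = np.zeros(50)
        x[0] = 1.0
        y = ef.lowpass_filter(x)
        tail = y[2:]
        assert np.all(np.diff(np.abs(tail)) <= 0)

    def test_multichannel_matches_per_channel(self, rng):
        X = rng.normal(size=(100, 3))
        Y = ef.lowpass_filter(X)
        for j in range(3):
            np.testing.assert_allclose(Y[:, j], ef.lowpass_filter(X[:, j]))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            ef.lowpass_filter(np.zeros(10), cutoff=20.0, fs=30.0)

    def test_matches_scipy_steady_state(self, rng):
        # same coefficients as a directly designed first-order Butterworth
        x = rng.normal(size=300)
        b, a = signal.butter(1, 1.0, fs=30.0)
        zi = signal.lfilter_zi(b, a) * x[0]
        want, _ = signal.lfilter(b, a, x, zi=zi)
        np.testing.assert_allclose(ef.lowpass_filter(x), want, rtol=1e-12)
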