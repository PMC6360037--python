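"""Plane projections, triplet angles, spectral features, windowing."""

import math

import numpy as np
import pytest

from gaitdx import features as ft
from gaitdx import io as gio
from gaitdx.errors import DegenerateGeometryError, TrialTooShortError
from gaitdx.preprocess import StepSummary


def law_of_cosines_angle(p1, vertex, p3):
    """Independent oracle: interior angle from the three side lengths."""
    a = math.dist(vertex, p1)
    b = math.dist(vertex, p3)
    c = math.dist(p1, p3)
    cosang = (a * a + b * b - c * c) / (2 * a * b)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


class TestProjection:
    @pytest.mark.parametrize(
        "plane,expected",
        [("sagittal", (1.0, 3.0)), ("frontal", (2.0, 3.0)), ("transverse", (1.0, 2.0))],
    )
    def test_orthographic_drop(self, plane, expected):
        assert tuple(ft.project_to_plane(np.array([1.0, 2.0, 3.0]), plane)) == expected

    def test_unknown_plane_rejected(self):
        with pytest.raises(ValueError):
            ft.project_to_plane(np.zeros(3), "coronal-ish")


class TestTripletAngle:
    def test_orthogonal_rays(self):
        assert ft.triplet_angle((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_collinear_opposite(self):
        assert ft.triplet_angle((1, 0), (0, 0), (-1, 0)) == pytest.approx(180.0)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            pts = rng.normal(scale=100.0, size=(3, 2))
            if min(np.linalg.norm(pts[0] - pts[1]), np.linalg.norm(pts[2] - pts[1])) < 1e-3:
                continue
            ours = ft.triplet_angle(pts[0], pts[1], pts[2])
            ref = law_of_cosines_angle(pts[0], pts[1], pts[2])
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            ft.triplet_angle((0, 0), (0, 0), (1, 1))


class TestAngleSeries:
    def test_81_angles_per_frame(self, trimmed_series):
        assert trimmed_series.values.shape[1] == 81
        assert len(ft.TRIPLETS) == 27
        assert np.all(trimmed_series.values >= 0.0)
        assert np.all(trimmed_series.values <= 180.0)

    def test_constructed_sagittal_angle(self):
        # place LGT and LLE on rays 60 degrees apart at vertex LPSIS (X-Z plane)
        rng = np.random.default_rng(1)
        base = rng.normal(scale=300.0, size=(19, 3)) + [0, 0, 800]
        i_lgt, i_lpsis, i_lle = (
            gio.MARKER_INDEX["LGT"], gio.MARKER_INDEX["LPSIS"], gio.MARKER_INDEX["LLE"],
        )
        v = base[i_lpsis]
        base[i_lgt] = v + [200.0, 50.0, 0.0]  # along +X in sagittal
        base[i_lle] = v + [
            300.0 * math.cos(math.radians(60.0)), -70.0,
            300.0 * math.sin(math.radians(60.0)),
        ]
        trial = gio.Trial(np.stack([base, base]), 50.0)
        series = ft.angle_series(trial, StepSummary(1, 1.0))
        assert series.values[0, 0] == pytest.approx(60.0, abs=1e-6)

    def test_invariance_to_translation_and_scaling(self, trimmed_series, trial_and_events):
        from gaitdx import preprocess as pp

        trial, gt = trial_and_events
        sub = pp.subsample(trial, 2)
        trimmed, steps = pp.trim_to_complete_steps(sub, gt.scaled(2))
        moved = gio.Trial(
            trimmed.positions * 2.5 + np.array([1000.0, -500.0, 30.0]),
            trimmed.frame_rate, trimmed.patient_id, trimmed.form,
        )
        series2 = ft.angle_series(moved, steps)
        assert np.allclose(series2.values, trimmed_series.values, atol=1e-8)

    def test_degenerate_triplet_identifies_frame(self):
        pos = np.abs(np.random.default_rng(2).normal(scale=200.0, size=(3, 19, 3)))
        # collapse LGT onto RGT in the sagittal projection (equal X and Z)
        i_l, i_r = gio.MARKER_INDEX["LGT"], gio.MARKER_INDEX["RGT"]
        pos[1, i_l] = pos[1, i_r] + [0.0, 150.0, 0.0]
        trial = gio.Trial(pos, 50.0)
        with pytest.raises(DegenerateGeometryError, match="frame 1"):
            ft.angle_series(trial, StepSummary(1, 1.0))


def brute_force_step_harmonics(values, n_steps):
    """O(n^2) DFT oracle: amplitudes at bins 0, N, ..., 19N, normalized."""
    F, A = values.shape
    out = np.empty((A, 20))
    for a in range(A):
        amps = []
        for h in range(20):
            k = h * n_steps
            re = sum(values[t, a] * math.cos(-2 * math.pi * k * t / F) for t in range(F))
            im = sum(values[t, a] * math.sin(-2 * math.pi * k * t / F) for t in range(F))
            amps.append(math.hypot(re, im))
        fund = amps[1]
        row = [amps[0]] + [x / fund if fund > 1e-12 else 0.0 for x in amps[1:]]
        out[a] = row
    return out


class TestSpectralFeatures:
    def test_constant_series_has_dc_only(self):
        values = np.full((80, 81), 37.5)
        series = ft.AngleSeries(values, 50.0, 2)
        sf = ft.spectral_features(series)
        assert np.allclose(sf.coeffs[:, 0], 80 * 37.5)
        assert np.allclose(sf.coeffs[:, 1:], 0.0)

    def test_pure_cosine_at_step_frequency(self):
        F, n = 160, 4
        t = np.arange(F)
        values = 90.0 + 30.0 * np.cos(2 * np.pi * n * t / F)[:, None] * np.ones((1, 81))
        sf = ft.spectral_features(ft.AngleSeries(values, 50.0, n))
        assert np.allclose(sf.coeffs[:, 1], 1.0)
        assert np.all(sf.coeffs[:, 2:] <= 1e-9)

    @pytest.mark.parametrize("n_steps", [1, 2, 3, 5])
    def test_matches_brute_force_dft_oracle(self, n_steps):
        rng = np.random.default_rng(n_steps)
        F = 20 * n_steps + rng.integers(0, 7)
        values = rng.uniform(10.0, 170.0, size=(F, 81))
        series = ft.AngleSeries(values, 50.0, n_steps)
        ours = ft.spectral_features(series).coeffs
        ref = brute_force_step_harmonics(values, n_steps)
        assert np.allclose(ours, ref, atol=1e-9 * max(1.0, np.abs(ref).max()))

    def test_time_reversal_leaves_amplitudes_unchanged(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0.0, 180.0, size=(90, 81))
        fwd = ft.spectral_features(ft.AngleSeries(values, 50.0, 3)).coeffs
        rev = ft.spectral_features(ft.AngleSeries(values[::-1], 50.0, 3)).coeffs
        assert np.allclose(fwd, rev, atol=1e-9 * max(1.0, fwd.max()))

    def test_too_short_series_rejected(self):
        series = ft.AngleSeries(np.full((59, 81), 20.0), 50.0, 3)
        with pytest.raises(ValueError, match="short"):
            ft.spectral_features(series)

    def test_flat_rows_zero_filled_not_fatal(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(10.0, 170.0, size=(80, 81))
        values[:, 17] = 42.0  # one flat angle
        sf = ft.spectral_features(ft.AngleSeries(values, 50.0, 2))
        assert np.allclose(sf.coeffs[17, 1:], 0.0)
        assert sf.coeffs[17, 0] == pytest.approx(80 * 42.0)


class TestWindowing:
    @pytest.mark.parametrize(
        "frames,expected",
        [(75, 1), (76, 1), (90, 2), (735, 45), (800, 45), (2000, 45)],
    )
    def test_window_count_formula(self, frames, expected):
        values = np.full((frames, 81), 90.0)
        ws = ft.window_sequences(ft.AngleSeries(values, 50.0, 4))
        assert len(ws.windows) == expected
        assert ft.n_windows(frames) == expected

    def test_too_short_trial_rejected(self):
        values = np.full((74, 81), 90.0)
        with pytest.raises(TrialTooShortError):
            ft.window_sequences(ft.AngleSeries(values, 50.0, 2))

    def test_windows_are_exact_slices_15_apart(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.0, 180.0, size=(120, 81))
        ws = ft.window_sequences(ft.AngleSeries(values, 50.0, 3))
        assert len(ws.windows) == 4
        for k, w in enumerate(ws.windows):
            assert np.array_equal(w, values[15 * k : 15 * k + 75])
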