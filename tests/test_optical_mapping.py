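"""Optical-mapping pipeline: filtering, ΔF/F, activation detection,
gradient conduction velocity, and wavefront-origin counting."""

import numpy as np
import pytest

from conftest import make_calcium_fixture
from photopace import optical_mapping as om
from photopace import synthetic as syn
from photopace.types import ActivationMap, Movie


def _movie(frames, frame_rate=400.0, pixel_size=1e-4):
    return Movie(frames=np.asarray(frames, float), frame_rate=frame_rate,
                 pixel_size=pixel_size, kind="fluorescence")


def _plane_map(angle_rad, speed, rows=24, cols=40, pixel_size=1e-4, offset=0.0):
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    T = (cc * np.cos(angle_rad) + rr * np.sin(angle_rad)) * pixel_size / speed
    T -= T.min() - offset
    return ActivationMap(T=T, valid=np.ones_like(T, bool), frame_rate=400.0,
                         pixel_size=pixel_size)


class TestSpatialFilter:
    def test_constant_image_unchanged(self):
        movie = _movie(np.full((3, 8, 8), 42.0))
        assert np.allclose(om.spatial_filter(movie).frames, 42.0)

    def test_impulse_spreads_to_ninth(self):
        frames = np.zeros((2, 9, 9))
        frames[:, 4, 4] = 1.0
        out = om.spatial_filter(_movie(frames)).frames
        assert np.allclose(out[0, 3:6, 3:6], 1.0 / 9.0)
        assert np.allclose(out[0].sum(), 1.0)

    def test_interior_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 100, size=(2, 8, 8))
        out = om.spatial_filter(_movie(frames)).frames
        for r in range(1, 7):
            for c in range(1, 7):
                assert np.isclose(
                    out[0, r, c], frames[0, r - 1 : r + 2, c - 1 : c + 2].mean()
                )

    def test_rejects_tiny_movie(self):
        with pytest.raises(ValueError, match="3x3"):
            om.spatial_filter(_movie(np.ones((2, 2, 5))))


class TestNormalizeDff:
    def test_constant_trace_maps_to_zero(self):
        movie = _movie(np.full((10, 4, 4), 80.0))
        assert np.allclose(om.normalize_dff(movie).frames, 0.0)

    def test_half_amplitude_peak(self):
        frames = np.full((20, 3, 3), 100.0)
        frames[10] = 150.0
        out = om.normalize_dff(_movie(frames)).frames
        assert np.isclose(out[10, 1, 1], 0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        frames = 100.0 + 50.0 * rng.uniform(size=(30, 4, 4))
        a = om.normalize_dff(_movie(frames)).frames
        b = om.normalize_dff(_movie(3.0 * frames)).frames
        assert np.allclose(a, b)


class TestSegmentBeats:
    def test_three_paced_beats(self):
        field, movie = make_calcium_fixture(noise_sd=0.0, n_beats=3)
        dff = om.normalize_dff(om.spatial_filter(movie))
        windows = om.segment_beats(dff, pacing_frequency=1.0)
        assert len(windows) == 3
        assert all(350 <= e - s <= 400 for s, e in windows)

    def test_single_beat_single_window(self):
        field, movie = make_calcium_fixture(noise_sd=0.0, n_beats=1)
        windows = om.segment_beats(om.normalize_dff(movie))
        assert len(windows) == 1
        assert windows[0] == (0, movie.n_frames)

    def test_windows_disjoint_and_ordered(self):
        field, movie = make_calcium_fixture(noise_sd=5.0, seed=9, n_beats=3)
        windows = om.segment_beats(om.normalize_dff(om.spatial_filter(movie)))
        for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
            assert e0 <= s1
            assert s0 < e0

    def test_flat_movie_has_no_beats(self):
        with pytest.raises(ValueError, match="no beats"):
            om.segment_beats(_movie(np.full((10, 4, 4), 1.0)))


class TestActivationTimes:
    def test_ideal_step(self):
        # a sampled step at frame 25 localizes to within half a frame under
        # either criterion (linear interpolation places the 50% crossing at
        # the inter-frame midpoint)
        frames = np.zeros((40, 5, 5))
        frames[25:] = 1.0
        movie = _movie(frames)
        # the centered difference ties on the two frames bracketing a step,
        # so max_derivative resolves only to +-1 frame
        for method, tol_frames in (("half_amplitude", 0.51), ("max_derivative", 1.01)):
            amap = om.activation_times(movie, (0, 40), method=method)
            assert np.allclose(amap.T, 25.0 / 400.0, atol=tol_frames / 400.0)

    def test_linear_ramp_crosses_at_midpoint(self):
        frames = np.zeros((40, 4, 4))
        ramp = np.linspace(0, 1, 21)
        frames[10:31] = ramp[:, None, None]
        frames[31:] = 1.0
        amap = om.activation_times(_movie(frames), (0, 40), method="half_amplitude")
        assert np.allclose(amap.T, 20.0 / 400.0)

    def test_low_amplitude_pixels_are_invalid(self):
        frames = np.zeros((30, 4, 4))
        frames[15:] = 1.0
        frames[:, 0, 0] = 0.0  # dead pixel: no upstroke
        amap = om.activation_times(_movie(frames), (0, 30))
        assert not amap.valid[0, 0]
        assert amap.valid[2, 2]

    def test_rendered_fixture_times_match_truth(self):
        field, movie = make_calcium_fixture(noise_sd=5.0, seed=6, n_beats=1)
        dff = om.normalize_dff(om.spatial_filter(movie))
        amap = om.activation_times(dff, (0, movie.n_frames))
        # constant rise/2 offset between truth (wave arrival) and the 50%
        # crossing cancels nowhere, so compare after removing the median shift
        delta = amap.T - field.T
        delta -= np.median(delta)
        assert np.percentile(np.abs(delta[amap.valid]), 99) < 1.5 / 400.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            om.activation_times(_movie(np.ones((10, 4, 4))), (5, 6))


class TestConductionVelocity:
    def test_plane_wave_speed(self):
        amap = _plane_map(0.0, 0.042)
        field = om.conduction_velocity(amap)
        assert abs(field.mean_speed - 0.042) / 0.042 < 0.01
        assert abs(field.median_speed - 0.042) / 0.042 < 0.01

    def test_fifty_random_plane_waves(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            angle = rng.uniform(0, 2 * np.pi)
            speed = rng.uniform(0.01, 0.10)
            field = om.conduction_velocity(_plane_map(angle, speed))
            assert abs(field.mean_speed - speed) / speed < 0.01
            vx = np.nanmean(field.vx[field.valid])
            vy = np.nanmean(field.vy[field.valid])
            measured = np.arctan2(vy, vx)
            err = np.degrees(np.angle(np.exp(1j * (measured - angle))))
            assert abs(err) < 2.0

    def test_constant_map_has_no_front(self):
        T = np.zeros((10, 10))
        amap = ActivationMap(T=T, valid=np.ones_like(T, bool), frame_rate=400.0,
                             pixel_size=1e-4)
        with pytest.raises(ValueError, match="no propagating front"):
            om.conduction_velocity(amap)

    def test_radial_wave_speed_off_source(self):
        v = 0.039
        field = syn.make_activation_field(31, 31, 1e-4, "point", (15, 15), v)
        amap = ActivationMap(T=field.T, valid=np.ones_like(field.T, bool),
                             frame_rate=400.0, pixel_size=1e-4)
        out = om.conduction_velocity(amap)
        rr, cc = np.mgrid[0:31, 0:31]
        far = (np.hypot(rr - 15, cc - 15) > 4) & out.valid
        assert np.allclose(out.speed[far], v, rtol=0.02)

    def test_speed_invariant_under_time_offset_and_rotation(self):
        base = _plane_map(0.7, 0.05)
        shifted = ActivationMap(T=base.T + 1.0, valid=base.valid, frame_rate=400.0,
                                pixel_size=1e-4)
        assert np.isclose(om.conduction_velocity(base).mean_speed,
                          om.conduction_velocity(shifted).mean_speed)
        rotated = ActivationMap(T=np.rot90(base.T).copy(), valid=np.rot90(base.valid).copy(),
                                frame_rate=400.0, pixel_size=1e-4)
        assert np.isclose(om.conduction_velocity(base).mean_speed,
                          om.conduction_velocity(rotated).mean_speed, rtol=1e-6)


class TestCountWavefronts:
    def test_edge_fixture_single_wave(self):
        field = syn.make_activation_field(20, 60, 1e-4, "edge", (10, 0), 0.042)
        amap = ActivationMap(T=field.T, valid=np.ones_like(field.T, bool),
                             frame_rate=400.0, pixel_size=1e-4)
        report = om.count_wavefronts(amap)
        assert report.classification == "edge_wave"
        assert report.n_fronts == 1
        assert report.origin_columns[0] <= 2

    def test_center_point_source_double_wave(self):
        field = syn.make_activation_field(20, 60, 1e-4, "point", (10, 30), 0.039)
        amap = ActivationMap(T=field.T, valid=np.ones_like(field.T, bool),
                             frame_rate=400.0, pixel_size=1e-4)
        report = om.count_wavefronts(amap)
        assert report.classification == "point_source_double_wave"
        assert report.n_fronts == 2
        assert abs(report.origin_columns[0] - 30) <= 2

    def test_two_synchronized_sources(self):
        a = syn.make_activation_field(20, 80, 1e-4, "point", (10, 20), 0.04)
        b = syn.make_activation_field(20, 80, 1e-4, "point", (10, 60), 0.04)
        T = np.minimum(a.T, b.T)
        amap = ActivationMap(T=T, valid=np.ones_like(T, bool), frame_rate=400.0,
                             pixel_size=1e-4)
        report = om.count_wavefronts(amap)
        assert report.n_origins == 2
        assert report.classification == "multiple_sources"

    def test_narrow_region_rejected(self):
        T = np.zeros((10, 3))
        amap = ActivationMap(T=T, valid=np.ones_like(T, bool), frame_rate=400.0,
                             pixel_size=1e-4)
        with pytest.raises(ValueError, match="narrower"):
            om.count_wavefronts(amap)


class TestFullPipeline:
    def test_time_shift_commutes_through_pipeline(self):
        # rolling a periodic movie by one beat period permutes each pixel's
        # trace, so the percentile baseline is bit-identical and the
        # activation times shift by exactly one period
        field, movie = make_calcium_fixture(noise_sd=0.0, n_beats=2, cols=30)
        k = 400  # one 1 Hz beat at 400 fps
        shifted = Movie(frames=np.roll(movie.frames, k, axis=0),
                        frame_rate=movie.frame_rate, pixel_size=movie.pixel_size,
                        kind="fluorescence")
        a = om.activation_times(om.normalize_dff(om.spatial_filter(movie)), (0, 400))
        b = om.activation_times(om.normalize_dff(om.spatial_filter(shifted)), (k, k + 400))
        assert np.allclose(b.T - a.T, k / movie.frame_rate, atol=1e-9)

    def test_noise_robustness_at_ten_percent(self):
        field, movie = make_calcium_fixture(speed=0.042, noise_sd=10.0, seed=13)
        result = om.analyze_calcium_movie(movie, pacing_frequency=1.0)
        assert abs(result.speed - 0.042) / 0.042 < 0.05

    def test_point_source_analysis_classifies_double_front(self):
        field, movie = make_calcium_fixture(speed=0.039, source_kind="point", seed=14)
        result = om.analyze_calcium_movie(movie, pacing_frequency=1.0)
        assert result.wavefront.n_fronts == 2
        assert abs(result.speed - 0.039) / 0.039 < 0.05
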