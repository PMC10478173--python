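"""PIV engine: correlation oracle checks, validation, traces and summaries."""

import numpy as np
import pytest
from scipy import ndimage, signal

from myoscreen.piv import (
    PivConfig,
    VelocityField,
    contraction_trace,
    correlate_pass,
    detect_peaks,
    direction_summary,
    multipass_piv,
    validate_vectors,
)
from myoscreen.synthetic import MovieSpec, make_contraction_movie

from conftest import speckle


def full_frame_shift_oracle(frame_a, frame_b):
    """Independent oracle: argmax of the full-frame cross-correlation."""
    a0 = frame_a - frame_a.mean()
    b0 = frame_b - frame_b.mean()
    corr = signal.fftconvolve(b0, a0[::-1, ::-1], mode="full")
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    return ix - (frame_a.shape[1] - 1), iy - (frame_a.shape[0] - 1)


class TestCorrelatePass:
    def test_identity_frames_give_zero_displacement(self):
        tex = speckle(0)
        res = correlate_pass(tex, tex, 64, 0.5)
        assert np.allclose(res["dx"], 0.0) and np.allclose(res["dy"], 0.0)
        assert res["valid"].all()

    @pytest.mark.parametrize("shift", [(3, 0), (0, 2), (4, 5), (-3, 1)])
    def test_integer_shift_matches_full_frame_oracle(self, shift):
        tex = speckle(1)
        moved = np.roll(tex, (shift[1], shift[0]), axis=(0, 1))
        odx, ody = full_frame_shift_oracle(tex, moved)
        assert (odx, ody) == shift
        res = correlate_pass(tex, moved, 64, 0.5)
        assert np.array_equal(np.round(res["dx"]), np.full_like(res["dx"], odx))
        assert np.array_equal(np.round(res["dy"]), np.full_like(res["dy"], ody))

    @pytest.mark.parametrize("sub", [0.25, 0.5, 0.75])
    def test_subpixel_shift_recovered(self, sub):
        tex = speckle(2)
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        moved = ndimage.map_coordinates(tex, np.stack([yy - sub, xx]),
                                        order=1, mode="nearest")
        res = correlate_pass(tex, moved, 64, 0.5)
        assert abs(res["dy"].mean() - sub) <= 0.1
        assert abs(res["dx"].mean()) <= 0.05

    def test_zero_variance_window_flagged_invalid(self):
        a = np.zeros((64, 64))
        a[:32] = speckle(3, 128)[:32, :64]
        res = correlate_pass(a, a, 32, 0.0)
        assert not res["valid"][1, :].all()  # constant bottom half
        assert res["valid"][0, :].all()

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            correlate_pass(np.zeros((64, 64)), np.zeros((32, 32)), 16)


class TestMultipass:
    def test_uniform_shift_equals_finest_pass_with_predictor(self):
        tex = speckle(4)
        moved = np.roll(tex, (3, 3), axis=(0, 1))
        field = multipass_piv(tex, moved, PivConfig())
        dx, dy = field.displacement_px
        single = correlate_pass(
            tex, moved, 16, 0.5,
            predictor=(np.full_like(dx, 3, dtype=int),
                       np.full_like(dy, 3, dtype=int)),
        )
        assert np.allclose(dx[field.valid], single["dx"][field.valid])
        assert np.allclose(dy[field.valid], single["dy"][field.valid])

    def test_zero_motion_below_noise_floor(self):
        spec = MovieSpec(height_px=96, width_px=96, n_frames=4,
                         amplitude_um=0.0, noise_sigma=0.005, seed=6)
        movie, _ = make_contraction_movie(spec)
        field = multipass_piv(movie[0], movie[1], PivConfig())
        dx, dy = field.displacement_px
        assert np.hypot(dx, dy)[field.valid].max() < 0.05

    def test_amplitude_linearity_of_mean_speed(self):
        kw = dict(height_px=96, width_px=96, n_frames=10, seed=8,
                  pulse_times_s=(0.1,), pulse_width_s=0.4, noise_sigma=0.003)
        m1, _ = make_contraction_movie(MovieSpec(amplitude_um=2.0, **kw))
        m2, _ = make_contraction_movie(MovieSpec(amplitude_um=4.0, **kw))
        cfg = PivConfig(window_sizes_px=(32, 16))
        t1 = contraction_trace(m1, cfg)
        t2 = contraction_trace(m2, cfg)
        ratio = np.nanmax(t2.mean_speed_um_s) / np.nanmax(t1.mean_speed_um_s)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_scale_equivariance_in_calibration(self):
        tex = speckle(5)
        moved = np.roll(tex, (2, 0), axis=(0, 1))
        f1 = multipass_piv(tex, moved, PivConfig(), dt_s=0.05, pixel_size_um=1.0)
        f2 = multipass_piv(tex, moved, PivConfig(), dt_s=0.05, pixel_size_um=2.0)
        f3 = multipass_piv(tex, moved, PivConfig(), dt_s=0.025, pixel_size_um=1.0)
        assert np.allclose(f2.v_y, 2.0 * f1.v_y)
        assert np.allclose(f3.v_y, 2.0 * f1.v_y)


class TestValidateVectors:
    @staticmethod
    def _field(vx, vy, valid=None):
        n = vx.shape
        valid = np.ones(n, bool) if valid is None else valid
        gx, gy = np.meshgrid(np.arange(n[1]), np.arange(n[0]))
        return VelocityField(gx, gy, vx, vy, valid, dt_s=0.05, pixel_size_um=1.0)

    def test_single_gross_outlier_invalidated(self):
        rng = np.random.default_rng(0)
        vx = rng.normal(0, 1, (10, 10))
        vy = rng.normal(0, 1, (10, 10))
        vx[4, 4] = 50.0
        field = self._field(vx, vy)
        # direct-computation oracle: only the planted vector exceeds 7 SD
        mu, sd = vx.mean(), vx.std()
        assert np.abs(vx - mu).max() > 7 * sd
        assert (np.abs(vx - mu) > 7 * sd).sum() == 1
        out = validate_vectors(field, 7.0)
        assert out.n_valid() == 99
        assert not out.valid[4, 4]

    def test_homogeneous_field_untouched(self):
        rng = np.random.default_rng(1)
        field = self._field(rng.normal(0, 1, (8, 8)), rng.normal(0, 1, (8, 8)))
        out = validate_vectors(field, 7.0)
        assert out.valid.all()

    def test_infinite_threshold_is_noop(self):
        rng = np.random.default_rng(2)
        vx = rng.normal(0, 1, (8, 8))
        vx[0, 0] = 1e6
        field = self._field(vx, rng.normal(0, 1, (8, 8)))
        out = validate_vectors(field, np.inf)
        assert np.array_equal(out.valid, field.valid)

    @pytest.mark.parametrize("thr", [1.0, 2.0, 3.0, 5.0, 7.0])
    def test_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(3)
        vx = rng.standard_t(df=2, size=(12, 12))
        vy = rng.standard_t(df=2, size=(12, 12))
        field = self._field(vx, vy)
        n_lo = validate_vectors(field, thr).n_valid()
        n_hi = validate_vectors(field, thr + 1.0).n_valid()
        assert n_lo <= n_hi

    def test_all_invalid_returned_with_warning(self):
        field = self._field(np.zeros((4, 4)), np.zeros((4, 4)),
                            valid=np.zeros((4, 4), bool))
        out = validate_vectors(field, 7.0)
        assert not out.valid.any()
        assert any("SD filter skipped" in s for s in out.warnings)


class TestTraceAndPeaks:
    CFG = PivConfig(window_sizes_px=(32, 16))

    def test_zero_motion_trace_length_and_floor(self):
        spec = MovieSpec(height_px=64, width_px=64, n_frames=10,
                         amplitude_um=0.0, noise_sigma=0.003, seed=9)
        movie, _ = make_contraction_movie(spec)
        tr = contraction_trace(movie, self.CFG, frame_rate_hz=20.0)
        assert len(tr) == 9
        # 0.05 px/frame at 20 fps and 1 um/px = 1 um/s
        assert np.nanmax(tr.mean_speed_um_s) < 1.0

    def test_time_reversal_preserves_speed(self, small_movie_spec):
        movie, _ = make_contraction_movie(small_movie_spec)
        fwd = contraction_trace(movie, self.CFG)
        rev = contraction_trace(movie[::-1].copy(), self.CFG)
        assert np.allclose(fwd.mean_speed_um_s, rev.mean_speed_um_s[::-1],
                           rtol=0.1, atol=0.05)

    def test_peak_near_truth_peak_velocity_phase(self, small_movie_spec):
        movie, truth = make_contraction_movie(small_movie_spec)
        tr = contraction_trace(movie, self.CFG)
        truth_speeds = np.array([
            np.hypot(*truth.pair_displacement_px(i)).mean()
            for i in range(truth.n_pairs)
        ])
        # a displacement pulse has two equal velocity bumps (contraction and
        # recoil); the measured peak must sit on one of them
        top_two = np.argsort(truth_speeds)[-2:]
        assert min(abs(tr.peak_index - int(i)) for i in top_two) <= 1

    def test_two_pulses_give_four_velocity_peaks(self):
        # each displacement pulse has a contraction and a recoil velocity peak
        spec = MovieSpec(height_px=64, width_px=64, n_frames=24,
                         amplitude_um=3.0, pulse_times_s=(0.1, 0.7),
                         pulse_width_s=0.4, noise_sigma=0.003, seed=10)
        movie, _ = make_contraction_movie(spec)
        tr = detect_peaks(contraction_trace(movie, self.CFG),
                          min_prominence=1.0)
        assert len(tr.peak_indices) == 4

    def test_flat_trace_has_no_prominent_peaks(self):
        spec = MovieSpec(height_px=64, width_px=64, n_frames=8,
                         amplitude_um=0.0, noise_sigma=0.003, seed=11)
        movie, _ = make_contraction_movie(spec)
        tr = detect_peaks(contraction_trace(movie, self.CFG),
                          min_prominence=1.0)
        assert len(tr.peak_indices) == 0

    def test_monotone_trace_peaks_at_boundary(self):
        tr = contraction_trace(
            make_contraction_movie(
                MovieSpec(height_px=64, width_px=64, n_frames=6,
                          amplitude_um=2.0, pulse_times_s=(0.0,),
                          pulse_width_s=0.5, noise_sigma=0.0, seed=12)
            )[0],
            self.CFG,
        )
        rising = tr.mean_speed_um_s[:3]
        assert np.all(np.diff(rising) > 0)  # monotone segment exists
        tr = detect_peaks(tr, min_prominence=0.0, include_boundaries=True)
        assert len(tr.peak_indices) >= 1


class TestDirectionSummary:
    def test_single_vector_closed_form(self):
        field = VelocityField(
            grid_x=np.array([[0.0]]), grid_y=np.array([[0.0]]),
            v_x=np.array([[1.0]]), v_y=np.array([[1.0]]),
            valid=np.ones((1, 1), bool), dt_s=0.05, pixel_size_um=1.0,
        )
        s = direction_summary(field)
        assert s["angles_deg"][0] == pytest.approx(45.0)
        assert s["magnitudes_um_s"][0] == pytest.approx(np.sqrt(2.0))

    def test_axis_pure_y_field(self):
        spec = MovieSpec(height_px=96, width_px=96, n_frames=8,
                         axis_anisotropy=1.0, contraction_axis_deg=90.0,
                         amplitude_um=4.0, pulse_times_s=(0.05,),
                         pulse_width_s=0.3, noise_sigma=0.0, seed=13)
        movie, _ = make_contraction_movie(spec)
        tr = contraction_trace(movie, PivConfig(window_sizes_px=(32, 16)),
                               store_fields=True)
        field = tr.fields[tr.peak_index]
        s = direction_summary(field)
        assert s["mean_abs_vx_um_s"] < 0.05 * s["mean_abs_vy_um_s"]
        assert s["mean_abs_vy_um_s"] == pytest.approx(s["mean_speed_um_s"],
                                                      rel=0.01)

    def test_no_valid_vectors_rejected(self):
        field = VelocityField(
            grid_x=np.zeros((1, 1)), grid_y=np.zeros((1, 1)),
            v_x=np.zeros((1, 1)), v_y=np.zeros((1, 1)),
            valid=np.zeros((1, 1), bool), dt_s=0.05, pixel_size_um=1.0,
        )
        with pytest.raises(ValueError):
            direction_summary(field)
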