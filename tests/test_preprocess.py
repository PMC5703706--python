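"""Temporal preprocessing: discard, slice timing, scrubbing, filtering, resampling."""

import numpy as np
import pytest

import lagflow as lf
from lagflow.errors import LagflowError, ParameterError, PipelineOrderError
from lagflow.lagmap import lag_correlate

from conftest import make_series


def sinusoid(freq, times, phase=0.0):
    return np.sin(2 * np.pi * freq * times + phase)


class TestDiscardInitial:
    @pytest.mark.parametrize(
        "tr,n,seconds,expected",
        [(2.0, 180, 10.0, 175), (2.5, 242, 10.0, 238), (2.0, 180, 0.0, 180)],
    )
    def test_volume_counts(self, tr, n, seconds, expected):
        rng = np.random.default_rng(0)
        s = make_series(rng.normal(size=(3, n)), dt=tr)
        out = lf.discard_initial(s, seconds)
        assert out.n_volumes == expected
        np.testing.assert_array_equal(out.data[..., 0], s.data[..., n - expected])

    def test_too_long_discard_rejected(self):
        s = make_series(np.zeros((2, 5)) + np.arange(5), dt=2.0)
        with pytest.raises(ParameterError):
            lf.discard_initial(s, 10.0)

    def test_motion_trimming_pairs_with_discard(self):
        mt = lf.MotionTrace.zeros(180)
        assert mt.drop_first(5).n_volumes == 175


class TestSliceTiming:
    def test_equal_slice_times_identity(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 2, 3, 40))
        s = lf.BoldSeries(data, 2.0, np.eye(4), np.ones((2, 2, 3), bool),
                          slice_times=np.zeros(3))
        out = lf.slice_timing_correct(s, reference=0)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_sinusoid_shifted_to_reference_grid(self):
        # slice 1 acquired 0.5*TR late; correction must recover the
        # signal as seen at the reference slice's acquisition times
        tr, n, f = 2.0, 120, 0.05
        t = np.arange(n) * tr
        data = np.zeros((1, 1, 2, n))
        data[0, 0, 0] = sinusoid(f, t)
        data[0, 0, 1] = sinusoid(f, t + 0.5 * tr)
        s = lf.BoldSeries(data, tr, np.eye(4), np.ones((1, 1, 2), bool),
                          slice_times=np.array([0.0, 1.0]))
        out = lf.slice_timing_correct(s, reference=0)
        expected = sinusoid(f, t)
        err = np.abs(out.data[0, 0, 1, 5:-5] - expected[5:-5]).max()
        assert err < 1e-3  # interior cubic-spline error bound at 0.05 Hz, TR 2 s

    def test_linear_ramp_corrected_exactly(self):
        # splines reproduce polynomials up to cubic exactly (interior)
        tr, n = 2.0, 30
        t = np.arange(n) * tr
        data = np.zeros((1, 1, 2, n))
        data[0, 0, 0] = 3.0 * t
        data[0, 0, 1] = 3.0 * (t + 1.0)
        s = lf.BoldSeries(data, tr, np.eye(4), np.ones((1, 1, 2), bool),
                          slice_times=np.array([0.0, 1.0]))
        out = lf.slice_timing_correct(s, reference=0)
        np.testing.assert_allclose(out.data[0, 0, 1], 3.0 * t, atol=1e-9)

    def test_missing_slice_times_instructive_error(self):
        s = make_series(np.random.default_rng(0).normal(size=(2, 20)), dt=2.0)
        with pytest.raises(ParameterError, match="slice.*order|order.*slice"):
            lf.slice_timing_correct(s)


class TestScrub:
    def make(self, n=60, tr=2.0, seed=0):
        rng = np.random.default_rng(seed)
        return make_series(rng.normal(size=(5, n)), dt=tr)

    def test_zero_motion_unchanged(self):
        s = self.make()
        out, rep = lf.scrub(s, lf.MotionTrace.zeros(60))
        assert rep.n_flagged == 0
        np.testing.assert_array_equal(out.data, s.data)

    def test_rate_scaling_5mm_not_flagged(self):
        # 5 mm jump at TR 2 s -> 1.25 mm per 0.5 s, under the 3 mm threshold
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.translations[40:, 0] = 5.0
        _, rep = lf.scrub(s, mt)
        assert rep.rates[40] == pytest.approx(1.25)
        assert rep.n_flagged == 0

    def test_13mm_jump_flagged_and_interpolated(self):
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.translations[40, 0] = 13.0  # one-volume spike: up at 40, down at 41
        out, rep = lf.scrub(s, mt)
        assert rep.trans_rates[40] == pytest.approx(3.25)
        assert 40 in rep.flagged_volumes and 41 in rep.flagged_volumes
        # volumes 40,41 replaced by linear interpolation between 39 and 42
        a, b = s.data[..., 39], s.data[..., 42]
        np.testing.assert_allclose(out.data[..., 40], a + (b - a) / 3.0, atol=1e-12)
        np.testing.assert_allclose(out.data[..., 41], a + 2 * (b - a) / 3.0, atol=1e-12)

    def test_exact_midway_is_neighbour_average(self):
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.translations[40, 0] = 13.0
        mt.translations[41, 0] = 13.0  # flags 40 (up) and 42 (down), 41 delta=0
        _, rep = lf.scrub(s, mt)
        assert list(rep.flagged_volumes) == [40, 42]

    def test_raw_delta_dialect_via_rate_window(self):
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.translations[40:, 0] = 5.0
        _, rep = lf.scrub(s, mt, rate_window=2.0)  # threshold raw deltas
        assert rep.rates[40] == pytest.approx(5.0)
        assert 40 in rep.flagged_volumes

    def test_rotation_thresholded_in_degrees(self):
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.rotations[30:, 2] = 13.0
        _, rep = lf.scrub(s, mt)
        assert 30 in rep.flagged_volumes

    def test_all_flagged_is_hard_error(self):
        s = self.make(n=10)
        mt = lf.MotionTrace(
            np.arange(10)[:, None] * np.array([20.0, 0, 0]), np.zeros((10, 3))
        )
        with pytest.raises(LagflowError, match="unusable"):
            lf.scrub(s, mt)

    def test_idempotent(self):
        s = self.make()
        mt = lf.MotionTrace.zeros(60)
        mt.translations[20, 0] = 15.0
        once, rep1 = lf.scrub(s, mt)
        twice, rep2 = lf.scrub(once, mt)
        assert list(rep1.flagged_volumes) == list(rep2.flagged_volumes)
        np.testing.assert_array_equal(once.data, twice.data)


class TestBandpass:
    def test_in_band_sinusoid_preserved_zero_phase(self):
        tr, n = 2.0, 300
        t = np.arange(n) * tr
        x = sinusoid(0.03, t)
        s = make_series([x], dt=tr)
        out = lf.bandpass(s).data[0, 0, 0]
        core = slice(30, -30)  # avoid filtfilt edge transients
        amp = out[core].std() / x[core].std()
        assert amp == pytest.approx(1.0, abs=0.05)
        # zero phase: cross-correlation peak with the input at lag 0
        lag, _, valid = lag_correlate(out[None, :], x - x.mean(), dt=tr, max_lag=6, step=2.0)
        assert valid[0] and lag[0] == 0.0

    def test_out_of_band_attenuated(self):
        tr, n = 2.0, 300
        t = np.arange(n) * tr
        x = sinusoid(0.2, t)
        s = make_series([x], dt=tr)
        out = lf.bandpass(s).data[0, 0, 0]
        assert out[30:-30].std() / x[30:-30].std() < 0.1

    def test_one_octave_outside_band_attenuated(self):
        tr, n = 2.0, 300
        t = np.arange(n) * tr
        x = sinusoid(0.14, t)  # one octave above the 0.07 Hz edge
        out = lf.bandpass(make_series([x], dt=tr)).data[0, 0, 0]
        assert out[30:-30].std() / x[30:-30].std() < 0.1

    def test_constant_series_zeroed(self):
        s = make_series(np.full((3, 200), 7.5), dt=2.0)
        out = lf.bandpass(s)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_band_beyond_nyquist_rejected(self):
        s = make_series(np.random.default_rng(0).normal(size=(2, 200)), dt=2.5)
        with pytest.raises(ParameterError, match="Nyquist"):
            lf.bandpass(s, 0.008, 0.3)


class TestResample:
    def test_identity_at_equal_dt(self):
        s = make_series(np.random.default_rng(0).normal(size=(3, 50)), dt=0.5)
        out = lf.resample_temporal(s, dt=0.5)
        np.testing.assert_array_equal(out.data, s.data)

    def test_sinusoid_resampled_within_bound(self):
        tr, n, f = 2.0, 200, 0.05
        t = np.arange(n) * tr
        s = make_series([sinusoid(f, t)], dt=tr)
        out = lf.resample_temporal(s, dt=0.5)
        t_new = np.arange(out.n_volumes) * 0.5
        err = np.abs(out.data[0, 0, 0] - sinusoid(f, t_new)).max()
        assert err < 0.01  # <1% of unit amplitude for in-band signals

    def test_grid_density_and_endpoints(self):
        s = make_series(np.random.default_rng(1).normal(size=(2, 40)), dt=2.5)
        out = lf.resample_temporal(s, dt=0.5)
        assert out.n_volumes == (40 - 1) * 5 + 1
        np.testing.assert_allclose(out.data[..., 0], s.data[..., 0], atol=1e-12)
        np.testing.assert_allclose(out.data[..., -1], s.data[..., -1], atol=1e-12)

    def test_invalid_dt_rejected(self):
        s = make_series(np.zeros((2, 40)) + np.arange(40.0), dt=2.0)
        with pytest.raises(ParameterError):
            lf.resample_temporal(s, dt=0.0)
        with pytest.raises(ParameterError):
            lf.resample_temporal(s, dt=3.0)


class TestPipelineOrder:
    def test_out_of_order_raises(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.normal(size=(2, 120)), dt=2.0)
        filtered = lf.bandpass(s)
        with pytest.raises(PipelineOrderError):
            lf.discard_initial(filtered, 10.0)
        with pytest.raises(PipelineOrderError):
            lf.scrub(filtered, lf.MotionTrace.zeros(120))
        resampled = lf.resample_temporal(filtered, 0.5)
        with pytest.raises(PipelineOrderError):
            lf.bandpass(resampled)

    def test_full_chain_history(self, truth):
        spec = lf.default_phantom_spec(n_volumes=100, noise_sd=0.2, seed=0)
        series, motion = lf.synthesize_subject(spec, truth, "single")
        clean, _ = lf.run_preprocessing(series, motion)
        assert clean.history == ("discard_initial", "slice_timing", "scrub",
                                 "bandpass", "resample")
        assert clean.sampling_interval == 0.5
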