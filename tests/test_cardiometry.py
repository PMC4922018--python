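import numpy as np
import pytest

from fishbeam import cardiometry as card
from fishbeam import synthetic as syn
from fishbeam.cardiometry import IntensityTrace, Rect


def trace(values, fps=300.0):
    return IntensityTrace(values=np.asarray(values, dtype=float), fps=fps)


class TestRoiMeanTrace:
    def test_uniform_frames(self):
        stack = card.FrameStack(frames=np.full((5, 8, 8), 7.0), fps=300)
        t = card.roi_mean_trace(stack, Rect(1, 1, 4, 4))
        assert np.allclose(t.values, 7.0)

    def test_small_roi_mean(self):
        frame = np.array([[0.0, 0.0], [10.0, 10.0]])
        stack = card.FrameStack(frames=frame[None], fps=300)
        t = card.roi_mean_trace(stack, Rect(0, 0, 2, 2))
        assert t.values[0] == pytest.approx(5.0)

    def test_column_gradient(self):
        frame = np.tile(np.arange(64, dtype=float), (16, 1))
        stack = card.FrameStack(frames=frame[None], fps=300)
        t = card.roi_mean_trace(stack, Rect(0, 10, 16, 20))
        assert t.values[0] == pytest.approx(14.5)

    def test_rgb_converted_to_luminance(self):
        rgb = np.zeros((2, 4, 4, 3))
        rgb[..., 1] = 100.0  # pure green
        stack = card.FrameStack(frames=rgb, fps=300)
        t = card.roi_mean_trace(stack, Rect(0, 0, 4, 4))
        assert np.allclose(t.values, 58.7)

    def test_out_of_bounds_roi_raises(self):
        stack = card.FrameStack(frames=np.zeros((2, 4, 4)), fps=300)
        with pytest.raises(ValueError):
            card.roi_mean_trace(stack, Rect(0, 0, 5, 2))


class TestCardiacSignal:
    def test_mean_minus_reference(self):
        hearts = [trace([10.0] * 4), trace([20.0] * 4), trace([30.0] * 4)]
        ref = trace([5.0] * 4)
        out = card.cardiac_signal(hearts, ref)
        assert np.allclose(out.values, 15.0)

    def test_zero_reference_passthrough(self):
        a = np.sin(np.linspace(0, 6, 50))
        hearts = [trace(a)] * 3
        out = card.cardiac_signal(hearts, trace(np.zeros(50)))
        assert np.allclose(out.values, a)

    def test_common_mode_cancellation_is_exact(self):
        """A common-mode artifact added to all four ROIs leaves the signal bit-identical.

        Uses integer-digitized intensities (what a camera produces), for
        which the per-trace subtraction is exact in floating point.
        """
        rng = np.random.default_rng(1)
        hearts = [trace(rng.integers(80, 180, 200).astype(float)) for _ in range(3)]
        ref = trace(rng.integers(80, 180, 200).astype(float))
        vent = np.rint(5.0 * np.sin(np.linspace(0, 40, 200)))
        base = card.cardiac_signal(hearts, ref)
        shifted = card.cardiac_signal(
            [trace(h.values + vent) for h in hearts], trace(ref.values + vent)
        )
        assert np.array_equal(base.values, shifted.values)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            card.cardiac_signal([trace([1, 2])] * 3, trace([1, 2, 3]))


class TestSmoothTrace:
    def test_constant_preserved(self):
        t = card.smooth_trace(trace(np.full(100, 3.5)), 21)
        assert np.allclose(t.values, 3.5)

    def test_impulse_spreads_window_mass(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = card.smooth_trace(trace(x), 21).values
        assert np.allclose(sm[40:61], 1 / 21)
        assert sm[39] == 0.0 and sm[61] == 0.0

    def test_linear_ramp_fixed_in_interior(self):
        x = np.arange(100, dtype=float)
        sm = card.smooth_trace(trace(x), 21).values
        assert np.allclose(sm[10:90], x[10:90])

    def test_mean_preserved_on_random_input(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=301)
        sm = card.smooth_trace(trace(x), 21).values
        # truncated-window smoothing redistributes but edge effects are tiny
        assert sm.mean() == pytest.approx(x.mean(), abs=5e-2)
        # and constants are preserved exactly
        const = card.smooth_trace(trace(np.full(301, x.mean())), 21).values
        assert np.allclose(const, x.mean(), rtol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            card.smooth_trace(trace(np.zeros(50)), 20)
        with pytest.raises(ValueError):
            card.smooth_trace(trace(np.zeros(50)), -3)


class TestMinimaDetection:
    def test_cosine_minima_at_half_period(self):
        t = np.arange(1000)
        x = np.cos(2 * np.pi * t / 100.0)
        idx = card.detect_diastole_minima(trace(x), min_separation=60, min_prominence=0.5)
        assert list(idx) == [50, 150, 250, 350, 450, 550, 650, 750, 850, 950]

    def test_constant_trace_has_no_minima(self):
        idx = card.detect_diastole_minima(trace(np.ones(500)))
        assert idx.size == 0

    def test_noisy_cosine_minima_within_two_frames(self):
        rng = np.random.default_rng(7)
        t = np.arange(1000)
        x = np.cos(2 * np.pi * t / 100.0) + rng.normal(0, 0.01, 1000)
        idx = card.detect_diastole_minima(trace(x), min_separation=60, min_prominence=0.5)
        assert idx.size == 10
        assert np.all(np.abs(idx - (50 + 100 * np.arange(10))) <= 2)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = np.cos(np.linspace(0, 40, 800)) + rng.normal(0, 0.05, 800)
        base = card.detect_diastole_minima(trace(x), 30, 0.6)
        shifted = card.detect_diastole_minima(trace(x + 123.0), 30, 0.6)
        scaled = card.detect_diastole_minima(trace(3.0 * x), 30, 3 * 0.6)
        assert np.array_equal(base, shifted)
        assert np.array_equal(base, scaled)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            card.detect_diastole_minima(trace([1.0, 2.0]))


class TestBeatQuantities:
    def test_interbeat_intervals(self):
        assert list(card.interbeat_intervals(np.array([50, 150, 250]))) == [100, 100]
        assert list(card.interbeat_intervals(np.array([0, 106, 212, 318]))) == [106] * 3

    def test_interbeat_needs_two_minima(self):
        with pytest.raises(ValueError):
            card.interbeat_intervals(np.array([42]))

    @pytest.mark.parametrize(
        "ibi, fps, bpm",
        [(300, 300, 60.0), (100, 300, 180.0), (105.88, 300, 170.0)],
    )
    def test_beat_by_beat_hr(self, ibi, fps, bpm):
        assert card.beat_by_beat_hr(np.array([ibi]), fps)[0] == pytest.approx(bpm, abs=0.01)

    def test_zero_ibi_rejected(self):
        with pytest.raises(ValueError):
            card.beat_by_beat_hr(np.array([0.0]), 300)


class TestSteadyStateHr:
    def make_beats(self, ibis, fps=300.0):
        minima = np.concatenate([[0], np.cumsum(ibis)]).astype(int)
        hrs = card.beat_by_beat_hr(np.asarray(ibis, float), fps)
        return card.BeatSeries(
            minima_indices=minima, ibis_frames=np.asarray(ibis, float), hr_bpm=hrs, fps=fps
        )

    def test_constant_rate(self):
        ibis = [300 * 60 // 170] * 100
        beats = self.make_beats(ibis)
        s = card.steady_state_hr(beats, window_seconds=180)
        assert s.mean_bpm == pytest.approx(card.beat_by_beat_hr(np.array(ibis), 300)[0])
        assert s.sd_bpm == 0.0

    def test_alternating_rates_average(self):
        ibis = [int(300 * 60 / 160), int(300 * 60 / 180)] * 40
        beats = self.make_beats(ibis)
        s = card.steady_state_hr(beats, window_seconds=180)
        mean_expected = np.mean(card.beat_by_beat_hr(np.array(ibis, float), 300))
        assert s.mean_bpm == pytest.approx(mean_expected)

    def test_window_membership_rule(self):
        # beats at frames 0, 100, ..., 1000; window [0, 1.67 s) at 300 fps = 500 frames
        beats = self.make_beats([100] * 10)
        s = card.steady_state_hr(beats, window_seconds=500 / 300.0)
        assert s.n_beats == 4  # minima 0..400 inside; beat (400,500) excluded

    def test_insufficient_beats_raise(self):
        beats = self.make_beats([100] * 10)
        with pytest.raises(ValueError):
            card.steady_state_hr(beats, window_seconds=0.5)


class TestFullPipeline:
    def test_recovers_generator_rate(self):
        params = syn.HeartSimParams(true_hr_bpm=165.0, seed=42)
        hearts, ref, truth = syn.gen_heart_trace(params)
        res = card.run_trace_pipeline(hearts, ref)
        assert res.summary is not None
        assert abs(res.summary.mean_bpm - 165.0) <= 1.0

    def test_video_pipeline_recovers_rate(self):
        params = syn.HeartSimParams(true_hr_bpm=170.0, duration_s=30.0, seed=3)
        stack, rois, truth = syn.gen_heart_video(params, frame_shape=(64, 96))
        res = card.run_heartrate_pipeline(stack, rois, window_seconds=30.0)
        assert res.summary is not None
        assert abs(res.summary.mean_bpm - 170.0) <= 1.0

    def test_no_cardiac_signal_reports_failure_not_crash(self):
        # ROIs see the ventilation artifact only: subtraction leaves a flat
        # trace, beat detection comes up empty and is reported, not raised.
        params = syn.HeartSimParams(true_hr_bpm=170.0, duration_s=10.0, noise_sd=0.0, seed=4)
        _, ref, _ = syn.gen_heart_trace(params)
        vent_only = [IntensityTrace(values=ref.values.copy(), fps=ref.fps) for _ in range(3)]
        res = card.run_trace_pipeline(vent_only, ref, window_seconds=10.0)
        assert res.summary is None
        assert res.failure is not None
        assert res.beats.n_beats == 0

    def test_reference_subtraction_matters_under_ventilation(self):
        """Disabling subtraction hurts more when the ventilation artifact is large."""
        strong = syn.HeartSimParams(
            true_hr_bpm=170.0, duration_s=60.0, seed=6,
            ventilation_amplitude=20.0, noise_sd=0.5,
        )
        quiet = syn.HeartSimParams(
            true_hr_bpm=170.0, duration_s=60.0, seed=6,
            ventilation_amplitude=0.0, noise_sd=0.5,
        )

        def recovered(params, subtract):
            hearts, ref, _ = syn.gen_heart_trace(params)
            res = card.run_trace_pipeline(
                hearts, ref, window_seconds=60.0, subtract_reference=subtract
            )
            return np.inf if res.summary is None else abs(res.summary.mean_bpm - 170.0)

        delta_strong = recovered(strong, False) - recovered(strong, True)
        delta_quiet = recovered(quiet, False) - recovered(quiet, True)
        assert delta_strong > delta_quiet


class TestRecoverySweep:
    def test_rate_sweep_within_one_bpm(self):
        """|recovered - true| <= 1 bpm in >= 95% of seeded replicates across rates."""
        rates = [120, 150, 165, 170, 174, 200]
        ok = 0
        total = 0
        for hr in rates:
            for seed in range(20):
                params = syn.HeartSimParams(true_hr_bpm=float(hr), seed=1000 * hr + seed)
                hearts, ref, _ = syn.gen_heart_trace(params)
                res = card.run_trace_pipeline(hearts, ref)
                total += 1
                if res.summary is not None and abs(res.summary.mean_bpm - hr) <= 1.0:
                    ok += 1
        assert ok / total >= 0.95

    def test_beat_count_matches_rate(self):
        for hr in (120.0, 174.0):
            params = syn.HeartSimParams(true_hr_bpm=hr, hr_jitter_cv=0.0, seed=0, duration_s=60.0)
            hearts, ref, _ = syn.gen_heart_trace(params)
            res = card.run_trace_pipeline(hearts, ref, window_seconds=60.0)
            expected = hr * 60.0 / 60.0
            assert abs(res.beats.n_beats - expected) <= 2  # window-edge beats
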