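import math

import numpy as np
import pytest

from ecgsync.detector_core import (
    AlignmentError,
    BoundaryError,
    DetectorConfig,
    DetectorState,
    EventSeries,
    InputError,
    OrderingError,
    StateCorruptionError,
    UniformSignal,
    decay_threshold,
    finite_difference,
    resample_to_grid,
    run_batch,
    run_streaming,
    schedule_trigger,
    step,
    update_heart_rate,
)


class TestUniformSignal:
    def test_time_of_sample(self):
        sig = UniformSignal(1.0, 0.5, np.array([0.0, 1.0, 2.0]))
        assert sig.times() == pytest.approx([1.0, 1.5, 2.0])
        assert sig.end_time == 2.0

    def test_needs_two_samples(self):
        with pytest.raises(InputError):
            UniformSignal(0.0, 0.5, np.array([1.0]))

    def test_interval_positive(self):
        with pytest.raises(InputError):
            UniformSignal(0.0, -0.1, np.array([0.0, 1.0]))

    def test_ttl_levels(self):
        assert UniformSignal(0.0, 1.0, np.array([0.0, 1.0, 0.0])).is_ttl()
        assert not UniformSignal(0.0, 1.0, np.array([0.0, 0.5])).is_ttl()


class TestEventSeries:
    def test_strictly_increasing(self):
        with pytest.raises(OrderingError):
            EventSeries("r_detection", np.array([0.0, 0.0]))

    def test_ok(self):
        assert len(EventSeries("r_detection", np.array([0.1, 0.2]))) == 2


class TestDetectorConfig:
    def test_decay_rate_range(self):
        with pytest.raises(InputError):
            DetectorConfig(decay_rate=0.0)
        with pytest.raises(InputError):
            DetectorConfig(decay_rate=1.0)

    def test_defaults(self, cfg):
        assert cfg.tick == 0.005
        assert cfg.decay_rate == 0.0014
        assert cfg.refractory == 0.020
        assert cfg.pulse_width == 0.025
        assert cfg.dt_mp == 0.0

    def test_unknown_key_rejected(self):
        with pytest.raises(InputError):
            DetectorConfig.from_mapping({"bogus": 1})


class TestFiniteDifference:
    def test_constant_signal_zero(self, cfg):
        sig = UniformSignal(0.0, cfg.tick, np.full(10, 3.7))
        assert finite_difference(sig, 0.02, cfg) == 0.0

    def test_linear_ramp(self, ramp, cfg):
        # slope 2 units/s over a 5 ms tick
        assert finite_difference(ramp, 0.1, cfg) == pytest.approx(0.010)

    def test_sine_closed_form(self, cfg):
        t = np.arange(0, 1.0, 0.001)
        sig = resample_to_grid(UniformSignal(0.0, 0.001, np.sin(2 * np.pi * t)), cfg)
        expected = math.sin(2 * math.pi * 0.005)  # sin(0.01*pi)
        assert finite_difference(sig, 0.0, cfg) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.0314108, abs=1e-6)

    def test_out_of_span(self, ramp, cfg):
        with pytest.raises(BoundaryError):
            finite_difference(ramp, ramp.end_time, cfg)

    def test_off_grid(self, ramp, cfg):
        with pytest.raises(AlignmentError):
            finite_difference(ramp, 0.0012, cfg)


class TestDecayThreshold:
    def test_single_first_order_step(self, cfg):
        assert decay_threshold(1.0, cfg) == pytest.approx(0.9986)

    def test_small_rate_is_near_identity(self):
        cfg = DetectorConfig(decay_rate=1e-12)
        assert decay_threshold(5.0, cfg) == pytest.approx(5.0, rel=1e-9)

    def test_500_steps_repeated_multiplication_oracle(self, cfg):
        thr = 1.0
        expected = 1.0
        for _ in range(500):
            thr = decay_threshold(thr, cfg)
            expected *= 1.0 - 0.0014
        assert thr == pytest.approx(expected)
        assert thr == pytest.approx(0.4963, abs=5e-5)

    def test_true_exponential_as_printed(self):
        cfg = DetectorConfig(decay_law="true_exponential", decay_rate=0.0014)
        thr = 2.0
        assert decay_threshold(thr, cfg) == pytest.approx(2.0 * math.exp(-2.0 * 0.0014))

    def test_nonpositive_threshold_rejected(self, cfg):
        with pytest.raises(StateCorruptionError):
            decay_threshold(0.0, cfg)


class TestUpdateHeartRate:
    def test_one_second_period(self):
        assert update_heart_rate(2.0, 1.0) == pytest.approx((1.0, 60.0))

    def test_066_period(self):
        tj, hr = update_heart_rate(1.66, 1.0)
        assert tj == pytest.approx(0.66)
        assert hr == pytest.approx(90.909, abs=1e-2)

    def test_half_second_period(self):
        assert update_heart_rate(1.0, 0.5)[1] == pytest.approx(120.0)

    def test_ordering_enforced(self):
        with pytest.raises(OrderingError):
            update_heart_rate(1.0, 1.0)


class TestScheduleTrigger:
    def test_first_grid_point_strictly_after(self):
        cfg = DetectorConfig(dt_mp=0.05)
        assert schedule_trigger(10.0, 1.0, cfg) == pytest.approx(10.955)

    def test_exact_grid_boundary_moves_one_tick(self, cfg):
        # ti + Tj lands on the grid; strictly-greater pushes one tick out
        assert schedule_trigger(10.0, 1.0, cfg) == pytest.approx(11.005)

    def test_clamp_when_dtmp_exceeds_period(self):
        cfg = DetectorConfig(dt_mp=2.0)
        assert schedule_trigger(10.0, 1.0, cfg) == pytest.approx(10.005)


class TestStep:
    def test_flat_signal_never_triggers(self, cfg):
        sig = UniformSignal(0.0, cfg.tick, np.zeros(200))
        state = DetectorState()
        outs = []
        for k in range(199):
            state, out, events = step(state, sig, k * cfg.tick, cfg)
            outs.append(out)
            assert not events
        assert state.detections_seen == 0
        assert all(o == 0 for o in outs)

    def test_refractory_blocks_and_decays(self, cfg):
        # two identical jumps 10 ms apart: the second exceeds thr but sits
        # inside the 20 ms refractory, so it must only decay the threshold
        y = np.zeros(40)
        y[5] = -1.0  # step up into tick 5->6? build explicit differences
        y = np.zeros(40)
        y[6:] += 1.0  # diff at tick 5 = +1
        y[8:] += 1.0  # diff at tick 7 = +1  (10 ms later)
        sig = UniformSignal(0.0, cfg.tick, y)
        state = DetectorState()
        det_times = []
        for k in range(39):
            state, _, events = step(state, sig, k * cfg.tick, cfg)
            det_times += [t for kind, t in events if kind == "r_detection"]
        assert det_times == [pytest.approx(0.025)]
        # threshold decayed after the blocked tick
        assert state.thr < 1.0

    def test_pulse_width_quantization(self, cfg):
        # drive two detections then check rising->falling spacing is 25 ms
        sig, _ = _two_beat_signal(cfg)
        res = run_streaming(sig, cfg)
        assert len(res.rising) >= 1
        for r, f in zip(res.rising.times, res.falling.times):
            assert f - r == pytest.approx(0.025, abs=1e-9)

    def test_off_grid_time_rejected(self, cfg):
        sig = UniformSignal(0.0, cfg.tick, np.zeros(10))
        with pytest.raises(AlignmentError):
            step(DetectorState(), sig, 0.0013, cfg)


def _two_beat_signal(cfg, n_beats=6, period=0.5):
    from ecgsync.simulator import EcgModelParams, generate_ecg

    params = EcgModelParams.for_beats(n_beats, mean_hr=60.0 / period, seed=3)
    return generate_ecg(params)


class TestRunStreaming:
    def test_deterministic(self, clean_trace, cfg):
        sig, _ = clean_trace
        a = run_streaming(sig, cfg)
        b = run_streaming(sig, cfg)
        assert np.array_equal(a.ttl.samples, b.ttl.samples)
        assert np.array_equal(a.detections.times, b.detections.times)

    def test_too_short_rejected(self, cfg):
        sig = UniformSignal(0.0, cfg.tick, np.zeros(3))
        run_streaming(sig, cfg)  # exactly 3 samples is the minimum
        with pytest.raises(InputError):
            run_streaming(UniformSignal(0.0, 0.0005, np.zeros(3)), cfg)

    def test_edges_after_warmup_near_derivative_max(self, clean_trace, cfg):
        from ecgsync.evaluation import derivative_peak_times

        sig, truth = clean_trace
        res = run_streaming(sig, cfg)
        refs = derivative_peak_times(sig, cfg, truth)
        for i in range(3, len(refs)):
            nearest = res.rising.times[np.argmin(np.abs(res.rising.times - refs[i]))]
            assert abs(nearest - refs[i]) <= cfg.tick + 1e-9

    def test_hr_series_reports_period(self, clean_trace, cfg):
        sig, _ = clean_trace
        res = run_streaming(sig, cfg)
        # constant 60 bpm: the settled estimates are 60 within one tick
        settled = [hr for _, hr in res.hr_series[-5:]]
        for hr in settled:
            assert hr == pytest.approx(60.0, abs=1.0)

    def test_batch_matches_streaming(self, wander_trace, cfg):
        sig, _ = wander_trace
        a = run_streaming(sig, cfg)
        b = run_batch(sig, cfg)
        assert np.array_equal(a.ttl.samples, b.ttl.samples)
        assert np.array_equal(a.detections.times, b.detections.times)
        assert np.array_equal(a.rising.times, b.rising.times)
        assert np.array_equal(a.falling.times, b.falling.times)
        assert np.allclose(a.threshold, b.threshold, rtol=1e-12, atol=0)

    def test_batch_matches_streaming_true_exponential(self, wander_trace):
        cfg = DetectorConfig(decay_law="true_exponential")
        sig, _ = wander_trace
        a = run_streaming(sig, cfg)
        b = run_batch(sig, cfg)
        assert np.array_equal(a.ttl.samples, b.ttl.samples)

    def test_resampling_path(self, cfg):
        # a 777 Hz trace is interpolated onto the 200 Hz grid
        from ecgsync.simulator import EcgModelParams, generate_ecg

        sig, truth = generate_ecg(EcgModelParams.for_beats(8, seed=9, sample_rate=777.0))
        res = run_streaming(sig, cfg)
        assert res.grid.sample_interval == cfg.tick
        assert len(res.detections) >= 8
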