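"""EPSC input counting, mEPSC detection, PPR, fiber metrics."""

import numpy as np
import pytest

import helpers
from synquant import ephys, synthio
from synquant.synthio import ResponseCurve, Trace, _biexp_kernel


def _staircase(levels, pts_per_level=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    amps = np.concatenate([np.full(pts_per_level, lv) for lv in levels])
    amps = amps + rng.normal(0, noise, amps.shape)
    stims = np.arange(len(amps), dtype=float)
    return ResponseCurve(list(zip(stims.tolist(), amps.tolist())))


class TestCountInputs:
    def test_noiseless_three_steps(self):
        curve = _staircase([0.0, 1.0, 1.8, 3.0])
        res = ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)
        assert res.n_inputs == 3
        assert res.step_levels_nA == pytest.approx([0.0, 1.0, 1.8, 3.0])
        assert not res.discard
        assert res.single_fiber_nA == pytest.approx(1.0)
        assert res.max_nA == pytest.approx(3.0)

    def test_flat_zero_curve(self):
        curve = _staircase([0.0])
        res = ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)
        assert res.n_inputs == 0

    def test_amplitude_drop_flags_discard(self):
        curve = _staircase([0.0, 2.0, 1.0])
        res = ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)
        assert res.discard

    def test_n_inputs_matches_level_count(self):
        curve, truth = synthio.gen_epsc_staircase(4, [0.5, 0.7, 0.4, 0.9],
                                                  noise_sd_nA=0.02, seed=5)
        res = ephys.count_inputs(curve, noise_sd_nA=0.02, min_step_nA=0.1)
        assert res.n_inputs == len(res.step_levels_nA) - 1
        assert res.n_inputs == truth.n_inputs

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_segmentation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pts = int(rng.integers(6, 13))
        n_steps = int(rng.integers(0, 4))
        noise = 0.02
        levels = np.concatenate([[0.0], np.cumsum(rng.uniform(0.15, 1.0, n_steps))])
        idx = np.sort(rng.choice(np.arange(1, n_pts), size=n_steps, replace=False))
        lab = np.zeros(n_pts, dtype=int)
        for i in idx:
            lab[i:] += 1
        amps = levels[lab] + rng.normal(0, noise, n_pts)
        curve = ResponseCurve(list(zip(np.arange(n_pts, dtype=float), amps)))
        res = ephys.count_inputs(curve, noise_sd_nA=noise, min_step_nA=0.1)
        oracle = helpers.exhaustive_staircase_count(amps, noise, 0.1)
        assert res.n_inputs == oracle

    def test_invariant_to_joint_amplitude_scaling(self):
        curve, _ = synthio.gen_epsc_staircase(3, [0.4, 0.6, 0.3],
                                              noise_sd_nA=0.02, seed=9)
        res1 = ephys.count_inputs(curve, noise_sd_nA=0.02, min_step_nA=0.1)
        scaled = ResponseCurve([(s, 5.0 * a) for s, a in curve.points])
        res2 = ephys.count_inputs(scaled, noise_sd_nA=0.1, min_step_nA=0.5)
        assert res1.n_inputs == res2.n_inputs

    def test_invariant_to_stimulus_axis_rescaling(self):
        curve, _ = synthio.gen_epsc_staircase(3, [0.4, 0.6, 0.3],
                                              noise_sd_nA=0.02, seed=9)
        res1 = ephys.count_inputs(curve, noise_sd_nA=0.02, min_step_nA=0.1)
        rescaled = ResponseCurve([(2.0 * s + 7.0, a) for s, a in curve.points])
        res2 = ephys.count_inputs(rescaled, noise_sd_nA=0.02, min_step_nA=0.1)
        assert res1.n_inputs == res2.n_inputs

    def test_too_few_points_rejected(self):
        curve = ResponseCurve([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        with pytest.raises(ValueError):
            ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)


def _trace_with_events(times_amps, duration=4.0, fs=20000.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    samples = rng.normal(0, noise, n) if noise else np.zeros(n)
    kern = -_biexp_kernel(np.arange(int(0.05 * fs)) / fs, 0.0005, 0.004)
    for t0, amp in times_amps:
        i0 = int(t0 * fs)
        seg = min(len(kern), n - i0)
        samples[i0:i0 + seg] += -amp * kern[:seg]
    return Trace(samples, fs)


class TestDetectMepsc:
    def test_threshold_separates_event_sizes(self):
        tr = _trace_with_events([(0.5, -15.0), (1.5, -5.0), (2.5, -20.0)])
        train = ephys.detect_mepsc(tr)
        amps = sorted(train.amplitudes_pA)
        assert len(train) == 2  # the -5 pA event stays above -9 pA
        assert amps[0] == pytest.approx(-20.0, abs=1.0)
        assert amps[1] == pytest.approx(-15.0, abs=1.0)

    def test_noise_only_trace_empty(self):
        tr = Trace(np.zeros(40000), 20000.0)
        assert len(ephys.detect_mepsc(tr)) == 0

    def test_count_monotone_in_threshold_depth(self):
        tr, _ = synthio.gen_mepsc_trace(duration_s=20.0, rate_hz=2.0, seed=3)
        n9 = len(ephys.detect_mepsc(tr, threshold_pA=-9.0))
        n15 = len(ephys.detect_mepsc(tr, threshold_pA=-15.0))
        n25 = len(ephys.detect_mepsc(tr, threshold_pA=-25.0))
        assert n9 >= n15 >= n25

    def test_close_events_merged_to_larger(self):
        tr = _trace_with_events([(1.0, -15.0), (1.004, -30.0)])
        train = ephys.detect_mepsc(tr, min_separation_ms=10.0)
        assert len(train) == 1
        # Merged to the larger peak; the second event rides on the tail of
        # the first, so the baseline-to-peak amplitude exceeds -30 pA.
        assert -45.0 < train.events[0].amplitude_pA <= -30.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.detect_mepsc(Trace(np.zeros(1000), 20000.0))

    def test_event_times_strictly_increasing(self):
        tr, _ = synthio.gen_mepsc_trace(duration_s=30.0, rate_hz=2.0, seed=8)
        train = ephys.detect_mepsc(tr)
        assert (np.diff(train.times_s) > 0).all()


class TestPairedPulseRatio:
    def test_well_separated_identical_pulses(self):
        traces, truth = synthio.gen_paired_pulse(
            ppr_by_interval={1000: 1.0}, noise_sd_pA=2.0, seed=0
        )
        r = ephys.paired_pulse_ratio(traces[1000], truth.stim_times_s[1000])
        assert r == pytest.approx(1.0, abs=0.02)

    def test_noiseless_half_ratio(self):
        traces, truth = synthio.gen_paired_pulse(
            ppr_by_interval={1000: 0.5}, noise_sd_pA=0.0, seed=1
        )
        r = ephys.paired_pulse_ratio(traces[1000], truth.stim_times_s[1000])
        assert r == pytest.approx(0.5, abs=0.01)

    def test_tail_subtraction_beats_naive_reading(self):
        traces, truth = synthio.gen_paired_pulse(
            ppr_by_interval={50: 0.7}, kinetics_ms=(1.0, 20.0),
            noise_sd_pA=0.0, seed=2,
        )
        tr = traces[50]
        t1, t2 = truth.stim_times_s[50]
        r = ephys.paired_pulse_ratio(tr, (t1, t2))
        assert r == pytest.approx(0.7, abs=0.03)
        # Naive peak reading rides on the first pulse's decay tail and is
        # biased upward.
        fs = tr.sampling_hz
        base = np.median(tr.samples_pA[: int(0.9 * t1 * fs)])
        d = base - tr.samples_pA
        a1 = d[int(t1 * fs):int(t2 * fs)].max()
        a2_naive = d[int(t2 * fs):].max()
        assert a2_naive / a1 > r

    def test_missing_second_pulse_is_error_not_zero(self):
        fs = 20000.0
        t = np.arange(int(0.8 * fs)) / fs
        sweep = -1000.0 * _biexp_kernel(t - 0.1, 0.001, 0.02)
        rng = np.random.default_rng(0)
        tr = Trace(sweep + rng.normal(0, 2.0, len(sweep)), fs)
        with pytest.raises(ValueError):
            ephys.paired_pulse_ratio(tr, (0.1, 0.35))

    def test_first_pulse_below_noise_floor_errors(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.normal(0, 5.0, 20000), 20000.0)
        with pytest.raises(ValueError):
            ephys.paired_pulse_ratio(tr, (0.3, 0.6))


class TestFiberMetrics:
    def test_single_input_fraction_one(self):
        curve = _staircase([0.0, 1.2])
        res = ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)
        frac, peak = ephys.fiber_metrics(res)
        assert frac == pytest.approx(1.0)
        assert peak == pytest.approx(1.2)

    def test_steps_1_1_2_give_quarter(self):
        curve = _staircase([0.0, 1.0, 2.0, 4.0])
        res = ephys.count_inputs(curve, noise_sd_nA=0.0, min_step_nA=0.1)
        frac, _ = ephys.fiber_metrics(res)
        assert frac == pytest.approx(0.25)

    def test_recovers_truth_on_generated_staircases(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            steps = list(rng.uniform(0.2, 1.0, 4))
            curve, _ = synthio.gen_epsc_staircase(4, steps, noise_sd_nA=0.02,
                                                  seed=seed)
            res = ephys.count_inputs(curve, noise_sd_nA=0.02, min_step_nA=0.1)
            frac, _ = ephys.fiber_metrics(res)
            assert frac == pytest.approx(steps[0] / sum(steps), rel=0.05)

    def test_no_inputs_errors(self):
        res = ephys.count_inputs(_staircase([0.0]), noise_sd_nA=0.0,
                                 min_step_nA=0.1)
        with pytest.raises(ValueError):
            ephys.fiber_metrics(res)


class TestAmpaNmda:
    def test_arithmetic(self):
        assert ephys.ampa_nmda_ratio(1.0, 1.0) == 1.0
        assert ephys.ampa_nmda_ratio(2.0, 0.5) == 4.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            ephys.ampa_nmda_ratio(1.0, 0.0)

    def test_two_component_synthetic_response(self):
        # +40 mV response = fast AMPAR + slow NMDAR component; the late
        # window reads the NMDAR peak within 5%.
        fs = 20000.0
        t = np.arange(int(0.6 * fs)) / fs
        stim = 0.1
        ampa = 800.0 * _biexp_kernel(t - stim, 0.0005, 0.004)
        nmda = 400.0 * _biexp_kernel(t - stim, 0.004, 0.08)
        tr = Trace(ampa + nmda, fs, holding_mV=40.0)
        nmda_peak = ephys.late_peak(tr, stim, window_s=(0.02, 0.1))
        assert nmda_peak == pytest.approx(400.0, rel=0.05)
        ratio = ephys.ampa_nmda_ratio(1.0, nmda_peak / 1000.0)
        assert ratio == pytest.approx(1000.0 / nmda_peak, rel=1e-6)
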