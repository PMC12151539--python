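"""Synthetic-data generators: ground-truth exactness, invariants,
determinism."""

import numpy as np
import pytest

from synquant import synthio
from synquant.synthio import NOISELESS


class TestTerritory:
    def test_full_overlap_masks_identical(self):
        img, truth = synthio.gen_territory_image(overlap_target=1.0, noise_sd=0.0, seed=0)
        assert np.array_equal(truth.contra_mask, truth.ipsi_mask)
        assert all(f == pytest.approx(1.0) for f in truth.overlap_fraction_at.values())

    def test_zero_overlap_masks_disjoint(self):
        img, truth = synthio.gen_territory_image(overlap_target=0.0, noise_sd=0.0, seed=0)
        n_both = (truth.contra_mask & truth.ipsi_mask).sum()
        assert n_both <= 2  # quantile ties only
        # Rendered-edge smoothing leaves only a thin boundary strip where
        # both channels carry (sub-threshold-scale) signal.
        assert max(truth.overlap_fraction_at.values()) < 0.03

    def test_target_overlap_by_direct_pixel_count(self):
        img, truth = synthio.gen_territory_image(overlap_target=0.30, seed=1)
        roi = img.dlgn_mask
        # Brute-force count on the truth masks themselves.
        frac = float((truth.contra_mask & truth.ipsi_mask & roi).sum()) / roi.sum()
        assert 0.28 <= frac <= 0.32
        assert truth.overlap_fraction == pytest.approx(frac)

    def test_truth_fractions_monotone_in_threshold(self):
        _, truth = synthio.gen_territory_image(overlap_target=0.4, seed=5)
        ts = sorted(truth.overlap_fraction_at)
        fr = [truth.overlap_fraction_at[t] for t in ts]
        assert all(b <= a + 1e-12 for a, b in zip(fr, fr[1:]))
        assert all(0.0 <= f <= 1.0 for f in fr)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            synthio.gen_territory_image(overlap_target=1.2)

    def test_deterministic(self):
        a, _ = synthio.gen_territory_image(seed=9)
        b, _ = synthio.gen_territory_image(seed=9)
        assert np.array_equal(a.contra, b.contra)
        assert np.array_equal(a.ipsi, b.ipsi)


SMALL = dict(
    shape_px=(24, 96, 96), voxel_size_um=(0.4, 0.2, 0.2), n_cells=2,
    punctum_radius_um=0.5, sphere_radius_um=(1.0, 2.5),
    spheres_per_cell=(5, 10), max_cell_extent_um=3.0,
    outside_puncta_density=0.0, noise_model=NOISELESS,
)


class TestEngulfmentStack:
    def test_symmetric_puncta_ratio_one(self):
        _, truth = synthio.gen_engulfment_stack(
            puncta_per_cell={"ch_R": 3, "ch_L": 3}, seed=2, **SMALL
        )
        for cid in truth.cell_volume_um3:
            assert truth.engulfed(cid, "ch_R") == pytest.approx(truth.engulfed(cid, "ch_L"))

    def test_empty_channel_zero_truth(self):
        _, truth = synthio.gen_engulfment_stack(
            puncta_per_cell={"ch_R": 0, "ch_L": 5}, seed=2, **SMALL
        )
        assert all(truth.engulfed(cid, "ch_R") == 0.0 for cid in truth.cell_volume_um3)

    def test_single_punctum_analytic_volume(self):
        _, truth = synthio.gen_engulfment_stack(
            puncta_per_cell={"ch_R": 1, "ch_L": 0}, seed=3, **SMALL
        )
        expected = 4.0 / 3.0 * np.pi * 0.5**3  # ~0.524 um^3
        for cid in truth.cell_volume_um3:
            assert truth.engulfed(cid, "ch_R") == pytest.approx(expected)

    def test_engulfed_never_exceeds_cell_volume(self):
        _, truth = synthio.gen_engulfment_stack(
            puncta_per_cell={"ch_R": 4, "ch_L": 4}, seed=4, **SMALL
        )
        for (cid, ch), v in truth.engulfed_volume_um3.items():
            assert 0.0 <= v <= truth.cell_volume_um3[cid]

    def test_impossible_placement_raises(self):
        with pytest.raises(RuntimeError, match="1000 attempts"):
            synthio.gen_engulfment_stack(
                shape_px=(24, 96, 96), voxel_size_um=(0.4, 0.2, 0.2),
                n_cells=40, sphere_radius_um=(1.0, 2.5),
                max_cell_extent_um=3.0, noise_model=NOISELESS, seed=0,
            )

    def test_deterministic(self):
        s1, t1 = synthio.gen_engulfment_stack(seed=6, **SMALL)
        s2, t2 = synthio.gen_engulfment_stack(seed=6, **SMALL)
        assert np.array_equal(s1["cells"].data, s2["cells"].data)
        assert np.array_equal(t1.cell_labels, t2.cell_labels)
        assert t1.engulfed_volume_um3 == t2.engulfed_volume_um3


class TestPunctaStack:
    def test_all_paired(self):
        _, truth = synthio.gen_puncta_stack(
            n_pre=40, n_post=40, paired_fraction=1.0, pair_distance_um=0.15,
            noise_model=NOISELESS, seed=0,
        )
        assert truth.n_true_pairs == 40

    def test_none_paired(self):
        _, truth = synthio.gen_puncta_stack(
            n_pre=40, n_post=40, paired_fraction=0.0, noise_model=NOISELESS, seed=0
        )
        assert truth.n_true_pairs == 0

    def test_pair_count_from_flags(self):
        _, truth = synthio.gen_puncta_stack(
            n_pre=200, n_post=200, paired_fraction=0.5, noise_model=NOISELESS, seed=7
        )
        assert truth.n_true_pairs == 100
        assert truth.paired_flags.sum() == 100

    def test_geometry_of_paired_and_unpaired(self):
        _, truth = synthio.gen_puncta_stack(
            n_pre=60, n_post=60, paired_fraction=0.5, pair_distance_um=0.15,
            pairing_threshold_um=0.3, noise_model=NOISELESS, seed=1,
        )
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth.pre_centers).query(truth.post_centers)
        assert d[truth.paired_flags] == pytest.approx(0.15, abs=1e-9)
        assert (d[~truth.paired_flags] >= 0.6 - 1e-9).all()

    def test_pair_distance_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            synthio.gen_puncta_stack(pair_distance_um=0.35, pairing_threshold_um=0.3)


class TestEpscStaircase:
    def test_noiseless_two_steps_three_levels(self):
        curve, _ = synthio.gen_epsc_staircase(
            2, [1.0, 0.5], noise_sd_nA=0.0, seed=0
        )
        levels = np.unique(np.round(curve.amplitudes_nA, 9))
        assert set(levels) == {0.0, 1.0, 1.5}

    def test_zero_inputs_flat_zero(self):
        curve, truth = synthio.gen_epsc_staircase(0, [], noise_sd_nA=0.0, seed=0)
        assert np.allclose(curve.amplitudes_nA, 0.0)
        assert truth.n_inputs == 0

    def test_plateau_equals_cumulative_sum(self):
        steps = [0.3, 0.5, 0.2, 0.8, 0.4]
        curve, truth = synthio.gen_epsc_staircase(5, steps, noise_sd_nA=0.0, seed=3)
        assert curve.amplitudes_nA[-1] == pytest.approx(sum(steps))
        assert truth.step_amplitudes_nA == pytest.approx(steps)

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            synthio.gen_epsc_staircase(1, [1.0], stim_step_uA=0.0)


class TestMepsc:
    def test_zero_rate_empty_truth(self):
        trace, truth = synthio.gen_mepsc_trace(duration_s=2.0, rate_hz=0.0, seed=0)
        assert truth.mepsc_times_s == []

    def test_single_event_peak_is_amplitude(self):
        trace, truth = synthio.gen_mepsc_trace(
            duration_s=2.0, rate_hz=0.5, amplitude_range_pA=(-20.0, -20.0),
            noise_sd_pA=0.0, seed=1,
        )
        assert len(truth.mepsc_times_s) == 1
        assert trace.samples_pA.min() == pytest.approx(-20.0, abs=0.05)

    def test_event_count_recorded_exactly(self):
        trace, truth = synthio.gen_mepsc_trace(duration_s=180.0, rate_hz=1.0, seed=11)
        assert len(truth.mepsc_times_s) == len(truth.mepsc_amplitudes_pA) == 157
        assert all(a < 0 for a in truth.mepsc_amplitudes_pA)
        assert np.all(np.diff(truth.mepsc_times_s) > 0)

    def test_rejects_bad_kinetics(self):
        with pytest.raises(ValueError):
            synthio.gen_mepsc_trace(kinetics_ms=(5.0, 4.0))


class TestPairedPulse:
    def test_long_interval_identical_pulses(self):
        traces, truth = synthio.gen_paired_pulse(
            ppr_by_interval={1000: 1.0}, noise_sd_pA=0.0, seed=0
        )
        tr = traces[1000]
        t1, t2 = truth.stim_times_s[1000]
        fs = tr.sampling_hz
        first = -tr.samples_pA[int(t1 * fs):int(t2 * fs)].min()
        second = -tr.samples_pA[int(t2 * fs):].min()
        assert second / first == pytest.approx(1.0, abs=0.01)

    def test_scaling_second_peak(self):
        traces, truth = synthio.gen_paired_pulse(
            ppr_by_interval={1000: 0.5}, noise_sd_pA=0.0, seed=0
        )
        tr = traces[1000]
        t1, t2 = truth.stim_times_s[1000]
        fs = tr.sampling_hz
        first = -tr.samples_pA[int(t1 * fs):int(t2 * fs)].min()
        second = -tr.samples_pA[int(t2 * fs):].min()
        assert second / first == pytest.approx(0.5, abs=0.01)

    def test_default_intervals(self):
        traces, truth = synthio.gen_paired_pulse(noise_sd_pA=0.0, seed=0)
        assert set(traces) == {50, 150, 250, 500, 1000}
        assert set(truth.ppr_true) == {50, 150, 250, 500, 1000}


def test_generators_use_independent_streams():
    # Same seed, different components: outputs differ (substreams), and
    # regenerating one component is unaffected by generating another.
    img1, _ = synthio.gen_territory_image(seed=42)
    _ = synthio.gen_mepsc_trace(duration_s=1.0, seed=42)
    img2, _ = synthio.gen_territory_image(seed=42)
    assert np.array_equal(img1.contra, img2.contra)
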