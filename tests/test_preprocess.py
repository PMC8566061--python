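import numpy as np
import pytest

from fixmodal.io_gaze import FixationTrial, segment_trials
from fixmodal.preprocess import (
    AlignmentError,
    PreprocessConfig,
    ThresholdError,
    WindowError,
    align_signal_to_target,
    apply_target_shift,
    compute_fix_vel_threshold,
    compute_velocity,
    detect_saccades_velocity,
    filter_complete_fixations,
    preprocess_recording,
    remove_anticipatory_saccades,
    remove_blink_saccades,
    remove_parabolic_segments,
    select_analysis_window,
)
from fixmodal.synthetic import SyntheticConfig, generate_recording

from conftest import make_recording


class TestComputeVelocity:
    def test_constant_position_zero_velocity(self, flat_recording):
        vel = compute_velocity(flat_recording)
        assert np.nanmax(vel.vr) == 0.0

    def test_linear_slope_scaled_to_deg_per_sec(self):
        x = 0.01 * np.arange(100.0)
        rec = make_recording(x, np.zeros(100))
        vel = compute_velocity(rec)
        np.testing.assert_allclose(vel.vx[1:-1], 10.0, atol=1e-9)

    def test_nan_propagates_one_sample_each_side(self):
        x = np.zeros(50)
        x[20] = np.nan
        vel = compute_velocity(make_recording(x, np.zeros(50)))
        assert np.isnan(vel.vr[19]) and np.isnan(vel.vr[20]) and np.isnan(vel.vr[21])
        assert np.isfinite(vel.vr[18]) and np.isfinite(vel.vr[22])

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            compute_velocity(make_recording([0.0, 0.0], [0.0, 0.0]))


class TestAlignment:
    def test_eye_identical_to_target_gives_zero(self):
        tx = np.repeat([0.0, 3.0], 300)
        rec = make_recording(tx, np.zeros(600), tx=tx, ty=np.zeros(600))
        assert align_signal_to_target(rec, (0, 400)) == 0

    def test_known_delay_recovered_and_matches_brute_force(self):
        delay = 237
        tx = np.repeat([0.0, 4.0, -2.0, 6.0], 500)
        eye = np.concatenate((np.full(delay, tx[0]), tx[:-delay]))
        rec = make_recording(eye, np.zeros(2000), tx=tx, ty=np.zeros(2000))
        shift = align_signal_to_target(rec, (0, 400))
        # independent oracle: exhaustive sweep of the mean |difference|
        costs = {}
        for s in range(0, 401):
            d = np.abs(eye[s:] - tx[: 2000 - s])
            costs[s] = d.mean()
        assert shift == min(costs, key=lambda s: (costs[s], s)) == delay

    def test_tie_breaks_to_smaller_shift(self, flat_recording):
        # eye == target == 0 everywhere: every shift costs 0
        assert align_signal_to_target(flat_recording, (0, 100)) == 0

    def test_all_nan_overlap_raises(self):
        rec = make_recording(np.full(50, np.nan), np.full(50, np.nan))
        with pytest.raises(AlignmentError):
            align_signal_to_target(rec, (0, 10))

    def test_apply_shift_delays_target(self):
        tx = np.repeat([0.0, 1.0], 50)
        rec = make_recording(np.zeros(100), np.zeros(100), tx=tx, ty=np.zeros(100))
        out = apply_target_shift(rec, 10)
        assert out.tx[59] == 0.0 and out.tx[60] == 1.0


class TestAnalysisWindow:
    def test_1000_sample_trial(self, flat_recording):
        trial = segment_trials(flat_recording)[0]
        trial.window = (0, 1000)
        trial.valid_mask = trial.valid_mask[:1000]
        start, stop = select_analysis_window(trial)
        assert (start, stop) == (191, 691)
        assert stop - start == 500

    def test_691_sample_trial_is_boundary(self, flat_recording):
        trial = FixationTrial(flat_recording, 0, (0.0, 0.0), (0, 691))
        start, stop = select_analysis_window(trial)
        assert stop == 691

    def test_690_sample_trial_fails(self, flat_recording):
        trial = FixationTrial(flat_recording, 0, (0.0, 0.0), (0, 690))
        with pytest.raises(WindowError):
            select_analysis_window(trial)


class TestFixVelThreshold:
    def test_degenerate_spread(self):
        x = 0.005 * np.arange(2000.0)  # constant 5 deg/s slope
        rec = make_recording(x, np.zeros(2000))
        vel = compute_velocity(rec)
        assert compute_fix_vel_threshold(rec, vel) == pytest.approx(5.0)

    def test_matches_direct_recomputation(self, rng):
        x = np.cumsum(rng.normal(0, 0.005, 5000))
        rec = make_recording(x, np.zeros(5000))
        vel = compute_velocity(rec)
        got = compute_fix_vel_threshold(rec, vel)
        vr = vel.vr[np.isfinite(vel.vr) & (vel.vr < 55)]
        m = np.median(vr)
        d = np.median(np.abs(vr - m))
        assert got == pytest.approx(m + 5 * 1.4826 * d)

    def test_all_nan_raises(self):
        rec = make_recording(np.full(2000, np.nan), np.full(2000, np.nan))
        vel = compute_velocity(rec)
        with pytest.raises(ThresholdError):
            compute_fix_vel_threshold(rec, vel)


class TestBlinkSaccades:
    def test_quiet_flanks_mask_only_the_gap(self):
        x = np.zeros(2000)
        x[1000:1100] = np.nan
        rec = make_recording(x, np.zeros(2000))
        vel = compute_velocity(rec)
        ivs = remove_blink_saccades(rec, vel, fixvelt=5.0)
        assert len(ivs) == 1
        # velocity NaN bleeds one sample each side of the gap, so the run of
        # three quiet samples ends two samples before the gap
        assert ivs[0].start >= 998 and ivs[0].end <= 1102
        assert np.isfinite(rec.x[995]) and np.isfinite(rec.x[1105])

    def test_high_velocity_ramp_masked_back_to_quiet_run(self):
        x = np.zeros(2000)
        ramp = np.linspace(0, 3.0, 50)  # ~60 deg/s, above threshold
        x[950:1000] = ramp
        x[1000:1100] = np.nan
        rec = make_recording(x, np.zeros(2000))
        vel = compute_velocity(rec)
        ivs = remove_blink_saccades(rec, vel, fixvelt=30.0)
        # hand-simulated backward march: the ramp's first sample (950) still
        # has zero central-difference velocity, so the last 3-below-threshold
        # run is 947..949 and masking starts right at the ramp, sample 950
        assert ivs[0].start == 950
        assert np.isnan(rec.x[950:1100]).all()
        assert np.isfinite(rec.x[949])

    def test_no_nan_leaves_recording_unchanged(self, flat_recording):
        vel = compute_velocity(flat_recording)
        before = flat_recording.x.copy()
        assert remove_blink_saccades(flat_recording, vel, 5.0) == []
        np.testing.assert_array_equal(flat_recording.x, before)


def _gaussian_bump_recording(peak=300.0, center=500, width=10.0, n=1000):
    """Position whose radial velocity is a Gaussian bump on a zero baseline."""
    t = np.arange(n)
    v = peak * np.exp(-0.5 * ((t - center) / width) ** 2)  # deg/s
    x = np.cumsum(v) / 1000.0
    return make_recording(x, np.zeros(n))


class TestVelocitySaccades:
    def test_zero_velocity_no_saccades(self, flat_recording):
        vel = compute_velocity(flat_recording)
        assert detect_saccades_velocity(flat_recording, vel) == []

    def test_bump_interval_brackets_entire_bump(self):
        rec = _gaussian_bump_recording()
        vel = compute_velocity(rec)
        vr0 = vel.vr.copy()
        ivs = detect_saccades_velocity(rec, vel)
        assert len(ivs) == 1
        # oracle: brute-force scan for local minima below 30 deg/s
        above = vr0 > 55
        lo = np.flatnonzero(above).min()
        hi = np.flatnonzero(above).max()
        candidates_left = [
            i for i in range(1, lo)
            if vr0[i] < 30 and vr0[i] <= vr0[i - 1] and vr0[i] <= vr0[i + 1]
        ]
        candidates_right = [
            i for i in range(hi + 1, len(vr0) - 1)
            if vr0[i] < 30 and vr0[i] <= vr0[i - 1] and vr0[i] <= vr0[i + 1]
        ]
        assert ivs[0].start == max(candidates_left)
        assert ivs[0].end == min(candidates_right) + 1
        # the interval brackets every sample of elevated velocity
        assert np.isnan(rec.x[ivs[0].start : ivs[0].end]).all()

    def test_peak_below_threshold_not_detected(self):
        rec = _gaussian_bump_recording(peak=54.0)
        vel = compute_velocity(rec)
        assert detect_saccades_velocity(rec, vel) == []

    def test_idempotent_on_own_output(self):
        rec = _gaussian_bump_recording()
        vel = compute_velocity(rec)
        first = detect_saccades_velocity(rec, vel)
        assert first
        vel2 = compute_velocity(rec)
        assert detect_saccades_velocity(rec, vel2) == []


class TestParabolicSegments:
    def test_exact_parabola_flagged(self):
        i = np.arange(27.0)
        x = np.zeros(200)
        x[50:77] = 0.001 * (i - 13) ** 2
        rec = make_recording(x, np.zeros(200))
        ivs = remove_parabolic_segments(rec)
        assert ivs and any(iv.start <= 50 and iv.end >= 77 for iv in ivs)

    def test_pure_line_not_flagged(self):
        rec = make_recording(0.01 * np.arange(200.0), np.zeros(200))
        assert remove_parabolic_segments(rec) == []

    def test_constant_window_not_flagged(self, flat_recording):
        assert remove_parabolic_segments(flat_recording) == []

    @pytest.mark.parametrize(
        "beta,expected", [(0.00056, True), (0.00054, False)]
    )
    def test_beta_threshold_boundary(self, beta, expected):
        i = np.arange(27.0)
        x = np.zeros(100)
        x[30:57] = beta * (i - 13) ** 2
        rec = make_recording(x, np.zeros(100))
        assert bool(remove_parabolic_segments(rec)) is expected

    def test_r2_threshold_boundary(self, rng):
        # a strong parabola drowned in noise: R^2 falls below 0.6
        i = np.arange(27.0)
        x = np.zeros(100)
        x[30:57] = 0.001 * (i - 13) ** 2 + rng.normal(0, 0.2, 27)
        rec = make_recording(x, np.zeros(100))
        assert remove_parabolic_segments(rec) == []

    def test_windows_containing_nan_skipped(self):
        i = np.arange(27.0)
        x = np.zeros(100)
        x[30:57] = 0.001 * (i - 13) ** 2
        x[40] = np.nan
        rec = make_recording(x, np.zeros(100))
        # every window over the parabola now contains the NaN
        ivs = remove_parabolic_segments(rec)
        assert all(iv.end <= 40 or iv.start > 40 for iv in ivs)


class TestAnticipatorySaccades:
    def _trial(self, x, y, target):
        rec = make_recording(
            x, y, tx=np.full(len(x), target[0]), ty=np.full(len(x), target[1])
        )
        return FixationTrial(rec, 0, target, (0, len(x)))

    def test_stable_on_target_untouched(self):
        trial = self._trial(np.zeros(1000), np.zeros(1000), (0.0, 0.0))
        assert remove_anticipatory_saccades(trial, (5.0, 0.0)) == []
        assert trial.valid_mask.all()

    def test_segment_near_next_target_masked(self):
        # final 150 ms sits 5 deg from the current target, 0.2 deg from next
        x = np.zeros(1000)
        x[850:] = 5.2
        x[840:850] = np.nan  # removed saccade gap separates the segments
        trial = self._trial(x, np.zeros(1000), (0.0, 0.0))
        ivs = remove_anticipatory_saccades(trial, (5.0, 0.0))
        assert len(ivs) == 1 and ivs[0].start == 850 and ivs[0].end == 1000
        assert np.isnan(trial.recording.x[850:]).all()
        assert np.isfinite(trial.recording.x[:840]).all()

    def test_far_from_both_targets_retained(self):
        x = np.zeros(1000)
        x[850:] = 5.0
        x[840:850] = np.nan
        trial = self._trial(x, np.zeros(1000), (0.0, 0.0))
        # next target at 10 deg: the 5-deg segment is 5 deg from both
        assert remove_anticipatory_saccades(trial, (10.0, 0.0)) == []

    def test_last_trial_never_touched(self):
        x = np.zeros(1000)
        x[850:] = 5.2
        trial = self._trial(x, np.zeros(1000), (0.0, 0.0))
        assert remove_anticipatory_saccades(trial, None) == []


class TestCompletenessFilter:
    def _trial_with_window(self, x):
        rec = make_recording(x, np.zeros(len(x)))
        return FixationTrial(rec, 0, (0.0, 0.0), (0, len(x)))

    def test_full_window_kept(self):
        trial = self._trial_with_window(np.zeros(1000))
        assert filter_complete_fixations([trial]) == [trial]

    def test_499_valid_samples_excluded(self):
        x = np.zeros(1000)
        x[191] = np.nan  # first window sample
        trial = self._trial_with_window(x)
        assert filter_complete_fixations([trial]) == []

    def test_interior_gap_excludes(self):
        x = np.zeros(1001)
        x[400] = np.nan
        trial = self._trial_with_window(x)
        assert filter_complete_fixations([trial]) == []


class TestPreprocessRecording:
    def test_masking_is_monotone_across_steps(self):
        rec, _ = generate_recording(SyntheticConfig(n_trials=20), seed=3)
        before = np.isnan(rec.x).sum()
        _, _, report = preprocess_recording(rec)
        work = report.attrs["recording"]
        # original NaN (blinks) are still NaN, and the count only grew
        assert np.isnan(work.x[np.isnan(rec.x)]).all()
        assert np.isnan(work.x).sum() >= before
        assert (report["samples_masked"] >= 0).all()

    def test_surviving_sets_are_clean(self):
        rec, _ = generate_recording(SyntheticConfig(n_trials=20), seed=4)
        sets, kept, _ = preprocess_recording(rec)
        assert len(sets) == 2 * len(kept)
        for s in sets:
            assert len(s.values) == 500 and np.isfinite(s.values).all()

    def test_noiseless_recording_keeps_all_interior_trials(self):
        cfg = SyntheticConfig(
            n_trials=10, noise_sd=1e-4, sensor_noise_sd=1e-4, blink_prob=0.0,
            regime_weights={"unimodal": 1.0, "drift": 0.0, "microsaccade_shift": 0.0},
        )
        rec, _ = generate_recording(cfg, seed=5)
        _, kept, _ = preprocess_recording(rec)
        # the last trial is lost to the latency shift; all others survive
        assert len(kept) >= 8
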