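import dataclasses

import numpy as np
import pytest
from scipy import stats

from avpercept.synthetic_data import (
    NON_COINCIDENT_OFFSETS, SENTINEL, SimParams, build_design,
    draw_subject_profile, minimum_jerk, read_trials, simulate_dataset,
    simulate_decision_time, simulate_percept, simulate_trajectory,
    write_trials)


def profile(params=None, seed=0):
    return draw_subject_profile(params or SimParams(),
                                np.random.default_rng(seed))


class TestDesign:
    @pytest.mark.parametrize("n_reps,per_task,uni,coinc,noncoinc",
                             [(15, 450, 75, 75, 300), (1, 30, 5, 5, 20)])
    def test_counts_scale_with_repetitions(self, n_reps, per_task, uni,
                                           coinc, noncoinc):
        d = build_design(2, n_reps)
        for (_, _), block in d.groupby(["subject", "task"]):
            assert len(block) == per_task
            assert (block["mode"] == 0).sum() == uni
            bi = block[block["mode"] == 1]
            assert (bi["xs"] == bi["xp"]).sum() == coinc
            assert (bi["xs"] != bi["xp"]).sum() == noncoinc

    def test_secondary_positions_enumerate_offsets(self):
        d = build_design(1, 1)
        bi = d[d["mode"] == 1]
        # brute-force check of the +/-20 deg bound over all primaries
        assert bi["xs"].min() == -20 and bi["xs"].max() == 20
        at10 = bi[(bi["xp"] == 10) & (bi["xs"] != 10)]
        assert sorted(set(at10["xs"])) == [0.0, 5.0, 15.0, 20.0]
        for xp, sub in bi.groupby("xp"):
            assert sorted(set(sub["xs"] - xp)) == sorted(
                (0.0,) + NON_COINCIDENT_OFFSETS)

    def test_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            build_design(0, 15)
        with pytest.raises(ValueError):
            build_design(2, 0)


class TestSubjectProfile:
    def test_zero_spread_reproduces_population_means(self):
        p = dataclasses.replace(
            SimParams(), bias_sd=0.0, sigma_jitter_sd=0.0, w_sd=0.0,
            delta_ecc_sd=0.0, sigma_logT_jitter_sd=0.0, subject_T_offset_sd=0.0)
        prof = profile(p)
        assert prof.bias == 0.0
        assert prof.sigma_a_uni == p.sigma_a_uni
        assert prof.w == pytest.approx(p.w)
        assert prof.subject_T_offset == 0.0

    def test_same_seed_same_profile(self):
        assert profile(seed=42) == profile(seed=42)

    def test_bias_spread_matches_configuration(self):
        rng = np.random.default_rng(1)
        p = SimParams()
        draws = [draw_subject_profile(p, rng).bias for _ in range(10_000)]
        assert np.std(draws) == pytest.approx(p.bias_sd, rel=0.05)


class TestPercept:
    def test_no_fusion_limit(self):
        prof = dataclasses.replace(profile(), w=0.0, bias=1.5)
        rng = np.random.default_rng(0)
        draws = simulate_percept(prof, 0, [0.0] * 4000, [10.0] * 4000, rng)
        assert np.mean(draws) == pytest.approx(1.5, abs=0.3)

    def test_deterministic_fusion_rule(self):
        prof = dataclasses.replace(profile(), w=0.95, bias=0.0,
                                   sigma_a_bi=1e-12)
        val = simulate_percept(prof, 0, 0.0, 10.0, np.random.default_rng(0))
        assert val == pytest.approx(9.5, abs=1e-6)

    def test_visual_task_segregates_secondary(self):
        # percept distribution must not depend on the secondary position
        prof = profile()
        rng = np.random.default_rng(7)
        a = simulate_percept(prof, 1, [0.0] * 10_000, [-10.0] * 10_000, rng)
        b = simulate_percept(prof, 1, [0.0] * 10_000, [10.0] * 10_000, rng)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_off_grid_raises(self):
        with pytest.raises(ValueError):
            simulate_percept(profile(), 0, 3.0, SENTINEL,
                             np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_percept(profile(), 0, 0.0, 12.0, np.random.default_rng(0))


class TestDecisionTime:
    def test_noiseless_limit_is_exact_median(self):
        prof = dataclasses.replace(profile(), sigma_logT=1e-12,
                                   subject_T_offset=0.0)
        t = simulate_decision_time(prof, 1, 0, SENTINEL,
                                   np.random.default_rng(0))
        assert t == pytest.approx(np.exp(prof.mu_logT[1][0]), rel=1e-6)

    def test_task_and_mode_orderings(self):
        prof = profile()
        rng = np.random.default_rng(3)
        n = 100_000
        t_au = simulate_decision_time(prof, 0, [0] * n, [np.nan] * n, rng)
        t_ab = simulate_decision_time(prof, 0, [1] * n, [5.0] * n, rng)
        t_vu = simulate_decision_time(prof, 1, [0] * n, [np.nan] * n, rng)
        t_vb = simulate_decision_time(prof, 1, [1] * n, [5.0] * n, rng)
        assert np.mean(t_au) > np.mean(t_vu)
        assert np.mean(t_ab) > np.mean(t_vb)
        assert np.mean(t_au) > np.mean(t_ab)
        assert np.mean(t_vu) > np.mean(t_vb)

    def test_eccentricity_penalty_is_multiplicative(self):
        prof = profile()
        rng = np.random.default_rng(4)
        n = 100_000
        t_ecc = simulate_decision_time(prof, 0, [1] * n, [20.0] * n, rng)
        t_mid = simulate_decision_time(prof, 0, [1] * n, [5.0] * n, rng)
        # closed-form log-normal mean ratio: exp(delta_ecc)
        assert np.mean(t_ecc) / np.mean(t_mid) == pytest.approx(
            np.exp(prof.delta_ecc), rel=0.02)

    def test_mode_secondary_consistency_enforced(self):
        with pytest.raises(ValueError):
            simulate_decision_time(profile(), 0, 0, 5.0,
                                   np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_decision_time(profile(), 0, 1, SENTINEL,
                                   np.random.default_rng(0))


class TestTrajectory:
    def test_zero_amplitude_is_constant(self):
        traj = simulate_trajectory(40.0, 0.5, 1.0, 100.0)
        assert np.ptp(traj.positions) == 0.0

    def test_velocity_integrates_to_displacement(self):
        traj = simulate_trajectory(-20.0, 0.5, 1.2, 500.0)
        disp = np.trapezoid(np.gradient(traj.positions, traj.times),
                            traj.times)
        assert disp == pytest.approx(-60.0, abs=0.05)

    def test_peak_speed_closed_form(self):
        # minimum-jerk peak speed = 1.875 |d| / T
        ts = np.linspace(0.0, 1.1, 4000)
        pos = minimum_jerk(ts, 40.0, -5.0, 1.1)
        peak = np.max(np.abs(np.gradient(pos, ts)))
        assert peak == pytest.approx(1.875 * 45.0 / 1.1, rel=1e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_trajectory(0.0, 0.5, -1.0, 100.0)
        with pytest.raises(ValueError):
            simulate_trajectory(55.0, 0.5, 1.0, 100.0)


class TestDataset:
    def test_default_size_and_unimodal_count(self, default_table):
        assert len(default_table) == 9000
        for (_, _), block in default_table.groupby(["subject", "task"]):
            assert len(block) == 450
            assert block["xs"].isna().sum() == 75

    def test_seed_determinism(self, tmp_path):
        a = simulate_dataset(SimParams(seed=99))
        b = simulate_dataset(SimParams(seed=99))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trials(a, pa)
        write_trials(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_csv_round_trip_preserves_sentinel(self, tmp_path):
        t = simulate_dataset(SimParams(seed=2, n_subjects=2, n_reps=1))
        path = tmp_path / "trials.csv"
        write_trials(t, path)
        assert "NA_UNIMODAL" in path.read_text()
        back = read_trials(path)
        assert back["xs"].isna().sum() == t["xs"].isna().sum()
        np.testing.assert_allclose(back["response_raw"], t["response_raw"])

    def test_log_times_are_normal_within_cells(self, default_table):
        # the time model is Gaussian on the log scale per (task, mode, subject)
        pvals = [
            stats.shapiro(np.log(cell["decision_time"]))[1]
            for _, cell in default_table.groupby(["subject", "task", "mode"])
            if len(cell) > 20
        ]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95
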