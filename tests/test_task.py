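"""Schedules, agents, and the ground-truth BOLD generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pitgimme as pg
from pitgimme.task import (
    ConfigError,
    PhaseMismatchError,
    SimulationError,
    binary_input_columns,
    convolved_inputs_microtime,
    read_events,
    write_events,
)


class TestSchedules:
    def test_pavlovian_counts(self, task_config):
        sched = pg.gen_pavlovian_schedule(task_config, seed=0)
        cs = sched[sched.trial_type.str.startswith("CS")]
        assert len(cs) == 45
        assert cs.trial_type.value_counts().eq(9).all()

    def test_pavlovian_single_rep(self):
        cfg = pg.TaskConfig(pav_reps_per_pairing=1)
        sched = pg.gen_pavlovian_schedule(cfg, seed=3)
        assert len(sched[sched.trial_type.str.startswith("CS")]) == 5

    def test_pavlovian_iti_choices(self, task_config):
        for seed in range(5):
            sched = pg.gen_pavlovian_schedule(task_config, seed=seed)
            itis = sched[sched.trial_type == "fixation"].duration
            assert set(itis.unique()) <= {7.0, 9.0, 11.0}

    def test_transfer_counts(self, task_config):
        sched = pg.gen_transfer_schedule(task_config, seed=1)
        cs = sched[sched.trial_type.str.startswith("CS")]
        assert len(cs) == 60
        assert cs.trial_type.value_counts().eq(12).all()
        assert (cs.duration == task_config.cs_duration_s).all()

    def test_transfer_empty(self):
        cfg = pg.TaskConfig(transfer_reps_per_cs=0)
        assert len(pg.gen_transfer_schedule(cfg, seed=0)) == 0

    def test_recharge_durations_in_range(self, task_config):
        for seed in range(5):
            sched = pg.gen_transfer_schedule(task_config, seed=seed)
            rech = sched[sched.trial_type == "recharge"].duration
            assert ((rech >= 2.0) & (rech <= 12.0)).all()

    def test_onsets_strictly_increasing_no_overlap(self, task_config):
        for gen in (pg.gen_pavlovian_schedule, pg.gen_transfer_schedule):
            sched = gen(task_config, seed=11)
            onsets = sched.onset.to_numpy()
            ends = onsets + sched.duration.to_numpy()
            assert (np.diff(onsets) > 0).all()
            assert (ends[:-1] <= onsets[1:] + 1e-9).all()

    def test_determinism_and_seed_sensitivity(self, task_config):
        a = pg.gen_transfer_schedule(task_config, seed=5)
        b = pg.gen_transfer_schedule(task_config, seed=5)
        c = pg.gen_transfer_schedule(task_config, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)
        # marginal counts identical across seeds
        va = a[a.trial_type.str.startswith("CS")].trial_type.value_counts()
        vc = c[c.trial_type.str.startswith("CS")].trial_type.value_counts()
        pd.testing.assert_series_equal(va.sort_index(), vc.sort_index())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(reps=st.integers(0, 6), seed=st.integers(0, 1000))
    def test_counting_conservation_property(self, reps, seed):
        cfg = pg.TaskConfig(pav_reps_per_pairing=max(reps, 1), transfer_reps_per_cs=reps)
        pav = pg.gen_pavlovian_schedule(cfg, seed=seed)
        tra = pg.gen_transfer_schedule(cfg, seed=seed)
        assert len(pav[pav.trial_type.str.startswith("CS")]) == max(reps, 1) * 5
        assert len(tra[tra.trial_type.str.startswith("CS")]) == reps * 5

    def test_events_roundtrip(self, task_config, tmp_path):
        sched = pg.gen_transfer_schedule(task_config, seed=2)
        path = tmp_path / "events.tsv"
        write_events(sched, path)
        back = read_events(path)
        assert np.allclose(back.onset, sched.onset, atol=1e-6)
        assert (back.trial_type == sched.trial_type).all()


class TestInstrumental:
    def test_perfect_agent_no_attacks(self, task_config):
        agent = pg.AgentParams(learn_start_p=1.0, learn_end_p=1.0)
        _, _, attacks = pg.gen_instrumental_run(task_config, agent, seed=0)
        assert len(attacks) == 0

    def test_never_pressing_agent_one_attack_per_second(self, task_config):
        agent = pg.AgentParams(learn_start_p=0.0, learn_end_p=0.0)
        _, record, attacks = pg.gen_instrumental_run(task_config, agent, seed=0)
        assert len(attacks) == 180
        assert len(record) == 0

    def test_learning_agent_attacks_decline(self, task_config):
        from pitgimme.behavior import bin_attacks

        agent = pg.AgentParams()
        firsts, lasts = [], []
        for seed in range(200):
            _, _, attacks = pg.gen_instrumental_run(task_config, agent, seed=seed)
            bins = bin_attacks(attacks)
            firsts.append(bins[0])
            lasts.append(bins[-1])
        assert np.mean(firsts) > np.mean(lasts)

    def test_invalid_session_length(self):
        with pytest.raises(ConfigError):
            pg.TaskConfig(session_length_s=0)


class TestTransferBehavior:
    def test_zero_baseline_no_presses(self, task_config):
        sched = pg.gen_transfer_schedule(task_config, seed=1)
        agent = pg.AgentParams(baseline_rate=0.0, specific_gain=5.0)
        rec = pg.gen_transfer_behavior(sched, agent, seed=1)
        assert len(rec) == 0

    def test_phase_mismatch_rejected(self, task_config):
        pav = pg.gen_pavlovian_schedule(task_config, seed=1)
        with pytest.raises(PhaseMismatchError):
            pg.gen_transfer_behavior(pav, pg.AgentParams(), seed=1)

    def test_poisson_mean_under_specific_gain(self, task_config):
        """R1 count in CS1 windows: rate x gain x duration = 0.1 x 5 x 4 = 2 per trial."""
        agent = pg.AgentParams(baseline_rate=0.1, specific_gain=5.0, general_gain=1.0)
        total, trials = 0, 0
        for seed in range(300):
            sched = pg.gen_transfer_schedule(task_config, seed=seed)
            rec = pg.gen_transfer_behavior(sched, agent, seed=seed)
            cs1 = sched[sched.trial_type == "CS1"]
            r1 = rec[rec.response == "R1"]
            for row in cs1.itertuples(index=False):
                total += (
                    (r1.timestamp >= row.onset) & (r1.timestamp < row.onset + row.duration)
                ).sum()
                trials += 1
        mean = total / trials
        # Monte-Carlo tolerance: sd of the mean ~ sqrt(2/3600) ~ 0.024
        assert abs(mean - 2.0) < 0.1

    def test_null_agent_rate_equality(self, task_config):
        """With all gains 1, per-second rates match across stimuli and intervals."""
        from pitgimme.behavior import transfer_rates

        frames = []
        for seed in range(40):
            sched = pg.gen_transfer_schedule(task_config, seed=seed)
            rec = pg.gen_transfer_behavior(sched, pg.null_agent(), seed=seed)
            frames.append(transfer_rates(rec, sched, subject_id=f"s{seed}"))
        tab = pd.concat(frames)
        by_stim = tab.groupby("stimulus")["rate"].mean()
        by_int = tab.groupby("interval")["rate"].mean()
        assert by_stim.max() - by_stim.min() < 0.08
        assert abs(by_int["pre"] - by_int["stim"]) < 0.05

    def test_no_presses_during_recharge(self, task_config):
        agent = pg.AgentParams(baseline_rate=1.0)
        sched = pg.gen_transfer_schedule(task_config, seed=9)
        rec = pg.gen_transfer_behavior(sched, agent, seed=9)
        for row in sched[sched.trial_type == "recharge"].itertuples(index=False):
            inside = (rec.timestamp >= row.onset) & (rec.timestamp < row.onset + row.duration)
            assert inside.sum() == 0


class TestBoldSimulation:
    def test_zero_truth_gives_white_noise(self, short_config):
        truth = pg.TrueNetwork(
            np.zeros((5, 5)),
            np.zeros((5, 5)),
            np.zeros((5, 2)),
            np.zeros((5, 2, 5)),
            np.full(5, 0.7),
            ({"peak_delay_s": 6.0, "dispersion": 1.0},),
        )
        sched = pg.gen_transfer_schedule(short_config, seed=0)
        mat = pg.simulate_bold(truth, [sched], short_config, seed=0)[0]
        sds = mat[list(pg.ROI_ORDER)].std()
        assert np.allclose(sds, 0.7, atol=0.12)
        lag1 = np.corrcoef(mat["putamen_l"][1:], mat["putamen_l"][:-1])[0, 1]
        assert abs(lag1) < 0.15

    def test_ar_autocorrelation_matches_theory(self):
        cfg = pg.TaskConfig(n_trs=540)
        phi = np.zeros((5, 5))
        phi[0, 0] = 0.6
        truth = pg.TrueNetwork(
            np.zeros((5, 5)), phi, np.zeros((5, 2)), np.zeros((5, 2, 5)),
            np.ones(5), ({"peak_delay_s": 6.0, "dispersion": 1.0},),
        )
        sched = pg.gen_transfer_schedule(cfg, seed=4)
        acs = []
        for seed in range(10):
            mat = pg.simulate_bold(truth, [sched], cfg, seed=seed)[0]
            y = mat["putamen_l"].to_numpy()
            acs.append(np.corrcoef(y[1:], y[:-1])[0, 1])
        assert abs(np.mean(acs) - 0.6) < 0.05

    def test_direct_input_recovered_by_ols(self):
        """gamma(putamen_l, specific) = 0.5 recovered by regressing on the true
        convolved input."""
        cfg = pg.TaskConfig(n_trs=540)
        gamma = np.zeros((5, 2))
        gamma[0, 0] = 0.5
        hrf = {"peak_delay_s": 6.0, "dispersion": 1.0}
        truth = pg.TrueNetwork(
            np.zeros((5, 5)), np.zeros((5, 5)), gamma, np.zeros((5, 2, 5)),
            np.ones(5), (hrf,),
        )
        sched = pg.gen_transfer_schedule(cfg, seed=8)
        u = convolved_inputs_microtime(sched, hrf, cfg.tr_s, cfg.n_trs)[:, 0]
        betas = []
        for seed in range(20):
            mat = pg.simulate_bold(truth, [sched], cfg, seed=seed)[0]
            x = np.column_stack([np.ones(cfg.n_trs), u])
            b = np.linalg.lstsq(x, mat["putamen_l"].to_numpy(), rcond=None)[0][1]
            betas.append(b)
        assert abs(np.mean(betas) - 0.5) < 0.05

    def test_stationary_covariance_closed_form(self, benchmark_truth):
        """With u = 0, the sample covariance approaches the VAR stationary covariance."""
        cfg = pg.TaskConfig(n_trs=5000, transfer_reps_per_cs=0)
        sched = pg.gen_transfer_schedule(cfg, seed=0)  # empty -> u = 0
        truth = pg.benchmark_network(1)
        mat = pg.simulate_bold(truth, [sched], cfg, seed=3)[0]
        y = mat[list(pg.ROI_ORDER)].to_numpy()
        s = np.cov(y, rowvar=False)
        b = np.linalg.inv(np.eye(5) - truth.a)
        bphi = b @ truth.phi
        szeta = b @ np.diag(truth.noise_sd**2) @ b.T
        vec = np.linalg.solve(
            np.eye(25) - np.kron(bphi, bphi), szeta.reshape(-1)
        ).reshape(5, 5)
        assert np.allclose(s, vec, atol=0.15)

    def test_singular_system_raises(self, short_config):
        a = np.zeros((5, 5))
        a[0, 1], a[1, 0] = 0.999, 0.999  # near-singular 2-cycle: (I-A) ~ rank deficient
        a2 = a.copy()
        a2[0, 1] = 1.0
        a2[1, 0] = 1.0
        with pytest.raises((ConfigError, SimulationError)):
            truth = pg.TrueNetwork(
                a2, np.zeros((5, 5)), np.zeros((5, 2)), np.zeros((5, 2, 5)),
                np.ones(5), ({"peak_delay_s": 6.0, "dispersion": 1.0},),
            )
            sched = pg.gen_transfer_schedule(short_config, seed=0)
            pg.simulate_bold(truth, [sched], short_config, seed=0)

    def test_network_validation(self):
        with pytest.raises(ConfigError):
            pg.TrueNetwork(
                np.eye(5) * 0.5, np.zeros((5, 5)), np.zeros((5, 2)),
                np.zeros((5, 2, 5)), np.ones(5), ({},),
            )  # nonzero diagonal
        with pytest.raises(ConfigError):
            pg.TrueNetwork(
                np.zeros((5, 5)), np.eye(5) * 1.2, np.zeros((5, 2)),
                np.zeros((5, 2, 5)), np.ones(5), ({},),
            )  # non-stationary

    def test_truth_structure_and_json_roundtrip(self, benchmark_truth, tmp_path):
        st = benchmark_truth.structure()
        assert len(st.non_ar_edges()) == 4
        path = tmp_path / "net.json"
        benchmark_truth.to_json(path)
        back = pg.TrueNetwork.from_json(path)
        assert np.allclose(back.a, benchmark_truth.a)
        assert back.hrf_params_per_subject == benchmark_truth.hrf_params_per_subject

    def test_binary_input_columns_counts(self, task_config):
        sched = pg.gen_transfer_schedule(task_config, seed=0)
        cols = binary_input_columns(sched, task_config.tr_s, task_config.n_trs)
        assert cols["specific"].sum() == 24
        assert cols["general"].sum() == 12


class TestVoxelVolume:
    def _setup(self, noise_sd, seed=0):
        from pitgimme.roi import GridSpec, default_roi_specs

        cfg = pg.TaskConfig(n_trs=20)
        truth = pg.benchmark_network(1)
        sched = pg.gen_transfer_schedule(cfg, seed=0)
        series = pg.simulate_bold(truth, [sched], cfg, seed=0)[0]
        grid = GridSpec.centered(shape=(40, 44, 30), voxel_mm=(3.0, 3.0, 4.0))
        specs = default_roi_specs()
        vol = pg.task.make_voxel_volume(series, specs, grid, noise_sd, seed)
        return series, specs, grid, vol

    def test_noise_free_roundtrip(self):
        from pitgimme.roi import mean_timeseries, sphere_mask

        series, specs, grid, vol = self._setup(noise_sd=0.0)
        for spec in specs:
            mask = sphere_mask(spec, grid)
            rec = mean_timeseries(vol, mask)
            assert np.allclose(rec, series[spec.name], atol=1e-5)

    def test_empty_specs_pure_noise(self):
        from pitgimme.roi import GridSpec

        cfg = pg.TaskConfig(n_trs=30)
        truth = pg.benchmark_network(1)
        sched = pg.gen_transfer_schedule(cfg, seed=0)
        series = pg.simulate_bold(truth, [sched], cfg, seed=0)[0]
        grid = GridSpec.centered(shape=(10, 10, 8))
        vol = pg.task.make_voxel_volume(series, [], grid, 1.0, seed=5)
        data = vol.get_fdata()
        assert abs(data.mean()) < 0.05
        assert abs(data.std() - 1.0) < 0.05

    def test_overlapping_spheres_sum(self):
        from pitgimme.roi import GridSpec, ROISpec, mean_timeseries

        cfg = pg.TaskConfig(n_trs=15)
        truth = pg.benchmark_network(1)
        sched = pg.gen_transfer_schedule(cfg, seed=0)
        series = pg.simulate_bold(truth, [sched], cfg, seed=0)[0]
        grid = GridSpec.centered(shape=(20, 20, 16), voxel_mm=(2.0, 2.0, 2.0))
        specs = [
            ROISpec("putamen_l", "L", (0.0, 0.0, 0.0), 6.0),
            ROISpec("putamen_r", "R", (2.0, 0.0, 0.0), 6.0),
        ]
        vol = pg.task.make_voxel_volume(series, specs, grid, 0.0, seed=0)
        center = mean_timeseries(vol, [(9, 9, 7)])  # voxel near both centers
        expected = series["putamen_l"].to_numpy() + series["putamen_r"].to_numpy()
        assert np.allclose(center, expected, atol=1e-5)
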