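"""Behavioral statistics: binning, learning test, exclusion, rates, ANOVA, probes."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pitgimme as pg
from pitgimme.behavior import (
    BehaviorError,
    DegenerateVarianceError,
    INTERVALS,
    RESPONSES,
    RatingSet,
    STIMULI,
    bin_attacks,
    default_probe_family,
    instrumental_exclusion,
    learning_test,
    pairwise_probes,
    rm_anova_3way,
    transfer_rates,
)


class TestBinAttacks:
    def test_six_bins_for_default_session(self):
        assert len(bin_attacks([])) == 6

    def test_zero_attacks(self):
        assert bin_attacks([]).tolist() == [0, 0, 0, 0, 0, 0]

    def test_hand_counted_example(self):
        assert bin_attacks([5, 35, 35, 179]).tolist() == [1, 2, 0, 0, 0, 1]

    def test_partial_bin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            counts = bin_attacks([10.0, 95.0], session_length_s=100.0, bin_s=30.0)
        assert counts.tolist() == [1, 0, 0]

    def test_sum_conserved(self):
        attacks = np.linspace(0.5, 179.5, 60)
        assert bin_attacks(attacks).sum() == 60


class TestLearningTest:
    def test_identical_vectors(self):
        t, df, p = learning_test([3, 4, 5], [3, 4, 5])
        assert t == 0 and p == 1 and df == 2

    def test_degenerate_variance_signalled(self):
        with pytest.raises(DegenerateVarianceError):
            learning_test([3, 4, 5], [1, 2, 3])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 10, size=8).astype(float)
            b = rng.integers(0, 10, size=8).astype(float)
            d = a - b
            if d.std(ddof=1) == 0:
                continue
            t, df, p = learning_test(a, b)
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert abs(t - t_oracle) < 1e-10
            assert df == 7


class TestExclusion:
    def test_keep_well_learned(self):
        rs = RatingSet("s1", {("R1", "O1"): 9, ("R1", "O2"): 2, ("R2", "O2"): 9, ("R2", "O1"): 1})
        keep, scores = instrumental_exclusion(rs)
        assert keep and scores == {"O1": 8, "O2": 7}

    def test_boundary_zero_excluded(self):
        rs = RatingSet("s1", {("R1", "O1"): 5, ("R1", "O2"): 5, ("R2", "O2"): 5, ("R2", "O1"): 5})
        keep, scores = instrumental_exclusion(rs)
        assert not keep and scores == {"O1": 0, "O2": 0}

    def test_reversed_learning_excluded(self):
        rs = RatingSet("s1", {("R1", "O1"): 1, ("R1", "O2"): 9, ("R2", "O2"): 10, ("R2", "O1"): 10})
        keep, _ = instrumental_exclusion(rs)
        assert not keep

    def test_missing_rating_rejected(self):
        with pytest.raises(BehaviorError):
            RatingSet("s1", {("R1", "O1"): 5})


class TestTransferRates:
    def test_zero_presses_zero_rates(self, task_config):
        sched = pg.gen_transfer_schedule(task_config, seed=0)
        rec = pd.DataFrame({"timestamp": [], "response": []})
        tab = transfer_rates(rec, sched)
        assert (tab.rate == 0).all()
        assert len(tab) == 20

    def test_normalization_by_presentations(self, task_config):
        """24 R1 presses inside CS1 windows -> rate(CS1, stim, R1) = 2.0."""
        sched = pg.gen_transfer_schedule(task_config, seed=0)
        cs1 = sched[sched.trial_type == "CS1"].head(12)
        times = []
        for row in cs1.itertuples(index=False):
            times += [row.onset + 0.5, row.onset + 1.5]
        rec = pd.DataFrame({"timestamp": times, "response": ["R1"] * 24})
        tab = transfer_rates(rec, sched)
        cell = tab[(tab.stimulus == "CS1") & (tab.interval == "stim") & (tab.response == "R1")]
        assert cell.rate.iloc[0] == 2.0
        assert tab.rate.sum() == 2.0

    def test_out_of_run_press_rejected(self, task_config):
        sched = pg.gen_transfer_schedule(task_config, seed=0)
        rec = pd.DataFrame({"timestamp": [1e6], "response": ["R1"]})
        with pytest.raises(BehaviorError):
            transfer_rates(rec, sched)


def _ss_oracle(y):
    """Independent mean-based sums-of-squares decomposition for the 3-way
    within-subject design; returns {effect: (ss_effect, ss_error)}."""
    n, a, b, c = y.shape
    grand = y.mean()
    out = {}
    m_s = y.mean(axis=(1, 2, 3))

    def marg(axes_keep):
        return y.mean(axis=tuple(ax for ax in (1, 2, 3) if ax not in axes_keep))

    # main effects
    for name, ax, k in (("stimulus", 1, a), ("interval", 2, b), ("response", 3, c)):
        m = y.mean(axis=tuple({1, 2, 3} - {ax})).mean(axis=0)
        ss = n * (y.shape[1] * b * c // k) * np.sum((m - grand) ** 2)
        cell = y.mean(axis=tuple({1, 2, 3} - {ax}))  # n x k
        ss_int = (a * b * c // k) * np.sum((cell - m_s[:, None] - m[None, :] + grand) ** 2)
        out[name] = (ss, ss_int)
    # two-way
    for name, axes, kk in (
        ("stimulus x interval", (1, 2), (a, b)),
        ("stimulus x response", (1, 3), (a, c)),
        ("interval x response", (2, 3), (b, c)),
    ):
        m_ab = y.mean(axis=tuple({1, 2, 3} - set(axes))).mean(axis=0)
        ax1, ax2 = axes
        m1 = y.mean(axis=tuple({1, 2, 3} - {ax1})).mean(axis=0)
        m2 = y.mean(axis=tuple({1, 2, 3} - {ax2})).mean(axis=0)
        resid = m_ab - m1[:, None] - m2[None, :] + grand
        mult = a * b * c // (kk[0] * kk[1])
        ss = n * mult * np.sum(resid**2)
        cell = y.mean(axis=tuple({1, 2, 3} - set(axes)))  # n x k1 x k2
        cell_s1 = y.mean(axis=tuple({1, 2, 3} - {ax1}))
        cell_s2 = y.mean(axis=tuple({1, 2, 3} - {ax2}))
        resid_s = (
            cell
            - cell_s1[:, :, None]
            - cell_s2[:, None, :]
            + m_s[:, None, None]
            - resid[None]
            - m1[None, :, None]
            - m2[None, None, :]
            + grand
            + m1[None, :, None]
            + m2[None, None, :]
            - grand
        )
        # subject interaction residual: cell_{s,ab} - effect terms
        resid_s = cell - cell_s1[:, :, None] - cell_s2[:, None, :] + m_s[:, None, None]
        resid_s = resid_s - resid[None]
        ss_err = mult * np.sum(resid_s**2)
        out[name] = (ss, ss_err)
    # three-way
    m_abc = y.mean(axis=0)
    terms = np.zeros_like(m_abc)
    m1 = y.mean(axis=(0, 2, 3))
    m2 = y.mean(axis=(0, 1, 3))
    m3 = y.mean(axis=(0, 1, 2))
    m12 = y.mean(axis=(0, 3))
    m13 = y.mean(axis=(0, 2))
    m23 = y.mean(axis=(0, 1))
    resid3 = (
        m_abc
        - m12[:, :, None]
        - m13[:, None, :]
        - m23[None, :, :]
        + m1[:, None, None]
        + m2[None, :, None]
        + m3[None, None, :]
        - grand
    )
    ss3 = n * np.sum(resid3**2)
    # error: full-cell residual after removing all subject-free and subject terms
    full = y
    s12 = y.mean(axis=3)
    s13 = y.mean(axis=2)
    s23 = y.mean(axis=1)
    s1 = y.mean(axis=(2, 3))
    s2 = y.mean(axis=(1, 3))
    s3 = y.mean(axis=(1, 2))
    resid_full = (
        full
        - s12[:, :, :, None]
        - s13[:, :, None, :]
        - s23[:, None, :, :]
        + s1[:, :, None, None]
        + s2[:, None, :, None]
        + s3[:, None, None, :]
        - m_s[:, None, None, None]
        - resid3[None]
    )
    ss3_err = np.sum(resid_full**2)
    out["stimulus x interval x response"] = (ss3, ss3_err)
    return out


class TestRmAnova:
    def _table(self, y):
        rows = []
        for s_i in range(y.shape[0]):
            for (i1, s), (i2, i), (i3, r) in product(
                enumerate(STIMULI), enumerate(INTERVALS), enumerate(RESPONSES)
            ):
                rows.append(
                    {
                        "subject": f"s{s_i}",
                        "stimulus": s,
                        "interval": i,
                        "response": r,
                        "rate": y[s_i, i1, i2, i3],
                    }
                )
        return pd.DataFrame(rows)

    def test_df_arithmetic_n11(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(11, 5, 2, 2))
        res = rm_anova_3way(self._table(y))
        stim = res[res.effect == "stimulus"].iloc[0]
        assert stim.df1 == 4 and stim.df2 == 40
        assert stim.eps <= 1.0 and stim.df1_corr <= 4.0

    def test_all_equal_cells_f_zero(self):
        y = np.full((4, 5, 2, 2), 2.5)
        res = rm_anova_3way(self._table(y))
        assert (res.F == 0).all()
        assert (res.ges == 0).all()

    def test_matches_ss_oracle(self):
        """F and generalized eta squared agree with an independent mean-based
        sums-of-squares decomposition on random 4-subject tables."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.integers(0, 8, size=(4, 5, 2, 2)).astype(float)
            res = rm_anova_3way(self._table(y)).set_index("effect")
            oracle = _ss_oracle(y)
            ss_sub = 20 * np.sum((y.mean(axis=(1, 2, 3)) - y.mean()) ** 2)
            total_err = sum(v[1] for v in oracle.values())
            for eff, (ss, ss_err) in oracle.items():
                row = res.loc[eff]
                df1, df2 = row.df1, row.df2
                f_oracle = 0.0 if ss_err == 0 else (ss / df1) / (ss_err / df2)
                assert abs(row.F - f_oracle) < 1e-8, eff
                ges_oracle = 0.0 if ss == 0 else ss / (ss + ss_sub + total_err)
                assert abs(row.ges - ges_oracle) < 1e-8, eff

    def test_matches_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 5, 2, 2))
        tab = self._table(y)
        res = rm_anova_3way(tab).set_index("effect")
        sm = AnovaRM(tab, "rate", "subject", within=["stimulus", "interval", "response"]).fit()
        mapping = {
            "stimulus": "stimulus",
            "interval": "interval",
            "response": "response",
            "stimulus x interval": "stimulus:interval",
            "stimulus x response": "stimulus:response",
            "interval x response": "interval:response",
            "stimulus x interval x response": "stimulus:interval:response",
        }
        for ours, theirs in mapping.items():
            assert abs(res.loc[ours].F - sm.anova_table.loc[theirs, "F Value"]) < 1e-8

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ges_bounded(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(5, 5, 2, 2))
        res = rm_anova_3way(self._table(y))
        assert ((res.ges >= 0) & (res.ges <= 1)).all()

    def test_incomplete_design_rejected(self):
        rng = np.random.default_rng(1)
        tab = self._table(rng.normal(size=(4, 5, 2, 2)))
        with pytest.raises(BehaviorError, match="missing"):
            rm_anova_3way(tab.iloc[:-1])


class TestPairwiseProbes:
    def test_single_comparison_unadjusted(self, null_rates_table):
        fam = default_probe_family()[:1]
        res = pairwise_probes(null_rates_table, fam)
        assert abs(res.p_raw.iloc[0] - res.p_bonferroni.iloc[0]) < 1e-12

    def test_bonferroni_arithmetic(self, null_rates_table):
        res = pairwise_probes(null_rates_table)
        m = len(default_probe_family())
        assert m == 20
        expect = np.minimum(1.0, res.p_raw * m)
        assert np.allclose(res.p_bonferroni, expect)

    def test_duplicate_family_rejected(self, null_rates_table):
        fam = default_probe_family()[:1] * 2
        with pytest.raises(BehaviorError):
            pairwise_probes(null_rates_table, fam)

    def test_specific_pit_pattern_detected(self):
        """Specific gains drive CS1/R1 and CS2/R2 pre-vs-stim probes; CS3 stays flat."""
        frames = []
        agent = pg.AgentParams(baseline_rate=0.1, specific_gain=5.0, general_gain=1.0)
        cfg = pg.TaskConfig()
        for i in range(11):
            sched = pg.gen_transfer_schedule(cfg, seed=30 + i)
            rec = pg.gen_transfer_behavior(sched, agent, seed=30 + i)
            frames.append(pg.behavior.transfer_rates(rec, sched, subject_id=f"s{i}"))
        tab = pd.concat(frames, ignore_index=True)
        res = pairwise_probes(tab).set_index("comparison")
        assert res.loc["CS1:R1:pre-vs-stim"].significant
        assert res.loc["CS2:R2:pre-vs-stim"].significant
        assert not res.loc["CS3:R1:pre-vs-stim"].significant
        assert not res.loc["CS3:R2:pre-vs-stim"].significant

    def test_power_monotone_in_specific_gain(self):
        """Rejection frequency of the CS1/R1 probe is non-decreasing in the gain."""
        cfg = pg.TaskConfig()
        rates = []
        for gain in (1.0, 2.5, 5.0):
            rej = 0
            for rep in range(12):
                frames = []
                agent = pg.AgentParams(baseline_rate=0.1, specific_gain=gain)
                for i in range(8):
                    sched = pg.gen_transfer_schedule(cfg, seed=rep * 50 + i)
                    rec = pg.gen_transfer_behavior(sched, agent, seed=rep * 50 + i)
                    frames.append(pg.behavior.transfer_rates(rec, sched, subject_id=f"s{i}"))
                tab = pd.concat(frames, ignore_index=True)
                row = pairwise_probes(tab).set_index("comparison").loc["CS1:R1:pre-vs-stim"]
                rej += row.p_raw < 0.05
            rates.append(rej / 12)
        assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9
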