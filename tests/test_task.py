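"""Schedules, agent simulation, and cohort generation."""

import numpy as np
import pandas as pd
import pytest

from revlearn.task import (
    default_cohort_spec,
    generate_cohort,
    make_ebdm_schedule,
    make_high_option_paths,
    make_reversal_block,
    make_session_schedule,
    simulate_agent,
    simulate_blocks,
)


class TestReversalBlock:
    def test_phase_structure(self):
        s = make_reversal_block(28, 7, 0.8, seed=1)
        assert s.n_phases == 4
        # reversals exactly after trials 7, 14, 21 (1-based)
        changes = np.flatnonzero(s.high_option[1:] != s.high_option[:-1]) + 1
        assert changes.tolist() == [7, 14, 21]

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            make_reversal_block(30, 7, 0.8, seed=0)

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1])
    def test_degenerate_probability_rejected(self, bad_p):
        with pytest.raises(ValueError):
            make_reversal_block(28, 7, bad_p, seed=0)

    def test_seed_determinism(self):
        a = make_reversal_block(28, 7, 0.8, seed=42)
        b = make_reversal_block(28, 7, 0.8, seed=42)
        assert np.array_equal(a.high_option, b.high_option)
        assert np.array_equal(a.reward_available, b.reward_available)

    def test_reward_availability_rate(self):
        # empirical availability of the better option converges to p_high
        rng = np.random.default_rng(0)
        hits = total = 0
        for _ in range(400):
            s = make_reversal_block(28, 7, 0.8, rng)
            hits += s.reward_available[np.arange(28), s.high_option].sum()
            total += 28
        rate = hits / total
        # binomial 99.9% band around 0.8 at n = 11200
        assert abs(rate - 0.8) < 3.29 * np.sqrt(0.8 * 0.2 / total)


class TestSessionAndEbdm:
    def test_session_counts_and_independence(self):
        ss = make_session_schedule(seed=9)
        assert ss.n_trials == 56
        assert set(ss.order) == {"social", "nonsocial"}
        for b in ss.blocks.values():
            b.validate()

    def test_session_determinism(self):
        a, b = make_session_schedule(seed=5), make_session_schedule(seed=5)
        assert a.order == b.order
        for k in a.blocks:
            assert np.array_equal(
                a.blocks[k].reward_available, b.blocks[k].reward_available
            )

    def test_block_order_varies_with_seed(self):
        orders = {make_session_schedule(seed=s).order for s in range(20)}
        assert len(orders) == 2

    def test_ebdm_balance(self):
        e = make_ebdm_schedule(6, seed=2)
        assert e.n_trials == 48
        counts = e.trials.value_counts()
        assert len(counts) == 8 and set(counts) == {6}

    def test_ebdm_single_repeat_all_distinct(self):
        e = make_ebdm_schedule(1, seed=3)
        assert e.n_trials == 8
        assert not e.trials.duplicated().any()

    def test_ebdm_minimum_rejected(self):
        with pytest.raises(ValueError):
            make_ebdm_schedule(0, seed=1)


class TestSimulateAgent:
    def test_flat_beta_choice_rate(self):
        sched = make_reversal_block(28, 7, 0.8, seed=1)
        rng = np.random.default_rng(0)
        choices = []
        for _ in range(200):
            sim = simulate_agent(
                "fictitious",
                dict(eta_rew=0.5, eta_nrew=0.5, beta=0.0),
                sched,
                rng,
            )
            choices.append(sim["choice"].to_numpy())
        rate = np.mean(np.concatenate(choices) == 0)
        assert rate == pytest.approx(0.5, abs=0.02)

    def test_sharp_learner_beats_chance(self):
        # high learning rate + high inverse temperature tracks the 80:20
        # reversals well above chance
        rng = np.random.default_rng(1)
        acc = []
        for _ in range(200):
            sched = make_reversal_block(28, 7, 0.8, rng)
            sim = simulate_agent(
                "fictitious", dict(eta_rew=0.8, eta_nrew=0.8, beta=5.0), sched, rng
            )
            acc.append((sim["choice"] == sim["high_option"]).mean())
        assert np.mean(acc) > 0.6

    def test_determinism_and_replay(self):
        sched = make_reversal_block(28, 7, 0.8, seed=7)
        p = dict(eta_rew=0.6, eta_nrew=0.3, beta=2.0)
        a = simulate_agent("fictitious", p, sched, seed=11)
        b = simulate_agent("fictitious", p, sched, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_consistent_with_schedule(self):
        sched = make_reversal_block(28, 7, 0.8, seed=3)
        sim = simulate_agent(
            "rw_pn", dict(eta_rew=0.4, eta_nrew=0.2, beta=1.0), sched, seed=4
        )
        avail = sched.reward_available[np.arange(28), sim["choice"]]
        assert np.array_equal(sim["outcome"].to_numpy(), np.where(avail, 1, -1))

    def test_unknown_model_rejected(self):
        sched = make_reversal_block(28, 7, 0.8, seed=3)
        with pytest.raises(ValueError):
            simulate_agent("nope", {}, sched, seed=0)


class TestCohort:
    def test_record_count_and_schema(self):
        cohort = generate_cohort(default_cohort_spec(n_subjects=40, seed=1))
        assert len(cohort.data) == 40 * 6 * 28  # 6720
        cells = cohort.data.groupby(["subject_id", "session", "feedback"]).size()
        assert cells.nunique() == 1 and cells.iloc[0] == 28

    def test_zero_group_sd_shares_parameters(self):
        spec = default_cohort_spec(n_subjects=5, seed=2)
        zero_sd = {k: np.zeros(6) for k in spec.group_sd}
        from revlearn.task import CohortSpec

        spec0 = CohortSpec(
            n_subjects=5, model="fictitious",
            group_mean=spec.group_mean, group_sd=zero_sd, seed=2,
        )
        cohort = generate_cohort(spec0)
        per_subj = cohort.subject_params.pivot_table(
            index="subject_id", columns=["session", "feedback", "param"],
            values="value",
        )
        assert np.allclose(per_subj.to_numpy() - per_subj.to_numpy()[0], 0)

    def test_replay_reproduces_choices(self):
        # the stored schedules and per-trial uniforms replay the simulated
        # choices exactly
        cohort = generate_cohort(default_cohort_spec(n_subjects=3, seed=9))
        key = ("s002", "iso_media", "social")
        blk = cohort.blocks[key]
        tp = cohort.subject_params
        params = {
            row["param"]: row["value"]
            for _, row in tp[
                (tp["subject_id"] == key[0])
                & (tp["session"] == key[1])
                & (tp["feedback"] == key[2])
            ].iterrows()
        }
        replay = simulate_agent("fictitious", params, blk["schedule"], u=blk["u"])
        obs = cohort.data[
            (cohort.data["subject_id"] == key[0])
            & (cohort.data["session"] == key[1])
            & (cohort.data["feedback"] == key[2])
        ].sort_values("trial")
        assert np.array_equal(replay["choice"].to_numpy(), obs["choice"].to_numpy())
        assert np.array_equal(replay["outcome"].to_numpy(), obs["outcome"].to_numpy())

    def test_determinism(self):
        a = generate_cohort(default_cohort_spec(n_subjects=4, seed=5))
        b = generate_cohort(default_cohort_spec(n_subjects=4, seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_yoked_schedules_repeat_across_sessions(self):
        cohort = generate_cohort(
            default_cohort_spec(n_subjects=2, seed=6, yoke_schedules=True)
        )
        h1 = cohort.blocks[("s001", "baseline", "social")]["schedule"].high_option
        h2 = cohort.blocks[("s002", "iso_total", "social")]["schedule"].high_option
        assert np.array_equal(h1, h2)

    def test_higher_learning_rate_cell_learns_better(self):
        # Monte-Carlo comparison through the vectorized simulator: a cell
        # generated with a much higher learning rate shows higher accuracy
        rng = np.random.default_rng(12)
        G = 4000
        high = make_high_option_paths(G, 28, 7, rng)
        slow = simulate_blocks(
            "fictitious",
            {"eta_rew": np.full(G, 0.1), "eta_nrew": np.full(G, 0.1),
             "beta": np.full(G, 3.0)},
            high, 0.8, rng,
        )[0]
        fast = simulate_blocks(
            "fictitious",
            {"eta_rew": np.full(G, 0.8), "eta_nrew": np.full(G, 0.8),
             "beta": np.full(G, 3.0)},
            high, 0.8, rng,
        )[0]
        assert (fast == high).mean() > (slow == high).mean() + 0.05
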