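import numpy as np
import pandas as pd
import pytest

from patchforage.behavior_analysis import (
    RAW,
    SIM_FILTERS,
    FilterConfig,
    condition_contrasts,
    leaving_surface,
    logistic_leaving_models,
    poke_predictors,
    reset_analysis,
    segment_trials,
    slope_cf_vs_rewards,
    stim_reward_interaction,
    subtractive_normalization,
)


def make_log(site_letters, rewards, durations=None, subject="s00", session=1,
             gap=0.05):
    """Hand-build a minimal event log from site letters and outcomes."""
    n = len(site_letters)
    durations = durations if durations is not None else [0.3] * n
    t, rows = 0.0, []
    trial = 1
    for i in range(n):
        if i and site_letters[i] != site_letters[i - 1]:
            trial += 1
        rows.append({
            "subject_id": subject, "group": "A", "day": 1, "session": session,
            "protocol": "medium", "p_rwd": 0.9, "p_sw": 0.3, "barrier": 0,
            "stim": 0, "trial": trial, "poke": i + 1, "site": site_letters[i],
            "reward": rewards[i], "poke_in": t, "poke_out": t + durations[i],
            "reward_volume": 2.0 * rewards[i], "active_site": "NA",
        })
        t += durations[i] + gap
    return pd.DataFrame(rows)


class TestSegmentation:
    def test_maximal_same_site_runs(self):
        log = make_log(list("LLRRR"), [1, 0, 1, 0, 0])
        bouts = segment_trials(log, RAW)
        assert len(bouts) == 2
        assert bouts["n_pokes"].tolist() == [2, 3]

    def test_reward_number_and_trailing_failures(self):
        log = make_log(list("LLLLL"), [1, 1, 0, 0, 0])
        bouts = segment_trials(log, RAW)
        assert bouts.loc[0, "reward_number"] == 2
        assert bouts.loc[0, "consecutive_failures"] == 3

    def test_short_poke_dropped_before_segmentation_merges_bouts(self):
        # a 50 ms poke at R between two L-runs disappears under the
        # 100 ms validity rule, so the L-runs merge into one bout
        log = make_log(list("LLRLLL"), [1, 0, 0, 1, 0, 0],
                       durations=[0.3, 0.3, 0.05, 0.3, 0.3, 0.3])
        bouts = segment_trials(log, FilterConfig(skip_first=0, keep_next=100,
                                                 exclude_zero_reward=False))
        assert len(bouts) == 1
        assert bouts.loc[0, "outcomes"] == (1, 0, 1, 0, 0)
        # without the duration rule the same log has three bouts
        assert len(segment_trials(log, RAW)) == 3

    def test_twenty_poke_log_matches_hand_computation(self):
        sites = list("LLLRRLLLLRRRLLRRRRRL")
        rewards = [1, 1, 0, 1, 0, 0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0]
        bouts = segment_trials(make_log(sites, rewards), RAW)
        assert bouts["n_pokes"].tolist() == [3, 2, 4, 3, 2, 5, 1]
        assert bouts["reward_number"].tolist() == [2, 1, 1, 2, 1, 1, 0]
        assert bouts["consecutive_failures"].tolist() == [1, 1, 2, 1, 1, 3, 1]

    def test_filter_order_is_duration_skip_keep_zero_reward(self):
        # 6 bouts; skip 1, keep 3 -> bouts 2..4 retained; the zero-reward
        # bout inside the window is then excluded and NOT back-filled
        sites = list("LL RR LL RR LL RR".replace(" ", ""))
        rewards = [1, 1,  0, 0,  1, 0,  1, 1,  0, 0,  1, 1]
        log = make_log(sites, rewards)
        filters = FilterConfig(skip_first=1, keep_next=3,
                               exclude_zero_reward=True)
        bouts = segment_trials(log, filters)
        assert bouts["trial_index"].tolist() == [3, 4]
        assert bouts["reward_number"].tolist() == [1, 2]

    def test_empty_after_filters_raises(self):
        log = make_log(list("LL"), [1, 0])
        with pytest.raises(ValueError, match="no bouts"):
            segment_trials(log, FilterConfig(skip_first=10, keep_next=50))


class TestSlopes:
    def test_constant_failures_give_zero_slope(self):
        bouts = pd.DataFrame({
            "subject_id": "a", "reward_number": [1, 2, 3, 4] * 5,
            "consecutive_failures": 2})
        res = slope_cf_vs_rewards(bouts)
        assert res.mean == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_subject_flagged_and_excluded(self):
        bouts = pd.DataFrame({
            "subject_id": ["a"] * 4 + ["b"] * 4,
            "reward_number": [2, 2, 2, 2, 1, 2, 3, 4],
            "consecutive_failures": [1, 2, 3, 4, 2, 2, 2, 2]})
        res = slope_cf_vs_rewards(bouts)
        per = res.per_subject.set_index("subject_id")
        assert bool(per.loc["a", "degenerate"])
        assert res.n_subjects == 1

    def test_ib_cohort_flat_sb_cohort_positive(self, ib_bouts, sb_bouts):
        assert abs(slope_cf_vs_rewards(ib_bouts).mean) < 0.05
        assert slope_cf_vs_rewards(sb_bouts).mean > 0.1

    def test_pooled_slope_invariant_to_relabeling_and_order(self, sb_bouts):
        base = slope_cf_vs_rewards(sb_bouts)
        shuffled = sb_bouts.sample(frac=1.0, random_state=0)
        relabeled = shuffled.assign(
            subject_id=shuffled["subject_id"].map(
                lambda s: {"s00": "zz", "s01": "aa", "s02": "mm"}[s]))
        perm = slope_cf_vs_rewards(relabeled)
        assert perm.mean == pytest.approx(base.mean, abs=1e-12)
        assert perm.sem == pytest.approx(base.sem, abs=1e-12)


class TestResetAnalysis:
    def test_identity_construction_gives_unit_slope(self):
        outcomes = [tuple([0] * k + [1] + [0] * k) for k in range(5) for _ in range(3)]
        bouts = pd.DataFrame({
            "subject_id": "a",
            "outcomes": outcomes,
            "reward_number": 1,
            "consecutive_failures": [len(o) - list(o).index(1) - 1
                                     for o in outcomes]})
        res = reset_analysis(bouts)
        assert res.mean == pytest.approx(1.0, abs=1e-12)

    def test_requires_single_reward_bouts(self):
        bouts = pd.DataFrame({"subject_id": ["a"], "outcomes": [(1, 1)],
                              "reward_number": [2],
                              "consecutive_failures": [0]})
        with pytest.raises(ValueError):
            reset_analysis(bouts)

    def test_ib_cohort_slope_near_zero(self, ib_bouts):
        # the medium schedule has little variance in pre-reward failures,
        # so the per-subject estimates are noisy; the pooled mean is small
        assert abs(reset_analysis(ib_bouts).mean) < 0.15


class TestLeavingSurface:
    def test_deterministic_threshold_policy(self):
        # leave exactly when 3 trailing failures accumulate
        outcomes = [(1, 0, 0, 0), (1, 1, 0, 0, 0), (1, 0, 1, 0, 0, 0)] * 10
        bouts = pd.DataFrame({"subject_id": "a", "outcomes": outcomes})
        p, counts = leaving_surface(bouts, max_rewards=3, max_failures=4,
                                    min_count=1)
        stacked = p.stack().dropna()
        for (_, f), val in stacked.items():
            assert val == (1.0 if f == 3 else 0.0)

    def test_counts_conserve_opportunities(self, ib_bouts):
        _, counts = leaving_surface(ib_bouts, min_count=1)
        assert counts.to_numpy().sum() == ib_bouts["n_pokes"].sum()

    def test_ib_rows_similar_columns_increasing(self, ib_bouts):
        p, _ = leaving_surface(ib_bouts, max_rewards=3, max_failures=3,
                               min_count=30)
        # hazard rises with trailing failures
        col0 = p.loc[1:, 0].dropna()
        col2 = p.loc[1:, 2].dropna()
        assert col2.mean() > col0.mean()
        # and is nearly unchanged across reward counts (reward reset)
        after_reward = p.loc[1:3, 0].dropna()
        assert after_reward.max() - after_reward.min() < 0.1

    def test_invalid_bounds_rejected(self, ib_bouts):
        with pytest.raises(ValueError):
            leaving_surface(ib_bouts, max_rewards=0)


class TestContrastsAndInteraction:
    def test_null_stim_effect_gives_zero_difference_unit_ratio(self):
        rng = np.random.default_rng(0)
        frames = []
        for subj in ("a", "b"):
            base = rng.poisson(3, size=100).astype(float)
            for stim in (0, 1):  # identical outcomes in both arms
                frames.append(pd.DataFrame({
                    "subject_id": subj, "protocol": "medium", "stim": stim,
                    "consecutive_failures": base}))
        bouts = pd.concat(frames, ignore_index=True)
        cells = condition_contrasts(bouts, factors=("protocol", "stim"))
        stim_cells = cells[cells["stim"] == 1]
        assert np.allclose(stim_cells["difference"], 0.0)
        assert np.allclose(stim_cells["ratio"], 1.0)

    def test_interaction_recovered_and_permutation_null(self):
        rng = np.random.default_rng(1)
        n = 600
        frames = []
        for subj in ("a", "b", "c"):
            stim = rng.integers(0, 2, n)
            rn = rng.integers(1, 5, n)
            cf = 2.0 + 0.5 * stim + 0.1 * rn + 0.8 * stim * rn \
                + rng.normal(0, 0.5, n)
            frames.append(pd.DataFrame({
                "subject_id": subj, "stim": stim, "reward_number": rn,
                "consecutive_failures": cf}))
        bouts = pd.concat(frames, ignore_index=True)
        res = stim_reward_interaction(bouts)
        assert res.mean == pytest.approx(0.8, abs=0.1)
        permuted = bouts.assign(
            stim=rng.permutation(bouts["stim"].to_numpy()))
        null = stim_reward_interaction(permuted)
        assert abs(null.mean) < 3 * null.sem + 0.05

    def test_degenerate_designs_flagged(self):
        bouts = pd.DataFrame({"subject_id": "a", "stim": 1,
                              "reward_number": [1, 2, 3],
                              "consecutive_failures": [1, 2, 3]})
        with pytest.raises(ValueError):
            stim_reward_interaction(bouts)


class TestLogisticLeaving:
    def test_failure_model_wins_on_evidence_driven_cohort(self, ib_log):
        models = logistic_leaving_models(ib_log, SIM_FILTERS)
        assert models["failure"].deviance < models["time"].deviance
        combined = models["combined"].params
        assert combined["consecutive_failure_index"] > 0

    def test_time_model_wins_on_clock_driven_cohort(self):
        # constructed agent: leaves when cumulative time at port exceeds
        # a threshold; poke durations jittered, rewards random
        rng = np.random.default_rng(2)
        rows = []
        t = 0.0
        site = "L"
        for bout in range(400):
            threshold = 2.0
            elapsed = 0.0
            poke = 0
            while True:
                poke += 1
                dur = float(rng.uniform(0.2, 0.8))
                rows.append({
                    "subject_id": "s00", "group": "A", "day": 1, "session": 1,
                    "protocol": "medium", "p_rwd": 0.9, "p_sw": 0.3,
                    "barrier": 0, "stim": 0, "trial": bout + 1, "poke": poke,
                    "site": site, "reward": int(rng.random() < 0.5),
                    "poke_in": t, "poke_out": t + dur,
                    "reward_volume": 0.0, "active_site": "NA"})
                t += dur + 0.05
                elapsed += dur + 0.05
                if elapsed > threshold:
                    break
            site = "R" if site == "L" else "L"
            t += 1.5
        log = pd.DataFrame(rows)
        models = logistic_leaving_models(log, RAW)
        assert models["time"].deviance < models["failure"].deviance

    def test_predictors_definition(self):
        log = make_log(list("LLLRR"), [1, 0, 0, 1, 0])
        pokes = poke_predictors(log, RAW)
        assert pokes["consecutive_failure_index"].tolist() == [0, 1, 2, 0, 1]
        assert pokes["leave"].tolist() == [0, 0, 1, 0, 1]
        assert pokes["time_at_port"].iloc[0] == 0.0
        assert pokes["time_at_port"].iloc[2] > pokes["time_at_port"].iloc[1]


class TestSubtractiveNormalization:
    def test_constant_vector_maps_to_zeros(self):
        df = pd.DataFrame({"subject_id": "a", "consecutive_failures": [3.0] * 5})
        assert np.allclose(subtractive_normalization(df), 0.0)

    def test_group_means_are_zero(self, sb_bouts):
        centered = subtractive_normalization(sb_bouts)
        means = centered.groupby(sb_bouts["subject_id"]).mean()
        assert np.allclose(means, 0.0, atol=1e-10)

    def test_centering_preserves_per_subject_slopes(self, sb_bouts):
        base = slope_cf_vs_rewards(sb_bouts)
        centered = sb_bouts.assign(
            consecutive_failures=subtractive_normalization(sb_bouts))
        after = slope_cf_vs_rewards(centered)
        assert after.mean == pytest.approx(base.mean, abs=1e-10)
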