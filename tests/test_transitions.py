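import numpy as np
import pytest

from sleepkit.core import Hypnogram, LaserTrain
from sleepkit.synthetic import SimConfig, default_laser_train, simulate_hypnogram
from sleepkit.transitions import (
    aligned_trial_states,
    bootstrap_transition_test,
    cumulative_transition,
    downsample_states,
    state_percentage_timecourse,
    transition_graph,
    transition_indicators,
)


def brute_force_curve(states, x, y):
    """Literal per-trial enumeration of P(X->Y | t <= d) on the 10 s grid."""
    m, n = states.shape
    d_grid = range(n + 1)
    p = sum(1 for k in range(m) if states[k, 0] == x)
    if p == 0:
        return None
    curve = []
    for di in d_grid:
        q = 0
        for k in range(m):
            if states[k, 0] != x:
                continue
            if x == y:
                stayed = all(states[k, j] == x for j in range(min(di, n - 1) + 1))
                q += stayed
            else:
                q += any(states[k, j] == y for j in range(1, min(di, n - 1) + 1))
        curve.append(q / p)
    return np.array(curve)


class TestDownsampling:
    def test_majority_vote(self):
        s = np.array(list("NNNWRRRR"), dtype="U1")
        assert downsample_states(s).tolist() == ["N", "R"]

    def test_tie_prefers_rem_then_nrem(self):
        assert downsample_states(np.array(list("RRWW"), dtype="U1")).tolist() == ["R"]
        assert downsample_states(np.array(list("NNWW"), dtype="U1")).tolist() == ["N"]

    def test_commutes_with_trial_alignment(self):
        """For onsets on the 10 s grid, downsampling the whole hypnogram and
        slicing equals slicing then downsampling."""
        from sleepkit.core import LaserTrain

        cfg = SimConfig(seed=4, duration_s=20_000.0)
        h, _ = simulate_hypnogram(cfg)
        laser = LaserTrain(onsets=np.arange(200.0, 19_000.0, 900.0), duration_s=120.0)
        trials = aligned_trial_states(h, laser)
        full = downsample_states(h.states)
        assert len(trials["laser"]) > 5
        for onset, row in zip(laser.onsets, trials["laser"]):
            k = int(onset // 10)
            assert (full[k : k + 12] == row).all()


class TestCumulativeTransition:
    def test_all_nrem_trials(self):
        states = np.array([list("N" * 12)] * 5, dtype="U1")
        trials = {"laser": states, "baseline": states}
        nn = cumulative_transition(trials, "N", "N")
        nr = cumulative_transition(trials, "N", "R")
        assert (nn.laser == 1.0).all()
        assert (nr.laser == 0.0).all()

    def test_hand_built_trials_match_hand_count(self):
        rows = [
            list("N" * 2) + list("R" * 10),  # enters R during epoch 2 -> d=20
            list("N" * 5) + list("R" * 7),  # enters R during epoch 5 -> d=50
            list("N" * 12),
            list("N" * 12),
        ]
        states = np.array(rows, dtype="U1")
        trials = {"laser": states, "baseline": states}
        cs = cumulative_transition(trials, "N", "R")
        expect = {0: 0.0, 10: 0.0, 20: 0.25, 30: 0.25, 40: 0.25, 50: 0.5, 120: 0.5}
        for d, v in expect.items():
            assert cs.laser[int(d // 10)] == pytest.approx(v)

    def test_undefined_pair_flagged_not_zero(self):
        states = np.array([list("N" * 12)] * 3, dtype="U1")
        cs = cumulative_transition({"laser": states, "baseline": states}, "R", "W")
        assert not cs.defined

    def test_forbidden_direct_wake_rem_edge(self):
        """Direct W→R scoring transitions never occur; the cumulative
        first-entry curve may still be positive via W→N→R sequences."""
        cfg = SimConfig(seed=5, duration_s=40_000.0)
        laser = default_laser_train(cfg, seed=5)
        h, _ = simulate_hypnogram(cfg, laser)
        down = downsample_states(h.states)
        assert not ((down[:-1] == "W") & (down[1:] == "R")).any()
        trials = aligned_trial_states(h, laser)
        cs = cumulative_transition(trials, "W", "R")
        # entries into R from W-at-onset trials pass through N first
        assert cs.defined

    def test_matches_enumeration_oracle_on_random_fixtures(self, rng):
        for _ in range(200):
            states = rng.choice(list("WNR"), size=(20, 12)).astype("U1")
            trials = {"laser": states, "baseline": states}
            for x in "WNR":
                for y in "WNR":
                    cs = cumulative_transition(trials, x, y)
                    oracle = brute_force_curve(states, x, y)
                    if oracle is None:
                        assert not cs.defined
                    else:
                        np.testing.assert_array_equal(cs.laser, oracle)

    def test_monotone_curves(self, rng):
        states = rng.choice(list("WNR"), size=(50, 12)).astype("U1")
        trials = {"laser": states, "baseline": states}
        for x in "WNR":
            for y in "WNR":
                cs = cumulative_transition(trials, x, y)
                if not cs.defined:
                    continue
                diffs = np.diff(cs.laser)
                if x == y:
                    assert (diffs <= 1e-12).all()
                else:
                    assert (diffs >= -1e-12).all()


class TestBootstrap:
    def _null_trials(self, rng, m=40):
        states = rng.choice(list("WNR"), size=(m, 12), p=[0.3, 0.5, 0.2]).astype("U1")
        return {"laser": states, "baseline": states.copy()}

    def test_identical_arms_give_zero_statistic_and_p_one(self, rng):
        trials = self._null_trials(rng)
        res = bootstrap_transition_test(trials, "N", "R", B=500, seed=1)
        assert res.statistic == 0.0
        assert (res.distribution == 0.0).all()
        assert res.p_value == 1.0

    def test_seed_reproducible(self, rng):
        states = rng.choice(list("WNR"), size=(40, 12)).astype("U1")
        states2 = rng.choice(list("WNR"), size=(40, 12)).astype("U1")
        trials = {"laser": states, "baseline": states2}
        a = bootstrap_transition_test(trials, "N", "R", B=500, seed=7)
        b = bootstrap_transition_test(trials, "N", "R", B=500, seed=7)
        np.testing.assert_array_equal(a.distribution, b.distribution)
        assert a.p_value == b.p_value

    def test_ci_bounds_are_distribution_percentiles(self, rng):
        states = rng.choice(list("WNR"), size=(40, 12)).astype("U1")
        states2 = rng.choice(list("WNR"), size=(40, 12)).astype("U1")
        res = bootstrap_transition_test(
            {"laser": states, "baseline": states2}, "N", "W", B=1000, seed=3
        )
        assert res.ci[0] == pytest.approx(np.percentile(res.distribution, 2.5))
        assert res.ci[1] == pytest.approx(np.percentile(res.distribution, 97.5))

    def test_needs_two_trials(self):
        states = np.array([list("N" * 12)], dtype="U1")
        with pytest.raises(ValueError, match="2 trials"):
            bootstrap_transition_test({"laser": states, "baseline": states}, "N", "R")


class TestGraphAndPercentages:
    def test_no_effect_ratios_near_one(self, rng):
        states = rng.choice(list("WNR"), size=(400, 12)).astype("U1")
        trials = {"laser": states, "baseline": states.copy()}
        sets = [cumulative_transition(trials, x, y) for x in "WNR" for y in "WNR" if x != y]
        graph, notes = transition_graph(sets)
        assert (np.abs(graph["ratio"] - 1.0) < 1e-9).all()

    def test_unobserved_pair_omitted(self):
        states = np.array([list("N" * 6 + "W" * 6)] * 8, dtype="U1")
        trials = {"laser": states, "baseline": states.copy()}
        sets = [cumulative_transition(trials, "N", y) for y in "RW"]
        graph, notes = transition_graph(sets)
        assert "N->R" not in set(graph.get("pair", []))
        assert any("N->R" in n for n in notes)

    def test_percentages_sum_to_100(self, rng):
        states = rng.choice(list("WNR"), size=(30, 96)).astype("U1")
        tc, _ = state_percentage_timecourse(states)
        np.testing.assert_allclose(tc[["W", "N", "R"]].sum(axis=1), 100.0)

    def test_single_trial_is_indicator(self):
        states = np.array([list("W" * 4 + "N" * 4)], dtype="U1")
        tc, _ = state_percentage_timecourse(states)
        assert set(np.unique(tc[["W", "N", "R"]].to_numpy())) == {0.0, 100.0}

    def test_per_trial_laser_baseline_means(self):
        states = np.array([list("N" * 48 + "R" * 48)], dtype="U1")
        tc, per_trial = state_percentage_timecourse(states, pre_s=120.0, laser_s=120.0)
        row = per_trial[(per_trial.trial == 0) & (per_trial.state == "R")].iloc[0]
        assert row.baseline_pct == 0.0 and row.laser_pct == 100.0
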