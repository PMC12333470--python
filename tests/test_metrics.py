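import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from syllakin.io import load_reference_table
from syllakin.metrics import (
    TransitionSummary,
    centroid_speed_series,
    delta_table,
    entropy,
    filter_expressed,
    group_syllable_stats,
    run_length_encode,
    session_velocity,
    steady_state,
    summarize_transitions,
    syllable_velocity,
    transition_frequency,
    transition_matrix,
    usage,
)
from syllakin.synthetic import (
    SyllableRepertoire,
    build_repertoire,
    build_transition_model,
    sample_markov_chain,
    simulate_session,
)
from syllakin.preprocess import egocentric_align


class TestCentroidSpeed:
    def test_straight_line(self):
        track = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        np.testing.assert_allclose(centroid_speed_series(track, 30.0), 30.0)

    def test_stationary(self):
        np.testing.assert_allclose(centroid_speed_series(np.ones((5, 2)), 30.0), 0.0)

    def test_rotation_invariant(self):
        rng = np.random.default_rng(0)
        track = rng.standard_normal((50, 2)).cumsum(axis=0)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        np.testing.assert_allclose(
            centroid_speed_series(track @ R.T, 30.0), centroid_speed_series(track, 30.0)
        )

    def test_length_matches_labels(self):
        assert centroid_speed_series(np.zeros((7, 2)), 30.0).size == 7


class TestSyllableVelocity:
    def test_single_constant(self):
        speeds = np.full(100, 100.0)
        assert syllable_velocity(speeds, np.zeros(100, dtype=int)) == {0: 100.0}

    def test_interleaved_generator_speeds(self):
        F = 16
        rep = SyllableRepertoire(np.array([150.0, 50.0]), [np.zeros((F, F))] * 2,
                                 np.zeros(2), np.zeros(2))
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        rec, truth = simulate_session(rep, P, duration=600.0, jitter_sd=0.0, seed=0)
        pose = egocentric_align(rec)
        speeds = centroid_speed_series(pose.centroid_track, 30.0)
        vel = syllable_velocity(speeds, truth.labels)
        assert vel[0] == pytest.approx(150.0, rel=0.01)
        assert vel[1] == pytest.approx(50.0, rel=0.01)

    def test_missing_syllable_absent_not_zero(self):
        vel = syllable_velocity(np.ones(4), np.array([2, 2, 5, 5]))
        assert set(vel) == {2, 5}

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            syllable_velocity(np.ones(3), np.zeros(4, dtype=int))


class TestSessionVelocity:
    def test_constant_motion(self):
        track = np.stack([np.arange(300.0), np.zeros(300)], axis=1)
        assert session_velocity(track, 30.0) == pytest.approx(30.0)

    def test_stationary(self):
        assert session_velocity(np.ones((10, 2)), 30.0) == 0.0

    def test_close_to_mean_speed_series(self):
        rng = np.random.default_rng(1)
        track = rng.standard_normal((2000, 2)).cumsum(axis=0)
        mean_series = centroid_speed_series(track, 30.0).mean()
        assert session_velocity(track, 30.0) == pytest.approx(mean_series, rel=0.01)


class TestUsage:
    def test_hand_count(self):
        u = usage(np.array([0, 0, 1, 1, 1, 2]))
        assert u == {0: pytest.approx(1 / 3), 1: pytest.approx(1 / 2), 2: pytest.approx(1 / 6)}

    def test_filter(self):
        assert filter_expressed({0: 0.6, 1: 0.004, 2: 0.396}, 0.005) == [0, 2]

    def test_constant(self):
        assert usage(np.full(10, 3)) == {3: 1.0}

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 9, size=1000)
        assert sum(usage(labels).values()) == pytest.approx(1.0, abs=1e-9)


class TestTransitionMatrix:
    def test_hand_count(self):
        s = transition_matrix([0, 0, 1, 1, 0, 2], [0, 1, 2])
        np.testing.assert_array_equal(s.counts[0], [0, 1, 1])
        np.testing.assert_array_equal(s.counts[1], [1, 0, 0])
        assert s.A[0, 1] == s.A[0, 2] == 0.5

    def test_constant_sequence_zero_counts(self):
        s = transition_matrix(np.zeros(50, dtype=int), [0, 1])
        assert s.counts.sum() == 0

    def test_long_simulation_close_to_truth(self):
        P = build_transition_model(5, 0.3, 30.0, seed=3)
        labels = sample_markov_chain(P, 200_000, np.random.default_rng(3))
        s = transition_matrix(labels, range(5))
        # conditional next-state distribution given a change
        off = P - np.diag(np.diag(P))
        expected = off / off.sum(axis=1, keepdims=True)
        assert np.abs(s.A - expected).sum(axis=1).max() < 0.05

    def test_rows_stochastic_on_support(self):
        labels = np.array([0, 1, 0, 2, 1, 0, 1])
        s = transition_matrix(labels, [0, 1, 2])
        sums = s.A.sum(axis=1)
        support = s.counts.sum(axis=1) > 0
        np.testing.assert_allclose(sums[support], 1.0, atol=1e-10)


class TestSteadyState:
    def test_uniform(self):
        np.testing.assert_allclose(steady_state(np.full((4, 4), 0.25)), 0.25, atol=1e-10)

    def test_hand_solved_two_state(self):
        A = np.array([[0.9, 0.1], [0.5, 0.5]])
        np.testing.assert_allclose(steady_state(A), [5 / 6, 1 / 6], atol=1e-10)

    def test_three_cycle(self):
        A = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        np.testing.assert_allclose(steady_state(A), 1 / 3, atol=1e-10)

    def test_reducible_uses_heaviest_class(self, caplog):
        A = np.array([
            [1.0, 0, 0, 0],
            [0, 0.5, 0.5, 0],
            [0, 0.5, 0.5, 0],
            [0, 0, 0, 1.0],
        ])
        pi = steady_state(A, empirical_mass=np.array([1.0, 10.0, 10.0, 1.0]))
        np.testing.assert_allclose(pi, [0, 0.5, 0.5, 0], atol=1e-10)


class TestEntropy:
    def test_uniform_rate_log2(self):
        s = TransitionSummary(np.arange(4), np.ones((4, 4)), np.full((4, 4), 0.25))
        assert entropy(s) == pytest.approx(2.0)

    def test_deterministic_cycle_zero(self):
        A = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        s = TransitionSummary(np.arange(3), A.copy(), A)
        assert entropy(s, mode="rate") == 0.0
        assert entropy(s, mode="local_sum") == 0.0

    def test_closed_form_two_state(self):
        A = np.full((2, 2), 0.5)
        s = TransitionSummary(np.arange(2), np.ones((2, 2)), A)
        assert entropy(s, mode="rate") == pytest.approx(1.0)
        assert entropy(s, mode="local_sum") == pytest.approx(2.0)

    def test_nats_base(self):
        s = TransitionSummary(np.arange(4), np.ones((4, 4)), np.full((4, 4), 0.25))
        assert entropy(s, log_base=np.e) == pytest.approx(np.log(4))

    def test_invalid_mode(self):
        s = TransitionSummary(np.arange(2), np.ones((2, 2)), np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            entropy(s, mode="bogus")

    @given(seed=hst.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_rate_bounded_by_local_sum(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(2, 7)
        A = rng.dirichlet(np.ones(K), size=K)
        s = TransitionSummary(np.arange(K), np.ones((K, K)), A)
        rate = entropy(s, mode="rate")
        local = entropy(s, mode="local_sum")
        assert 0.0 <= rate <= local + 1e-12
        assert rate <= np.log2(K) + 1e-12


class TestTransitionFrequency:
    def test_constant_zero(self):
        assert transition_frequency(np.zeros(30, dtype=int), 30.0) == 0.0

    def test_alternating_hand_count(self):
        labels = np.arange(30) % 2
        assert transition_frequency(labels, 30.0) == pytest.approx(29.0)

    def test_mean_run_reciprocal(self):
        # mean run 16.7 frames at 30 fps -> ~1.8 transitions/s
        P = build_transition_model(6, 16.7 / 30.0, 30.0, seed=5)
        labels = sample_markov_chain(P, 100_000, np.random.default_rng(5))
        assert transition_frequency(labels, 30.0) == pytest.approx(30.0 / 16.7, rel=0.05)

    @given(seed=hst.integers(0, 100), n=hst.integers(2, 500))
    @settings(max_examples=25, deadline=None)
    def test_equals_runs_minus_one_over_duration(self, seed, n):
        labels = np.random.default_rng(seed).integers(0, 4, size=n)
        values, _ = run_length_encode(labels)
        fps = 30.0
        assert transition_frequency(labels, fps) == pytest.approx(
            (len(values) - 1) / (n / fps))


class TestDeltaTable:
    @staticmethod
    def _stats(df, prefix):
        import pandas as pd

        return pd.DataFrame({
            "velocity": df[f"{prefix}_velocity"].to_numpy(),
            "usage": df[f"{prefix}_usage"].to_numpy(),
        }, index=df["syllable"])

    def test_identical_groups_zero(self):
        df = load_reference_table("6ohda")
        a = self._stats(df, "control")
        t = delta_table(a, a)
        np.testing.assert_allclose(t["delta_velocity"], 0.0)
        np.testing.assert_allclose(t["delta_usage"], 0.0)

    def test_published_syllable_14(self):
        df = load_reference_table("6ohda")
        t = delta_table(self._stats(df, "control"), self._stats(df, "lesion"))
        assert t.loc[14, "delta_velocity"] == pytest.approx(172.43 - 91.67)

    def test_antisymmetric(self):
        df = load_reference_table("6ohda")
        a, b = self._stats(df, "control"), self._stats(df, "lesion")
        t_ab = delta_table(a, b)
        t_ba = delta_table(b, a)
        np.testing.assert_allclose(t_ab["delta_velocity"], -t_ba["delta_velocity"])

    def test_disjoint_raises(self):
        df = load_reference_table("6ohda")
        a = self._stats(df, "control")
        b = self._stats(df, "lesion")
        b.index = b.index + 1000
        with pytest.raises(ValueError):
            delta_table(a, b)


class TestPipelineClosure:
    def test_generator_to_metrics_closure(self):
        rep = build_repertoire(6, (0, 150), seed=8)
        P = build_transition_model(6, 0.4, 30.0, seed=8)
        rec, truth = simulate_session(rep, P, duration=100_000 / 30.0, fps=30.0,
                                      jitter_sd=0.0, seed=8)
        pose = egocentric_align(rec)
        speeds = centroid_speed_series(pose.centroid_track, 30.0)
        vel = syllable_velocity(speeds, truth.labels)
        for k, true_speed in enumerate(rep.speeds):
            if true_speed > 0:
                assert vel[k] == pytest.approx(true_speed, rel=0.05)
        emp_usage = np.array([usage(truth.labels).get(k, 0.0) for k in range(6)])
        tv = 0.5 * np.abs(emp_usage - steady_state(P)).sum()
        assert tv <= 0.05
        expected_freq = 30.0 * (1 - np.mean([P[k, k] for k in truth.labels]))
        assert transition_frequency(truth.labels, 30.0) == pytest.approx(expected_freq, rel=0.10)


class TestGroupStats:
    def test_missing_syllable_not_deflated(self):
        per_animal = [
            {"velocity": {0: 100.0, 1: 50.0}, "usage": {0: 0.8, 1: 0.2}},
            {"velocity": {0: 110.0}, "usage": {0: 1.0}},
        ]
        table = group_syllable_stats(per_animal)
        assert table.loc[0, "velocity"] == pytest.approx(105.0)
        assert table.loc[1, "velocity"] == pytest.approx(50.0)  # one animal only
        assert table.loc[1, "n_velocity"] == 1
        assert table.loc[1, "usage"] == pytest.approx(0.1)  # usage basis includes zeros

    def test_summarize_transitions_fills_fields(self):
        P = build_transition_model(4, 0.3, 30.0, seed=9)
        labels = sample_markov_chain(P, 20_000, np.random.default_rng(9))
        s = summarize_transitions(labels, range(4), fps=30.0)
        assert s.pi is not None and s.pi.sum() == pytest.approx(1.0)
        assert s.entropy_ >= 0
        assert s.transition_frequency_ > 0
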