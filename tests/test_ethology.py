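"""Ethogram analytics: proportions, transitions, clustering, embedding."""
import numpy as np
import pandas as pd
import pytest

import painmap as pm
from painmap.containers import Ethogram, ValidationError
from painmap.ethology import (
    EmbedClassifier,
    action_proportions,
    cluster_proportions,
    differential_actions,
    proportion_table,
    speed_map,
    summarize_transitions,
    transition_matrix,
)


def _seq_ethogram(labels, label_set=None, bout_s=1.0):
    n = len(labels)
    bouts = pd.DataFrame(
        {
            "label": labels,
            "start_s": np.arange(n) * bout_s,
            "end_s": (np.arange(n) + 1) * bout_s,
        }
    )
    return Ethogram(bouts=bouts, label_set=tuple(label_set or sorted(set(labels))))


class TestProportions:
    def test_single_bout_gets_everything(self):
        e = _seq_ethogram(["rearing"], label_set=["rearing", "sniffing"])
        p = action_proportions(e)
        assert p["rearing"] == 1.0 and p["sniffing"] == 0.0

    def test_time_weighted_hand_arithmetic(self, simple_ethogram):
        p = action_proportions(simple_ethogram, weighting="time")
        np.testing.assert_allclose([p["A"], p["B"]], [0.6, 0.4], atol=1e-12)

    def test_bout_weighted_counts(self, simple_ethogram):
        p = action_proportions(simple_ethogram, weighting="bout")
        np.testing.assert_allclose([p["A"], p["B"]], [0.5, 0.5], atol=1e-12)

    def test_sum_to_one(self):
        e, _ = pm.gen_ethogram(pm.EthogramSpec(total_duration=60, seed=3))
        for w in ("time", "bout"):
            assert abs(action_proportions(e, w).sum() - 1.0) < 1e-9

    def test_empty_ethogram_errors(self):
        e = Ethogram(bouts=pd.DataFrame(columns=["label", "start_s", "end_s"]),
                     label_set=("A",))
        with pytest.raises(ValidationError):
            action_proportions(e)


class TestTransitions:
    def test_self_transitions_only(self):
        tm = transition_matrix(_seq_ethogram(["A", "A", "A"], label_set=["A", "B"]))
        assert tm.probabilities.loc["A", "A"] == 1.0
        assert tm.unobserved_rows["B"]
        assert (tm.probabilities.loc["B"] == 0.0).all()

    def test_alternating_hand_count(self):
        tm = transition_matrix(_seq_ethogram(["A", "B", "A", "B"]))
        assert tm.probabilities.loc["A", "B"] == 1.0
        assert tm.probabilities.loc["B", "A"] == 1.0
        assert tm.counts.loc["A", "B"] == 2 and tm.counts.loc["B", "A"] == 1

    def test_ten_label_alphabet_shape(self):
        e, _ = pm.gen_ethogram(pm.EthogramSpec(total_duration=300, seed=1))
        tm = transition_matrix(e)
        assert tm.probabilities.shape == (10, 10)
        assert set(tm.labels) == set(pm.ACTION_LABELS)

    def test_pseudocount_regularizes(self):
        tm = transition_matrix(_seq_ethogram(["A", "B", "A"]), pseudocount=0.5)
        # row A: counts (0 self, 2 to B)? A->B=1, A->A=0 ... sequence A,B,A: A->B, B->A
        np.testing.assert_allclose(tm.probabilities.loc["A"], [0.25, 0.75])
        rows = tm.probabilities.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_single_bout_errors(self):
        with pytest.raises(ValidationError):
            transition_matrix(_seq_ethogram(["A"], label_set=["A", "B"]))

    def test_generator_round_trip_recovers_matrix(self):
        # law of large numbers: empirical transitions converge to the chain
        rng = np.random.default_rng(5)
        k = 4
        p = rng.dirichlet(np.ones(k) * 2, size=k)
        spec = pm.EthogramSpec(
            action_labels=[f"a{i}" for i in range(k)],
            transition_matrix=p,
            mean_bout_duration=1.0,
            total_duration=2e4,  # ~20k bouts
            seed=6,
        )
        e, truth = pm.gen_ethogram(spec)
        tm = transition_matrix(e)
        est = tm.probabilities.loc[spec.action_labels, spec.action_labels].to_numpy()
        tv_per_row = 0.5 * np.abs(est - p).sum(axis=1)
        assert tv_per_row.max() < 0.05


class TestFlows:
    def test_identity_matrix_full_self_share(self):
        tm = transition_matrix(_seq_ethogram(["A", "A", "B", "B"]))
        flows, self_share = summarize_transitions(tm)
        # A only self-transitions except the single A->B handoff
        assert self_share["B"] == 1.0

    def test_uniform_symmetry_and_row_count(self):
        e, _ = pm.gen_ethogram(pm.EthogramSpec(
            action_labels=list("abcd"), total_duration=5000, mean_bout_duration=1.0, seed=2))
        tm = transition_matrix(e, pseudocount=1.0)
        props = action_proportions(e)
        flows, _ = summarize_transitions(tm, props, floor=0.0)
        assert len(flows) == 16  # K_a^2 with floor 0
        flows_floored, _ = summarize_transitions(tm, props, floor=0.2)
        assert len(flows_floored) == (tm.probabilities.to_numpy() >= 0.2).sum()


class TestClustering:
    def test_planted_partition_recovered(self, rng):
        base_a = np.array([0.7, 0.1, 0.1, 0.1])
        base_b = np.array([0.1, 0.1, 0.1, 0.7])
        rows = [base_a + rng.normal(scale=0.01, size=4) for _ in range(5)]
        rows += [base_b + rng.normal(scale=0.01, size=4) for _ in range(5)]
        table = pd.DataFrame(np.abs(rows), index=[f"m{i}" for i in range(10)])
        table = table.div(table.sum(axis=1), axis=0)
        labels, order = cluster_proportions(table, k=2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_duplicated_rows_same_cluster(self):
        table = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1], [0.9, 0.1]],
                             index=list("wxyz"))
        labels, _ = cluster_proportions(table, k=2, linkage="average")
        assert labels["w"] == labels["x"] and labels["y"] == labels["z"]

    def test_too_many_clusters_errors(self):
        table = pd.DataFrame([[0.5, 0.5], [0.4, 0.6]])
        with pytest.raises(ValidationError):
            cluster_proportions(table, k=3)


class TestEmbedding:
    def test_fixed_seed_reproducible(self, rng):
        x = rng.random((12, 6))
        y = np.array(["CON"] * 6 + ["MA"] * 6)
        e1 = EmbedClassifier(random_state=3).fit(x, y)
        e2 = EmbedClassifier(random_state=3).fit(x, y)
        np.testing.assert_array_equal(e1.embedding_, e2.embedding_)
        assert e1.accuracy_ == e2.accuracy_

    def test_planted_separation_detected(self, rng):
        # strongly distinct repertoires embed into separable clouds
        a = rng.dirichlet([20, 2, 2, 2], size=10)
        b = rng.dirichlet([2, 2, 2, 20], size=10)
        x = np.vstack([a, b])
        y = np.array(["CON"] * 10 + ["MA"] * 10)
        model = EmbedClassifier(random_state=0).fit(x, y)
        assert model.accuracy_ > 0.9

    def test_null_accuracy_below_planted_separation(self):
        # a linear boundary in a 2-D embedding of 20 points always overfits
        # somewhat, so the null training accuracy sits above chance (~0.65)
        # but far below genuinely separated repertoires
        null_accs, planted_accs = [], []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            y = np.array(["CON"] * 10 + ["MA"] * 10)
            x_null = rng.dirichlet(np.ones(10) * 8, size=20)
            null_accs.append(EmbedClassifier(random_state=rep).fit(x_null, y).accuracy_)
            a = rng.dirichlet([20, 2, 2, 2], size=10)
            b = rng.dirichlet([2, 2, 2, 20], size=10)
            planted_accs.append(
                EmbedClassifier(random_state=rep).fit(np.vstack([a, b]), y).accuracy_)
        assert 0.5 <= np.mean(null_accs) <= 0.8
        assert np.mean(planted_accs) > 0.9
        assert np.mean(planted_accs) - np.mean(null_accs) > 0.15

    def test_infeasible_perplexity_errors(self, rng):
        x = rng.random((5, 3))
        y = np.array(["a", "a", "b", "b", "b"])
        with pytest.raises(ValidationError):
            EmbedClassifier(perplexity=10).fit(x, y)


class TestDifferential:
    def test_ten_hypotheses_adjusted(self, rng):
        table = pd.DataFrame(rng.dirichlet(np.ones(10) * 5, size=12),
                             columns=list(pm.ACTION_LABELS))
        groups = pd.Series(["CON"] * 6 + ["MA"] * 6, index=table.index)
        res = differential_actions(table, groups)
        assert len(res) == 10
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()

    def test_planted_shift_detected(self, rng):
        alpha_con = np.full(6, 10.0)
        alpha_ma = alpha_con.copy()
        alpha_ma[0] *= 4
        table = pd.DataFrame(
            np.vstack([rng.dirichlet(alpha_con, size=20), rng.dirichlet(alpha_ma, size=20)]),
            columns=[f"act{i}" for i in range(6)],
        )
        groups = pd.Series(["CON"] * 20 + ["MA"] * 20, index=table.index)
        res = differential_actions(table, groups)
        assert res.loc["act0", "significant"]
        assert res.loc["act0", "direction"] == "MA>CON"

    def test_degenerate_group_sizes_error(self, rng):
        table = pd.DataFrame(rng.random((3, 4)))
        groups = pd.Series(["CON", "CON", "MA"], index=table.index)
        with pytest.raises(ValidationError):
            differential_actions(table, groups)


class TestSpeedMap:
    def test_stationary_path_zero_speed(self):
        traj = pm.Trajectory(t_s=np.arange(10) * 0.1, x_cm=np.full(10, 25.0),
                             y_cm=np.full(10, 25.0), sample_rate=10.0)
        grid, summary = speed_map(traj)
        assert summary["total_distance_cm"] == 0.0
        occupied = grid[~np.isnan(grid)]
        np.testing.assert_array_equal(occupied, 0.0)

    def test_constant_velocity_closed_form(self):
        # straight path at 10 cm/s sampled at 10 Hz
        t = np.arange(40) * 0.1
        traj = pm.Trajectory(t_s=t, x_cm=5 + 10 * t, y_cm=np.full(40, 25.0),
                             sample_rate=10.0)
        grid, summary = speed_map(traj, grid_cm=5.0)
        occupied = grid[~np.isnan(grid)]
        np.testing.assert_allclose(occupied, 10.0, atol=1e-9)
        np.testing.assert_allclose(summary["total_distance_cm"], 39.0, atol=1e-9)

    def test_total_distance_invariant_to_grid(self, rng):
        traj, _ = pm.gen_trajectory(pm.TrajectorySpec(duration=20, seed=9))
        _, s1 = speed_map(traj, grid_cm=2.0)
        _, s2 = speed_map(traj, grid_cm=10.0)
        assert s1["total_distance_cm"] == s2["total_distance_cm"]


class TestPermutationInvariance:
    def test_relabeling_permutes_outputs(self):
        e = _seq_ethogram(["A", "B", "C", "A", "C"], label_set=["A", "B", "C"])
        mapping = {"A": "Z", "B": "Y", "C": "X"}
        bouts2 = e.bouts.assign(label=e.bouts["label"].map(mapping))
        e2 = Ethogram(bouts=bouts2, label_set=("X", "Y", "Z"))
        p1 = action_proportions(e)
        p2 = action_proportions(e2)
        for old, new in mapping.items():
            assert p1[old] == p2[new]
        t1 = transition_matrix(e).probabilities
        t2 = transition_matrix(e2).probabilities
        for a in "ABC":
            for b in "ABC":
                assert t1.loc[a, b] == t2.loc[mapping[a], mapping[b]]
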