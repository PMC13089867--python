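"""Task-graph structure, trial schedules, and ISI sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affordmap import graph as G
from affordmap.rdm import linkdist_rdm


class TestGraphStructure:
    def test_module_tiling_and_gap(self, small_graph):
        # offset 21, 2 modules: 21-24 and 26-29 carry states, 25 is the gap
        assert list(small_graph.numbers) == [21, 22, 23, 24, 26, 27, 28, 29]
        assert G.state_of(21, small_graph) == 1
        assert G.state_of(26, small_graph) == 1
        assert G.state_of(25, small_graph) is None
        assert G.state_of(9999, small_graph) is None

    def test_offset_must_exceed_20(self):
        with pytest.raises(G.InvalidOffsetError):
            G.build_graph(20, 1)

    def test_closure_exhaustive(self):
        g = G.build_graph(21, 1)
        # every afforded action from every state lands on a state-bearing
        # residue (checked over all 8 state-action pairs)
        for state, actions in g.affordances.items():
            for a in actions:
                target = ((state - 1) + a) % g.period
                assert target < 4

    @given(k=st.integers(min_value=0, max_value=30), j=st.integers(0, 4))
    @settings(deadline=None, max_examples=50)
    def test_periodicity(self, graph, k, j):
        n = graph.offset + j
        m = n + 5 * k
        if graph.state_of(m) is not None and graph.state_of(n) is not None:
            assert graph.state_of(n) == graph.state_of(m)

    def test_offset_shift_invariance(self):
        a = G.build_graph(25, 4)
        b = G.build_graph(26, 4)
        assert np.array_equal(G.link_distance_matrix(a), G.link_distance_matrix(b))
        assert a.affordances == b.affordances

    def test_successors_worked_examples(self):
        g49 = G.build_graph(48, 2)  # 49 is state 2
        assert g49.state_of(49) == 2
        assert G.successors(49, g49) == (50, 51)
        g = G.build_graph(21, 2)  # 23 is state 3 affording -2/-1
        assert G.successors(23, g) == (21, 22)
        g24 = G.build_graph(24, 12)  # 29 state 1 -> (27, 31); 79 -> (77, 81)
        assert G.successors(29, g24) == (27, 31)
        assert G.successors(79, g24) == (77, 81)

    def test_successors_rejects_gap_number(self, small_graph):
        with pytest.raises(G.NotAStateError):
            G.successors(25, small_graph)

    def test_link_distances_via_bfs_oracle(self, small_graph):
        # brute-force BFS over explicit state-number expansion
        g = small_graph
        numbers = set(int(n) for n in g.numbers)
        dist = np.full((4, 4), np.inf)
        for start in numbers:
            s0 = g.state_of(start)
            seen, frontier, d = {start}, [start], 0
            while frontier:
                for n in frontier:
                    s = g.state_of(n)
                    dist[s0 - 1, s - 1] = min(dist[s0 - 1, s - 1], d)
                frontier = [
                    m
                    for n in frontier
                    for m in g.successors(n)
                    if m in numbers and not (m in seen or seen.add(m))
                ]
                d += 1
        # directed reachability agrees with the undirected matrix here
        assert np.array_equal(G.link_distance_matrix(g), dist)
        assert list(linkdist_rdm(g).vector) == [2, 1, 1, 1, 1, 2]


class TestRunSequence:
    @pytest.mark.parametrize("n_trials,n_probe", [(80, 16), (20, 4), (12, 4)])
    def test_counterbalancing_contract(self, graph, n_trials, n_probe):
        seq = G.generate_run_sequence(
            graph, "fmri", n_trials=n_trials, n_probe=n_probe, seed=7
        )
        assert len(seq.trials) == n_trials
        assert seq.probe_trials.shape[0] == n_probe
        tc = seq.transition_counts()
        assert tc.max() - tc.min() <= 1
        counts = seq.stimulus_trials["state"].value_counts()
        assert counts.nunique() == 1  # conditions evenly represented

    def test_probe_structure(self, graph):
        seq = G.generate_run_sequence(graph, "eyetracker", seed=3)
        probes = seq.probe_trials
        assert probes["probe_correct"].sum() == 8  # half of 16 are true pairs
        assert (probes["response_window"] == 1.2).all()
        for _, p in probes.iterrows():
            pair = tuple(sorted(int(x) for x in p["probe_pair"].split(",")))
            true_pair = graph.successors(int(p["number"]))
            assert (pair == true_pair) == bool(p["probe_correct"])

    def test_seed_determinism(self, graph):
        a = G.generate_run_sequence(graph, "fmri", seed=11)
        b = G.generate_run_sequence(graph, "fmri", seed=11)
        assert a.trials.equals(b.trials)

    def test_infeasible_counts_rejected(self, graph):
        with pytest.raises(G.InfeasibleDesignError):
            G.generate_run_sequence(graph, "fmri", n_trials=21, n_probe=4)

    def test_events_tsv_roundtrip(self, graph, tmp_path):
        seq = G.generate_run_sequence(graph, "fmri", seed=5)
        path = tmp_path / "events.tsv"
        G.write_events_tsv(seq, path)
        back = G.read_events_tsv(path)
        for col in ["trial_type", "state", "number", "is_probe"]:
            assert list(back.trials[col]) == list(seq.trials[col])
        np.testing.assert_allclose(back.trials["onset"], seq.trials["onset"])


class TestIsiSampling:
    def test_truncated_exponential_mean(self):
        isis, _ = G.sample_isi_sequence(10_000, 3.0, seed=0)
        assert isis.min() >= 0.5 and isis.max() <= 8.0
        assert abs(isis.mean() - 3.0) < 0.05  # Monte-Carlo tolerance

    def test_constraint_satisfied_for_all_models(self, graph):
        from affordmap.rdm import affordance_rdm, linkdist_rdm, magnitude_rdm
        from scipy.stats import spearmanr

        models = [m(graph).values for m in (affordance_rdm, linkdist_rdm, magnitude_rdm)]
        seq = G._eulerian_condition_sequence(64, np.random.default_rng(0))
        isis, tried = G.sample_isi_sequence(
            64, 3.0, model_rdms=models, condition_sequence=seq, seed=1
        )
        assert tried >= 1
        for m in models:
            d = np.asarray(m)[seq[:-1] - 1, seq[1:] - 1]
            rho = spearmanr(isis[:63], d).statistic
            assert abs(rho) < 0.1

    def test_constant_model_trivially_satisfied(self):
        const = np.ones((4, 4)) - np.eye(4)
        seq = np.array([1, 2, 3, 4] * 4)
        isis, tried = G.sample_isi_sequence(
            16, 2.5, model_rdms=[const], condition_sequence=seq, seed=2
        )
        assert tried == 1


class TestTrainingSchedule:
    def test_block_counts(self):
        sched = G.make_training_schedule(40, extended_after=[20, 40])
        assert sched.total_test_trials == 720
        assert sched.total_generalization_trials == 48
        assert sched.exploration_per_block == 16

    def test_no_extended_tests(self):
        sched = G.make_training_schedule(10)
        assert sched.total_generalization_trials == 0
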