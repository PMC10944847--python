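"""Per-round actions, steady-state detection, and the simulation driver."""

import logging

import numpy as np
import pytest

from conftest import make_custom_state, make_state, sources_with_row0
from echochamber import (
    discrepancy,
    initialize_state,
    is_steady,
    make_model_spec,
    naive_learning_action,
    run_simulation,
    selective_exposure_action,
    step_round,
    summarize,
)


def _galton_state(opinions, sources, **kw):
    return make_custom_state(opinions, sources, model="galton", **kw)


class TestDiscrepancy:
    def test_sum_of_absolute_deviations(self):
        state = _galton_state(
            [0.0, 1.0, -1.0, 2.0], [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]
        )
        assert discrepancy(state, 0) == 4.0

    def test_zero_when_sources_agree(self):
        state = _galton_state([0.5] * 4, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        assert discrepancy(state, 0) == 0.0

    def test_binary_counts_disagreements(self):
        ops = [1, 1, 1, 0, 0, 0, 1]  # agent 0 True; sources {T,T,F,F,F}
        srcs = sources_with_row0(7, 5, [1, 2, 3, 4, 5])
        state = make_custom_state(ops, srcs, model="condorcet")
        assert discrepancy(state, 0) == 3.0

    def test_invalid_index_raises(self):
        state = make_state(n=10, k=2)
        with pytest.raises(IndexError):
            discrepancy(state, 10)


class TestNaiveLearning:
    def test_adopts_the_source_median(self):
        ops = [0.7, 0.1, 0.5, 0.9, 0.2, 0.3]
        srcs = sources_with_row0(6, 5, [1, 2, 3, 4, 5])
        state = _galton_state(ops, srcs)
        assert naive_learning_action(state, 0) is True
        assert state.opinions[0] == 0.3

    def test_binary_median_is_the_source_majority(self):
        ops = [0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 1.0]
        srcs = sources_with_row0(7, 5, [1, 2, 3, 4, 5])
        state = make_custom_state(ops, srcs, model="condorcet")
        assert naive_learning_action(state, 0) is True
        assert state.opinions[0] == 1.0  # 3-of-5 majority

    def test_fixed_point_is_a_noop(self):
        ops = [0.3, 0.1, 0.5, 0.9, 0.2, 0.3]
        srcs = sources_with_row0(6, 5, [1, 2, 3, 4, 5])
        state = _galton_state(ops, srcs)
        assert naive_learning_action(state, 0) is False

    def test_minimizes_discrepancy_over_all_opinions(self, rng):
        """The adopted opinion attains the minimal summed absolute deviation."""
        for _ in range(50):
            state = make_state(n=20, k=5, seed=int(rng.integers(1 << 30)))
            i = int(rng.integers(20))
            naive_learning_action(state, i)
            best = discrepancy(state, i)
            x = state.opinions
            sources = state.graph.sources[i]
            for cand in np.concatenate([x, rng.normal(0, 2, 10)]):
                assert np.abs(x[sources] - cand).sum() >= best - 1e-12


class TestSelectiveExposure:
    def test_swaps_worst_source_for_the_unique_closer_candidate(self):
        # agent 0 at 0; sources at .1, .2, 5.0; non-sources at .05 and 7.0
        ops = [0.0, 0.1, 0.2, 5.0, 0.05, 7.0]
        srcs = [
            [1, 2, 3],
            [0, 2, 3],
            [0, 1, 3],
            [0, 1, 2],
            [0, 1, 2],
            [0, 1, 2],
        ]
        state = _galton_state(ops, srcs)
        # brute-force candidate set: non-sources strictly closer than the worst
        worst = max((abs(ops[0] - ops[j]), j) for j in srcs[0])[1]
        cands = [
            l
            for l in range(6)
            if l != 0 and l not in srcs[0] and abs(ops[l]) < abs(ops[worst])
        ]
        assert worst == 3 and cands == [4]

        assert selective_exposure_action(state, 0) is True
        assert set(state.graph.sources[0]) == {1, 2, 4}
        assert state.opinions.tolist() == ops  # opinions untouched

    def test_noop_when_sources_agree_exactly(self):
        ops = [0.4, 0.4, 0.4, 0.4, 9.0]
        srcs = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2], [0, 1, 2]]
        state = _galton_state(ops, srcs)
        assert selective_exposure_action(state, 0) is False

    def test_noop_when_no_closer_candidate_exists(self):
        ops = [0.0, 0.1, 0.2, 0.3, 5.0, 9.0]
        srcs = [
            [1, 2, 3],
            [0, 2, 3],
            [0, 1, 3],
            [0, 1, 2],
            [0, 1, 2],
            [0, 1, 2],
        ]
        state = _galton_state(ops, srcs)
        assert selective_exposure_action(state, 0) is False
        assert set(state.graph.sources[0]) == {1, 2, 3}  # in-degree intact

    def test_strictly_reduces_discrepancy_when_not_a_noop(self, rng):
        for _ in range(60):
            state = make_state(
                model="bimodal", n=20, k=4, beta=1.0, seed=int(rng.integers(1 << 30))
            )
            i = int(rng.integers(20))
            before = discrepancy(state, i)
            if selective_exposure_action(state, i):
                assert discrepancy(state, i) < before


class TestStepRound:
    @pytest.mark.parametrize("beta", [0.0, 0.3, 1.0])
    def test_graph_invariants_conserved_every_round(self, beta):
        state = make_state(model="condorcet", n=21, k=3, beta=beta, seed=3)
        for _ in range(5):
            step_round(state)
            state.graph.validate()  # in-degree k, no self/duplicate sources

    def test_beta_one_never_touches_opinions(self):
        state = make_state(model="exponential", n=21, k=3, beta=1.0, seed=4)
        x0 = state.opinions.copy()
        for _ in range(30):
            step_round(state)
            assert np.array_equal(state.opinions, x0)

    def test_beta_zero_never_touches_edges(self):
        state = make_state(model="galton", n=30, k=4, beta=0.0, seed=5)
        s0 = state.graph.sources.copy()
        for _ in range(30):
            step_round(state)
            assert np.array_equal(state.graph.sources, s0)

    def test_beta_zero_diversity_is_non_increasing(self):
        state = make_state(model="galton", n=40, k=5, beta=0.0, seed=6)
        prev = float(np.std(state.opinions))
        for _ in range(20):
            step_round(state)
            cur = float(np.std(state.opinions))
            assert cur <= prev + 1e-12
            prev = cur


class TestSteadyState:
    @pytest.mark.parametrize("model", ["condorcet", "galton"])
    @pytest.mark.parametrize("beta", [0.0, 0.5, 1.0])
    def test_converged_states_are_fixed_points(self, model, beta):
        n = 21 if model == "condorcet" else 20
        spec = make_model_spec(model, {"n": n})
        result = run_simulation(spec, k=3, beta=beta, seed=11)
        assert result.converged
        state = result.final_state
        assert is_steady(state)
        # a further round can change nothing, whatever actions are drawn
        assert step_round(state) is False

    def test_not_steady_when_a_closer_candidate_exists(self):
        ops = [0.0, 0.1, 0.2, 5.0, 0.05, 7.0]
        srcs = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2], [0, 1, 2], [0, 1, 2]]
        state = _galton_state(ops, srcs, beta=1.0)
        assert not is_steady(state)

    def test_steady_at_beta_zero_when_opinions_are_medians(self):
        ops = [0.5, 0.5, 0.5, 0.5]
        srcs = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]
        state = _galton_state(ops, srcs, beta=0.0)
        assert is_steady(state)


class TestRunSimulation:
    def test_identical_seeds_give_bit_identical_results(self):
        spec = make_model_spec("bimodal", {"n": 30})
        a = run_simulation(spec, k=4, beta=0.4, seed=99)
        b = run_simulation(spec, k=4, beta=0.4, seed=99)
        assert np.array_equal(a.final_state.opinions, b.final_state.opinions)
        assert np.array_equal(a.final_state.graph.sources, b.final_state.graph.sources)
        assert a.rounds_to_steady == b.rounds_to_steady
        assert a.converged == b.converged

    def test_beta_one_preserves_the_opinion_multiset_each_round(self):
        spec = make_model_spec("condorcet", {"n": 21})
        state = initialize_state(spec, 3, 1.0, "random", 12)
        x0 = np.sort(state.opinions.copy())
        for _ in range(20):
            step_round(state)
            assert np.array_equal(np.sort(state.opinions), x0)

    def test_beta_one_collective_decision_equals_initial_aggregation(self):
        spec = make_model_spec("condorcet", {"n": 21})
        for seed in range(10):
            result = run_simulation(
                spec, k=3, beta=1.0, seed=seed, record_trajectory=True
            )
            initial = result.trajectory[0]
            final = summarize(result.final_state)
            assert final.collective_decision == initial.collective_decision

    def test_round_cap_is_reported_not_raised(self, caplog):
        spec = make_model_spec("galton")
        with caplog.at_level(logging.WARNING):
            result = run_simulation(spec, k=5, beta=0.0, seed=1, max_rounds=1)
        assert not result.converged
        assert result.rounds_to_steady == 1
        assert any("round cap" in r.message for r in caplog.records)

    def test_trajectory_has_one_record_per_round_boundary(self):
        spec = make_model_spec("condorcet", {"n": 21})
        result = run_simulation(spec, k=3, beta=0.0, seed=2, record_trajectory=True)
        assert result.trajectory[0].round == 0
        assert len(result.trajectory) >= result.rounds_to_steady + 1

    def test_invalid_arguments_raise(self):
        spec = make_model_spec("galton", {"n": 20})
        with pytest.raises(ValueError):
            run_simulation(spec, k=5, beta=1.5, seed=0)
        with pytest.raises(ValueError):
            run_simulation(spec, k=5, beta=0.5, seed=0, max_rounds=0)
        with pytest.raises(ValueError):
            run_simulation(spec, k=25, beta=0.5, seed=0)
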