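"""Structure moves, evidence scoring and greedy model-comparison search."""

import math

import numpy as np
import pytest

from mlsbayes import (
    EnvironmentProcess,
    FitnessTable,
    HierarchyStructure,
    InvalidMoveError,
    ModelState,
    MultilevelDistribution,
    StructureMove,
    apply_move,
    check_ci,
    compare_models,
    default_move_generator,
    evidence,
    greedy_search,
    initial_state,
    project_ci,
    replicator_step,
    two_state_synergy_environment,
)
from conftest import random_distribution
from oracles import product_evidence_log


def make_state(dist, tables):
    return ModelState(dist.structure, dist, tables)


class TestEvidence:
    def test_worked_example(self, ex1_dist, ex1_table):
        assert evidence(ex1_dist, ex1_table) == pytest.approx(1.6, abs=1e-15)

    def test_uniform_likelihood_gives_its_constant(self, ex1_dist):
        w = FitnessTable(ex1_dist.structure, "e", np.full((2, 2), 0.8))
        assert evidence(ex1_dist, w) == pytest.approx(0.8, abs=1e-15)

    def test_equals_replicator_average_fitness_exactly(self, ex1_dist, ex1_table):
        _, avg = replicator_step(ex1_dist, ex1_table)
        assert evidence(ex1_dist, ex1_table) == avg


class TestApplyMove:
    def test_null_top_level_move_is_evidence_neutral(self, ex1_dist, ex1_table):
        """All mass kept in 'free', neutral fitness: the score cannot move."""
        state = make_state(ex1_dist, {"e": ex1_table})
        move = StructureMove(kind="add_top_level", level="C2", label="nascent",
                             grouping={}, epsilon=0.5)
        new = apply_move(state, move)
        assert new.structure.n_levels == 3
        # untouched mass is preserved bit for bit in the free slice
        np.testing.assert_array_equal(new.distribution.values[..., 1],
                                      ex1_dist.values)
        np.testing.assert_array_equal(new.distribution.values[..., 0], 0.0)
        assert evidence(new.distribution, new.tables["e"]) == \
            evidence(ex1_dist, ex1_table)

    def test_grouping_move_conserves_mass_exactly(self, ex1_dist, ex1_table):
        state = make_state(ex1_dist, {"e": ex1_table})
        move = StructureMove(kind="add_top_level", level="C2", label="grp",
                             grouping={"A": 1.0, "B": 0.5}, epsilon=0.25)
        new = apply_move(state, move)
        np.testing.assert_array_equal(
            new.distribution.values.sum(axis=-1), ex1_dist.values)

    def test_add_value_then_merge_round_trips(self, ex1_dist, ex1_table):
        state = make_state(ex1_dist, {"e": ex1_table})
        split = StructureMove(kind="add_value", level="I", label="I1b",
                              donors=("I1",), epsilon=0.5)
        merged = apply_move(apply_move(state, split),
                            StructureMove(kind="merge_value", level="I",
                                          label="I1b", into="I1"))
        assert merged.structure == state.structure
        np.testing.assert_array_equal(merged.distribution.values,
                                      ex1_dist.values)
        np.testing.assert_array_equal(merged.tables["e"].values, ex1_table.values)

    def test_add_value_copies_donor_fitness(self, ex1_dist, ex1_table):
        state = make_state(ex1_dist, {"e": ex1_table})
        new = apply_move(state, StructureMove(
            kind="add_value", level="I", label="I3", donors=("I2",), epsilon=0.5))
        np.testing.assert_array_equal(new.tables["e"].values[2], ex1_table.values[1])
        assert evidence(new.distribution, new.tables["e"]) == \
            pytest.approx(evidence(ex1_dist, ex1_table), abs=1e-15)

    def test_delete_link_then_project_satisfies_ci(self, ci_counterexample):
        tables = {"e": FitnessTable(ci_counterexample.structure, "e",
                                    np.ones(ci_counterexample.structure.shape))}
        state = make_state(ci_counterexample, tables)
        new = apply_move(state, StructureMove(kind="delete_link", link=("I", "C2")))
        assert ("I", "C2") in new.structure.deleted_links
        projected = project_ci(new.distribution, new.structure)
        assert check_ci(projected, "I", "C2", tol=1e-12).satisfied
        back = apply_move(new, StructureMove(kind="restore_link", link=("I", "C2")))
        assert back.structure == state.structure

    def test_delete_environment_link_freezes_tables(self, ex1_dist, ex1_table):
        state = make_state(ex1_dist, {"e": ex1_table})
        new = apply_move(state, StructureMove(kind="delete_link", link=("e", "I")))
        assert new.tables["e"].is_constant_along("I")

    @pytest.mark.parametrize("move", [
        StructureMove(kind="add_top_level", level="C1", label="x"),      # name clash
        StructureMove(kind="add_value", level="I", label="I1",
                      donors=("I2",)),                                   # label clash
        StructureMove(kind="add_value", level="Z", label="n", donors=("I1",)),
        StructureMove(kind="add_top_level", level="C2", label="x",
                      grouping={"A": 1.0}, epsilon=1.5),                 # eps range
        StructureMove(kind="restore_link", link=("I", "C1")),            # not deleted
    ])
    def test_invalid_moves_raise(self, ex1_dist, ex1_table, move):
        from mlsbayes import UnknownLevelError
        state = make_state(ex1_dist, {"e": ex1_table})
        with pytest.raises((InvalidMoveError, UnknownLevelError)):
            apply_move(state, move)


class TestCompareModels:
    @pytest.fixture
    def single_env(self, ex1_structure, ex1_table):
        flat = FitnessTable(ex1_structure, "e", np.ones((2, 2)))
        return EnvironmentProcess(env_states=("e",), kind="iid",
                                  tables={"e": ex1_table}), flat

    def test_identical_states_score_identically(self, ex1_dist, ex1_table):
        env = EnvironmentProcess(env_states=("e",), kind="iid",
                                 tables={"e": ex1_table})
        state = make_state(ex1_dist, {"e": ex1_table})
        a, b = compare_models([state, state], env, T=7, seed=1)[:2]
        assert a.mean_log_evidence == b.mean_log_evidence
        assert a.per_step_log_evidence == b.per_step_log_evidence

    def test_higher_evidence_model_ranks_first(self, ex1_dist, ex1_table,
                                               ex1_structure):
        """Per-step evidence 1.6 vs 1.0 on one observation: gap 0.6, rank 0."""
        flat = FitnessTable(ex1_structure, "e", np.ones((2, 2)))
        env = EnvironmentProcess(env_states=("e",), kind="iid",
                                 tables={"e": ex1_table})
        state_a = make_state(ex1_dist, {"e": flat})
        state_b = make_state(ex1_dist, {"e": ex1_table})
        scores = compare_models([state_a, state_b], env, T=1, seed=0)
        assert scores[0].per_step_evidence[0] == pytest.approx(1.0, abs=1e-15)
        assert scores[1].per_step_evidence[0] == pytest.approx(1.6, abs=1e-15)
        gap = scores[1].per_step_evidence[0] - scores[0].per_step_evidence[0]
        assert gap == pytest.approx(0.6, abs=1e-15)
        assert scores[1].rank == 0 and scores[0].rank == 1

    def test_frozen_irrelevant_level_ties_and_parent_wins(self, ex1_dist, ex1_table):
        """Uniform mass along a frozen extra axis contributes a factor one."""
        env = EnvironmentProcess(env_states=("e",), kind="iid",
                                 tables={"e": ex1_table})
        parent = make_state(ex1_dist, {"e": ex1_table})
        child = apply_move(parent, StructureMove(
            kind="add_top_level", level="C2", label="void",
            grouping={"A": 1.0, "B": 1.0}, epsilon=0.5))
        scores = compare_models([child, parent], env, T=5, seed=2)
        assert scores[0].mean_log_evidence == scores[1].mean_log_evidence
        assert scores[1].rank == 0  # fewer levels wins the tie

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ranking_matches_brute_force_product(self, seed, ex1_structure):
        """Windowed scores agree with full-enumeration prod_t wbar_t."""
        rng = np.random.default_rng(seed)
        env_states = ("u", "v")
        T = 12
        states, oracle_logs = [], []
        env_tables_per_state = []
        for _ in range(3):
            dist = random_distribution(rng, ex1_structure)
            tabs = {e: FitnessTable(ex1_structure, e,
                                    rng.random((2, 2)) + 0.1)
                    for e in env_states}
            states.append(make_state(dist, tabs))
            env_tables_per_state.append(tabs)
        env = EnvironmentProcess(env_states=env_states, kind="iid",
                                 probabilities=(0.5, 0.5),
                                 tables=env_tables_per_state[0])
        seq = env.sample_sequence(T, seed=seed + 100)
        scores = compare_models(states, env, T=T, seed=seed + 100)
        for st, sc in zip(states, scores):
            oracle = product_evidence_log(
                st.distribution.values,
                {e: st.tables[e].values for e in env_states}, seq)
            assert sc.mean_log_evidence * T == pytest.approx(oracle, abs=1e-9)
            oracle_logs.append(oracle)
        impl_order = sorted(range(3), key=lambda i: -scores[i].mean_log_evidence)
        oracle_order = sorted(range(3), key=lambda i: -oracle_logs[i])
        assert impl_order == oracle_order

    def test_extinct_model_scores_minus_infinity(self, ex1_structure, ex1_dist):
        dead = FitnessTable(ex1_structure, "e", np.zeros((2, 2)))
        env = EnvironmentProcess(env_states=("e",), kind="iid",
                                 tables={"e": dead})
        score = compare_models([make_state(ex1_dist, {"e": dead})], env,
                               T=3, seed=0)[0]
        assert score.mean_log_evidence == float("-inf")


class TestGreedySearch:
    def test_null_synergy_accepts_no_moves(self):
        env = two_state_synergy_environment(s=1.0)
        start = initial_state(env, HierarchyStructure.from_levels(
            [("I", ("I1", "I2", "I3"))]))
        final, events = greedy_search(start, env, seed=5, window=24, max_rounds=5)
        assert final.structure == start.structure
        assert not any(ev.accepted for ev in events)

    def test_strong_synergy_recovers_grouping(self):
        env = two_state_synergy_environment(s=4.0)
        start = initial_state(env, HierarchyStructure.from_levels(
            [("I", ("I1", "I2", "I3"))]))
        final, events = greedy_search(start, env, seed=5, window=24, max_rounds=5)
        accepted = [ev for ev in events if ev.accepted]
        assert len(accepted) >= 1
        assert accepted[0].move.kind == "add_top_level"
        assert accepted[0].move.grouping == {"I1": 1.0, "I2": 1.0}
        assert final.structure.n_levels == 2

    def test_search_from_truth_accepts_nothing(self):
        env = two_state_synergy_environment(s=4.0)
        start = initial_state(env, HierarchyStructure.from_levels(
            [("I", ("I1", "I2", "I3"))]))
        truth, _ = greedy_search(start, env, seed=5, window=24, max_rounds=5)
        final, events = greedy_search(truth, env, seed=17, window=24, max_rounds=5)
        assert final.structure == truth.structure
        assert not any(ev.accepted for ev in events)

    def test_same_seed_same_accepted_sequence(self):
        env = two_state_synergy_environment(s=4.0)
        start = initial_state(env, HierarchyStructure.from_levels(
            [("I", ("I1", "I2", "I3"))]))
        runs = [greedy_search(start, env, seed=9, window=24, max_rounds=5)
                for _ in range(2)]
        moves_a = [ev.move for ev in runs[0][1] if ev.accepted]
        moves_b = [ev.move for ev in runs[1][1] if ev.accepted]
        assert moves_a == moves_b
        assert runs[0][0].structure == runs[1][0].structure

    def test_default_generator_proposes_pairs_and_splits(self):
        env = two_state_synergy_environment(s=2.0)
        start = initial_state(env, HierarchyStructure.from_levels(
            [("I", ("I1", "I2", "I3"))]))
        moves = default_move_generator(start)
        kinds = [m.kind for m in moves]
        assert kinds.count("add_top_level") == 3  # 3 unordered pairs
        assert kinds.count("add_value") == 3


def test_evidence_identity_holds_for_every_scored_step(ex1_dist, ex1_table):
    """Per-step score evidence equals the replicator's average fitness."""
    env = EnvironmentProcess(env_states=("e",), kind="iid",
                             tables={"e": ex1_table})
    state = make_state(ex1_dist, {"e": ex1_table})
    score = compare_models([state], env, T=5, seed=0)[0]
    dist = ex1_dist
    for step_log in score.per_step_log_evidence:
        ev = evidence(dist, ex1_table)
        assert step_log == math.log(ev)
        dist, _ = replicator_step(dist, ex1_table)
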