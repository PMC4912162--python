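"""Assembly and solution of post- and pre-survey decision problems."""

import warnings

import numpy as np
import pytest

from harvestmdp.errors import MultichainWarning
from harvestmdp.mdp import DiscreteMDP, solve_average_reward
from harvestmdp.objective import feasible_actions_post
from harvestmdp.belief import model_averaged, simplex_grid
from harvestmdp.policy import (
    PolicyFamily,
    PolicyTable,
    assemble_post,
    assemble_pre,
    solve_policy,
)


class TestAssemblePost:
    def test_vertex_belief_equals_single_model(self, tiny_case):
        w = np.array([0.0, 1.0, 0.0, 0.0])
        mdp = assemble_post(w, tiny_case.tables, tiny_case.utilities)
        np.testing.assert_allclose(mdp.reward, tiny_case.utilities[1], atol=1e-14)
        for a in range(4):
            np.testing.assert_allclose(
                np.asarray(mdp.transition[a]),
                np.asarray(tiny_case.tables[1].kernel[a]),
                atol=1e-14,
            )

    def test_state_count_is_grid_product(self, tiny_case):
        mdp = assemble_post(
            np.array([0.25, 0.25, 0.25, 0.25]), tiny_case.tables, tiny_case.utilities
        )
        assert mdp.n_states == tiny_case.n_grid.n * tiny_case.p_grid.n

    def test_rewards_nonnegative(self, tiny_case):
        mdp = assemble_post(
            np.array([0.1, 0.5, 0.1, 0.3]), tiny_case.tables, tiny_case.utilities
        )
        assert mdp.reward.min() >= 0


class TestAssemblePre:
    def test_augmented_state_count(self, tiny_case):
        mdp = assemble_pre(
            np.array([0.1, 0.5, 0.1, 0.3]), tiny_case.tables, tiny_case.utilities
        )
        assert mdp.n_states == 4 * tiny_case.n_states

    def test_identity_lag_collapses_to_post(self, tiny_case):
        """With a deterministic identity lag kernel the pre-survey problem
        carries no state uncertainty: per-state optimal gains match the
        post problem built on the same (identity) dynamics, at every
        previous action."""
        S = tiny_case.n_states
        ident = [[np.eye(S)] * 4 for _ in range(4)]
        w = np.array([0.1, 0.5, 0.1, 0.3])
        n_vals, _ = tiny_case.tables[0].state_values()
        post = DiscreteMDP(
            [np.eye(S)] * 4,
            model_averaged(tiny_case.utilities, w),
            feasible_actions_post(n_vals),
        )
        pre = assemble_pre(w, tiny_case.tables, tiny_case.utilities, lag_kernels=ident)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MultichainWarning)
            g_post = solve_average_reward(post, tol=1e-10).state_gains
            g_pre = solve_average_reward(pre, tol=1e-10).state_gains.reshape(4, S)
        for ap in range(4):
            np.testing.assert_allclose(g_pre[ap], g_post, atol=1e-8)

    def test_mixture_averaging_never_beats_post(self, tiny_case):
        """Information-value bound: the pre-survey problem built as an
        exact coarsening of the post-survey mixture MDP cannot achieve a
        higher gain than the post problem."""
        for w in simplex_grid(4, 0.5).points[::2]:
            post = assemble_post(w, tiny_case.tables, tiny_case.utilities)
            pre = assemble_pre(
                w, tiny_case.tables, tiny_case.utilities, reward_averaging="mixture"
            )
            g_post = solve_average_reward(post, tol=1e-9).gain
            g_pre = solve_average_reward(pre, tol=1e-9).gain
            assert g_pre <= g_post + 1e-7

    def test_per_model_and_mixture_coincide_at_vertices(self, tiny_case):
        w = np.array([0.0, 0.0, 0.0, 1.0])
        a = assemble_pre(w, tiny_case.tables, tiny_case.utilities)
        b = assemble_pre(w, tiny_case.tables, tiny_case.utilities, reward_averaging="mixture")
        np.testing.assert_allclose(a.reward, b.reward, atol=1e-12)


class TestSolvePolicy:
    def test_compensatory_models_prescribe_liberal_everywhere(self, tiny_case):
        for k in (2, 3):  # ScRs, ScRw
            w = np.zeros(4)
            w[k] = 1.0
            for mode, assemble in (("post", assemble_post), ("pre", assemble_pre)):
                mdp = assemble(w, tiny_case.tables, tiny_case.utilities)
                table = solve_policy(mdp, mode, w, tiny_case.tables, tol=1e-8)
                assert (table.actions == 3).all(), (k, mode)

    def test_zero_reward_zero_gain(self, tiny_case):
        mdp = assemble_post(np.array([0, 1.0, 0, 0]), tiny_case.tables, tiny_case.utilities)
        zero = DiscreteMDP(mdp.transition, np.zeros_like(mdp.reward), mdp.feasible)
        table = solve_policy(zero, "post", (0, 1.0, 0, 0), tiny_case.tables)
        assert table.gain == pytest.approx(0.0, abs=1e-12)

    def test_policy_respects_closed_season_constraint(self, coarse_case):
        fam = coarse_case.family("post")
        table = fam.get(coarse_case.belief_grid.index_of((0.1, 0.5, 0.1, 0.3)))
        n_vals, _ = coarse_case.tables[0].state_values()
        closed = table.actions == 0
        assert np.all(n_vals[closed] < 4.75)

    def test_strong_density_dependence_more_liberal(self, coarse_case):
        # stronger density dependence -> more liberal prescriptions
        fam = coarse_case.family("post")
        sars = fam.get(coarse_case.belief_grid.index_of((1.0, 0, 0, 0)))
        sarw = fam.get(coarse_case.belief_grid.index_of((0, 1.0, 0, 0)))
        assert sars.actions.mean() > sarw.actions.mean()
        assert np.all(sars.actions >= sarw.actions - 1)


class TestPolicyFamily:
    def test_lazy_cache_and_vertex_consistency(self, tiny_case):
        fam = tiny_case.family("post")
        assert fam.n_solved == 0
        idx = tiny_case.belief_grid.index_of((0, 0, 0, 1.0))
        t1 = fam.get(idx)
        assert fam.n_solved == 1
        assert fam.get(idx) is t1  # cached

    def test_family_size_matches_lattice(self, tiny_case):
        assert len(tiny_case.family("post")) == 286

    def test_lookup_snaps_to_nearest(self, tiny_case):
        fam = tiny_case.family("post")
        q = np.array([0.09, 0.51, 0.11, 0.29])
        table = fam.lookup(q)
        np.testing.assert_allclose(table.belief, (0.1, 0.5, 0.1, 0.3), atol=1e-12)


class TestPolicyTableIO:
    def test_round_trip_post(self, tiny_case, tmp_path):
        fam = tiny_case.family("post")
        table = fam.get(tiny_case.belief_grid.index_of((0.1, 0.5, 0.1, 0.3)))
        path = tmp_path / "policy.tsv"
        table.save(path)
        loaded = PolicyTable.load(path)
        np.testing.assert_array_equal(loaded.actions, table.actions)
        assert loaded.belief == table.belief
        assert loaded.gain == table.gain
        np.testing.assert_array_equal(loaded.n_values, table.n_values)

    def test_round_trip_pre_has_previous_action_column(self, tiny_case, tmp_path):
        mdp = assemble_pre(
            np.array([0, 1.0, 0, 0]), tiny_case.tables, tiny_case.utilities
        )
        table = solve_policy(mdp, "pre", (0, 1.0, 0, 0), tiny_case.tables)
        frame = table.to_frame()
        assert "previous_action" in frame.columns
        assert len(frame) == 4 * tiny_case.n_states
        path = tmp_path / "pre.tsv"
        table.save(path)
        loaded = PolicyTable.load(path)
        np.testing.assert_array_equal(loaded.actions, table.actions)
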