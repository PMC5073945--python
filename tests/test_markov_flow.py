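"""Transition model, stationary distribution and flow-score pipeline."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

from cufid import (
    CorrespondenceMatrix,
    TransitionModel,
    assemble_transition,
    compute_correspondence,
    cross_transitions,
    intra_transition,
    network_flow,
    pct,
    steady_state,
    threshold_scores,
)
from conftest import make_network, make_similarity, random_instance


def model_from_matrix(p_full: np.ndarray, n_x: int = 1) -> TransitionModel:
    """Wrap an explicit stochastic matrix for direct steady_state tests."""
    n = p_full.shape[0]
    n_y = n - n_x
    z = sp.csr_matrix
    return TransitionModel(
        p_x=z((n_x, n_x)), p_y=z((n_y, n_y)),
        p_xy=z((n_x, n_y)), p_yx=z((n_y, n_x)),
        p_full=sp.csr_matrix(p_full),
    )


def dense_stationary(p_full: sp.spmatrix) -> np.ndarray:
    """Independent oracle: eigenvalue-1 left eigenvector by dense solve."""
    w, vecs = scipy.linalg.eig(p_full.toarray().T)
    close = np.flatnonzero(np.abs(w - 1.0) < 1e-9)
    assert len(close) == 1, "oracle requires a unique unit eigenvalue"
    v = np.real(vecs[:, close[0]])
    return v / v.sum()


class TestIntraTransition:
    def test_path_middle_node_splits_evenly(self, path3):
        p = intra_transition(path3).toarray()
        assert np.allclose(p[path3.index("b")], [0.5, 0.0, 0.5])

    def test_weighted_star_center_row(self):
        net = make_network("star", [("c", "l1", 2.0), ("c", "l2", 3.0)])
        p = intra_transition(net).toarray()
        assert np.allclose(p[net.index("c")], [0.0, 0.4, 0.6])

    def test_isolated_node_gets_zero_row(self):
        net = make_network("iso", [("a", "b")], isolated=["d"])
        p = intra_transition(net).toarray()
        assert np.all(p[net.index("d")] == 0.0)


class TestCrossTransitions:
    @pytest.fixture
    def simple_sim(self):
        net_x = make_network("X", [("u1", "u2")])
        net_y = make_network("Y", [("v1", "v2")])
        return make_similarity(
            net_x, net_y, {("u1", "v1"): 1.0, ("u1", "v2"): 1.0, ("u2", "v2"): 2.0}
        )

    def test_row_normalised_similarity(self, simple_sim):
        p_xy, _ = cross_transitions(simple_sim)
        assert np.allclose(p_xy.toarray(), [[0.5, 0.5], [0.0, 1.0]])

    def test_column_normalised_similarity(self, simple_sim):
        _, p_yx = cross_transitions(simple_sim)
        assert np.allclose(p_yx.toarray(), [[1.0, 0.0], [1 / 3, 2 / 3]])

    def test_node_without_entries_gets_zero_row(self):
        net_x = make_network("X", [("u1", "u2")])
        net_y = make_network("Y", [("v1", "v2")])
        sim = make_similarity(net_x, net_y, {("u1", "v1"): 3.0})
        p_xy, p_yx = cross_transitions(sim)
        assert np.all(p_xy.toarray()[1] == 0.0)
        assert np.all(p_yx.toarray()[1] == 0.0)

    def test_scaling_a_pair_does_not_decrease_its_conditionals(self, rng):
        net_x, net_y, sim = random_instance(rng, full_sim=True)
        p_xy, p_yx = cross_transitions(sim)
        u, v = net_x.nodes[0], net_y.nodes[0]
        i, j = net_x.index(u), net_y.index(v)
        boosted = dict(sim.entries)
        boosted[(u, v)] *= 3.0
        sim2 = make_similarity(net_x, net_y, boosted)
        q_xy, q_yx = cross_transitions(sim2)
        assert q_xy[i, j] >= p_xy[i, j]
        assert q_yx[j, i] >= p_yx[j, i]


class TestAssemble:
    def test_both_blocks_active_row_sums_to_one(self):
        net_x = make_network("X", [("u1", "u2")])
        net_y = make_network("Y", [("v1", "v2")])
        sim = make_similarity(net_x, net_y, {("u1", "v1"): 2.0})
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        full = model.p_full.toarray()
        assert np.allclose(full.sum(axis=1), 1.0, atol=1e-12)
        # u1 has intra and cross moves: each block contributes mass 0.5
        assert np.isclose(full[0, 1], 0.5) and np.isclose(full[0, 2], 0.5)

    def test_single_active_block_used_unscaled(self):
        net_x = make_network("X", [("u1", "u2")], isolated=["u3"])
        net_y = make_network("Y", [("v1", "v2")])
        sim = make_similarity(net_x, net_y, {("u3", "v1"): 1.0, ("u3", "v2"): 3.0})
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        row = model.p_full.toarray()[net_x.index("u3")]
        assert np.allclose(row, [0, 0, 0, 0.25, 0.75])

    def test_fully_isolated_node_gets_uniform_row(self):
        net_x = make_network("X", [("u1", "u2")], isolated=["u3"])
        net_y = make_network("Y", [("v1", "v2")])
        sim = make_similarity(net_x, net_y, {("u1", "v1"): 1.0})
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        row = model.p_full.toarray()[net_x.index("u3")]
        assert np.allclose(row, 1.0 / 5)

    def test_block_mix_weights_the_intra_block(self):
        net_x = make_network("X", [("u1", "u2")])
        net_y = make_network("Y", [("v1", "v2")])
        sim = make_similarity(net_x, net_y, {("u1", "v1"): 1.0})
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y),
            *cross_transitions(sim), block_mix=0.8,
        )
        full = model.p_full.toarray()
        assert np.isclose(full[0, 1], 0.8) and np.isclose(full[0, 2], 0.2)

    @pytest.mark.parametrize("seed", range(8))
    def test_row_stochastic_for_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        net_x, net_y, sim = random_instance(rng, n_x=8, n_y=7, sim_density=0.3)
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        sums = np.asarray(model.p_full.sum(axis=1)).ravel()
        assert np.abs(sums - 1.0).max() <= 1e-12

    def test_dimension_mismatch_raises(self):
        z = sp.csr_matrix
        with pytest.raises(ValueError, match="shape"):
            assemble_transition(z((2, 2)), z((3, 3)), z((2, 2)), z((3, 2)))


class TestSteadyState:
    def test_symmetric_two_node_chain(self):
        model = model_from_matrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        pi = steady_state(model)
        assert np.allclose(pi, [0.5, 0.5], atol=1e-9)

    def test_asymmetric_two_node_chain_matches_linear_solve(self):
        # pi P = pi with P = [[.9,.1],[.5,.5]]: 0.1 pi0 = 0.5 pi1 -> (5/6, 1/6)
        model = model_from_matrix(np.array([[0.9, 0.1], [0.5, 0.5]]))
        pi = steady_state(model)
        assert np.allclose(pi, [5 / 6, 1 / 6], atol=1e-9)

    def test_relabeling_permutes_pi_identically(self, rng):
        net_x, net_y, sim = random_instance(rng, full_sim=True)
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        pi = steady_state(model)
        n = model.p_full.shape[0]
        perm = rng.permutation(n)
        p_perm = model.p_full.toarray()[np.ix_(perm, perm)]
        pi_perm = steady_state(model_from_matrix(p_perm))
        assert np.allclose(pi_perm, pi[perm], atol=1e-8)

    def test_non_stochastic_matrix_rejected(self):
        model = model_from_matrix(np.array([[0.9, 0.5], [0.5, 0.5]]))
        with pytest.raises(RuntimeError, match="stochastic"):
            steady_state(model)

    def test_max_iter_warns_and_flags(self, caplog):
        # unequal-sided pure bipartite walk oscillates and cannot converge
        model = model_from_matrix(
            np.array([[0, 0.5, 0.5], [1.0, 0, 0], [1.0, 0, 0]]), n_x=1
        )
        with caplog.at_level("WARNING", logger="cufid"):
            steady_state(model, tol=1e-15, max_iter=5)
        assert not model.converged
        assert any("did not reach" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_power_method_matches_dense_eigen_oracle(self, seed):
        """On tiny instances the power-method fixed point agrees with the
        unit-eigenvalue eigenvector from a dense solve."""
        rng = np.random.default_rng(seed)
        net_x, net_y, sim = random_instance(rng, n_x=3, n_y=3, full_sim=True)
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        pi = steady_state(model)
        assert np.abs(pi - dense_stationary(model.p_full)).max() <= 1e-8


class TestNetworkFlow:
    def test_single_cross_pair_carries_unit_flow(self):
        net_x = make_network("X", [], isolated=["a"])
        net_y = make_network("Y", [], isolated=["p"])
        sim = make_similarity(net_x, net_y, {("a", "p"): 7.0})
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        pi = steady_state(model)
        c = network_flow(pi, model.p_xy, model.p_yx, sim)
        assert np.isclose(c.scores[0, 0], 1.0)

    def test_support_equals_similarity_support(self, rng):
        net_x, net_y, sim = random_instance(rng, sim_density=0.3)
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        pi = steady_state(model)
        c = network_flow(pi, model.p_xy, model.p_yx, sim)
        assert set(zip(*c.scores.nonzero())) == set(zip(*sim.matrix().nonzero()))

    @pytest.mark.parametrize("seed", range(5))
    def test_total_flow_equals_similarity_bearing_stationary_mass(self, seed):
        """Flow conservation: summing c over all cross edges returns the
        stationary mass of every node that has at least one similarity
        entry (each such node's outgoing cross conditional sums to 1)."""
        rng = np.random.default_rng(100 + seed)
        net_x, net_y, sim = random_instance(rng, n_x=9, n_y=7, sim_density=0.4)
        model = assemble_transition(
            intra_transition(net_x), intra_transition(net_y), *cross_transitions(sim)
        )
        pi = steady_state(model)
        c = network_flow(pi, model.p_xy, model.p_yx, sim)
        s = sim.matrix()
        x_bearing = np.asarray(s.sum(axis=1)).ravel() > 0
        y_bearing = np.asarray(s.sum(axis=0)).ravel() > 0
        expected = model.pi_x[x_bearing].sum() + model.pi_y[y_bearing].sum()
        assert abs(c.scores.sum() - expected) <= 1e-10


class TestPct:
    def unit_path_instance(self):
        net_x = make_network("X", [("a", "b")])
        net_y = make_network("Y", [("p", "q")])
        sim = make_similarity(net_x, net_y, {("a", "p"): 1.0})
        c = CorrespondenceMatrix(
            sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.0]])),
            "raw_flow", list(net_x.nodes), list(net_y.nodes),
        )
        return net_x, net_y, c

    def test_alpha_one_is_identity(self, rng):
        net_x, net_y, sim = random_instance(rng)
        model, c_raw, _, _ = compute_correspondence(net_x, net_y, sim)
        out = pct(c_raw, model.p_x, model.p_y, alpha=1.0)
        assert np.allclose(out.scores.toarray(), c_raw.scores.toarray())

    def test_alpha_zero_shifts_single_entry_to_neighbours(self):
        net_x, net_y, c = self.unit_path_instance()
        out = pct(c, intra_transition(net_x), intra_transition(net_y), alpha=0.0)
        expected = np.zeros((2, 2))
        expected[net_x.index("b"), net_y.index("q")] = 1.0
        assert np.allclose(out.scores.toarray(), expected)

    def test_mass_preserved_on_regular_networks(self, rng):
        # the propagated term's total is c_x^T C c_y with c the column
        # sums of the row-stochastic matrices; on regular graphs these
        # are all 1, so the PCT preserves total score mass exactly
        cycle = lambda name, pre, n: make_network(
            name, [(f"{pre}{i}", f"{pre}{(i + 1) % n}") for i in range(n)]
        )
        net_x, net_y = cycle("CX", "u", 5), cycle("CY", "v", 4)
        sim = make_similarity(
            net_x, net_y,
            {(u, v): float(rng.uniform(0.5, 2.0)) for u in net_x.nodes for v in net_y.nodes},
        )
        _, c_raw, c_pct, _ = compute_correspondence(net_x, net_y, sim)
        assert np.isclose(c_pct.scores.sum(), c_raw.scores.sum())

    def test_matches_entrywise_brute_force(self, rng):
        net_x, net_y, sim = random_instance(rng, edge_p=0.4, sim_density=0.5)
        model, c_raw, c_pct, _ = compute_correspondence(net_x, net_y, sim)
        px = model.p_x.toarray()
        py = model.p_y.toarray()
        c = c_raw.scores.toarray()
        alpha = 0.9
        expected = np.zeros_like(c)
        for b in range(c.shape[0]):
            for q in range(c.shape[1]):
                prop = sum(
                    px[b, a] * c[a, p] * py[q, p]
                    for a in range(c.shape[0])
                    for p in range(c.shape[1])
                )
                expected[b, q] = alpha * c[b, q] + (1 - alpha) * prop
        assert np.allclose(c_pct.scores.toarray(), expected)

    def test_alpha_out_of_range_rejected(self, rng):
        net_x, net_y, sim = random_instance(rng)
        model, c_raw, _, _ = compute_correspondence(net_x, net_y, sim)
        with pytest.raises(ValueError, match="alpha"):
            pct(c_raw, model.p_x, model.p_y, alpha=1.5)


class TestThreshold:
    def stage_pair(self, raw, transformed, nodes=("u1", "u2"), ynodes=("v1", "v2")):
        c_raw = CorrespondenceMatrix(
            sp.csr_matrix(np.asarray(raw, dtype=float)), "raw_flow",
            list(nodes), list(ynodes),
        )
        c_pct = CorrespondenceMatrix(
            sp.csr_matrix(np.asarray(transformed, dtype=float)), "pct",
            list(nodes), list(ynodes),
        )
        return c_raw, c_pct

    def test_percentile_zero_keeps_all_positive_entries(self):
        c_raw, c_pct = self.stage_pair([[1, 0], [0, 0]], [[0.9, 0.4], [0.2, 0]])
        out = threshold_scores(c_pct, c_raw, beta_percentile=0.0)
        assert np.allclose(out.scores.toarray(), [[0.9, 0.4], [0.2, 0]])

    def test_raw_supported_entry_kept_below_threshold(self):
        # beta (p90 of positives) is far above the (u1, v1) score, but the
        # raw flow there was positive, so the transformed value survives
        c_raw, c_pct = self.stage_pair(
            [[0.01, 0], [0, 0]], [[0.05, 5.0], [4.0, 3.0]]
        )
        out = threshold_scores(c_pct, c_raw, beta_percentile=90.0)
        assert out.scores[0, 0] == 0.05

    def test_unsupported_entry_below_threshold_removed(self):
        c_raw, c_pct = self.stage_pair(
            [[0.01, 0], [0, 0]], [[0.05, 5.0], [0.04, 3.0]]
        )
        out = threshold_scores(c_pct, c_raw, beta_percentile=90.0)
        assert out.scores[1, 0] == 0.0
        assert out.stage == "thresholded"

    def test_support_contains_raw_support(self, rng):
        net_x, net_y, sim = random_instance(rng, sim_density=0.4)
        _, c_raw, c_pct, c_bar = compute_correspondence(net_x, net_y, sim)
        raw_support = set(zip(*c_raw.scores.nonzero()))
        bar_support = set(zip(*c_bar.scores.nonzero()))
        assert raw_support <= bar_support


class TestEquivariance:
    def test_swapping_networks_transposes_scores(self, rng):
        net_x, net_y, sim = random_instance(rng, sim_density=0.5)
        _, c_raw, _, c_bar = compute_correspondence(net_x, net_y, sim)
        sim_t = make_similarity(
            net_y, net_x, {(v, u): s for (u, v), s in sim.entries.items()}
        )
        _, c_raw_t, _, c_bar_t = compute_correspondence(net_y, net_x, sim_t)
        assert np.allclose(
            c_raw_t.scores.toarray(), c_raw.scores.toarray().T, atol=1e-12
        )
        assert np.allclose(
            c_bar_t.scores.toarray(), c_bar.scores.toarray().T, atol=1e-12
        )

    def test_relabeling_nodes_permutes_scores(self, rng):
        net_x, net_y, sim = random_instance(rng, sim_density=0.5)
        _, c_raw, _, _ = compute_correspondence(net_x, net_y, sim)
        # rebuild X with a different node order (reversed edge stream)
        from cufid import PPINetwork

        net_x2 = PPINetwork.from_interactions(
            "Xr",
            [(b, a, w) for (a, b), w in reversed(net_x.edges.items())],
            isolated=list(reversed(net_x.nodes)),
        )
        assert net_x2.nodes != net_x.nodes  # the reindexing is non-trivial
        sim2 = make_similarity(net_x2, net_y, sim.entries)
        _, c_raw2, _, _ = compute_correspondence(net_x2, net_y, sim2)
        d1 = c_raw.scores.toarray()
        d2 = c_raw2.scores.toarray()
        for u in net_x.nodes:
            assert np.allclose(
                d2[net_x2.index(u)], d1[net_x.index(u)], atol=1e-12
            )
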