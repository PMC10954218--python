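"""Velocity estimation, directed transitions, absorption, drivers."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gastrufate import cluster as cl
from gastrufate import velocity as vl
from gastrufate._utils import as_dense
from gastrufate.pseudotime import TransitionMatrix


def _tm(matrix):
    return TransitionMatrix(T=sp.csr_matrix(np.asarray(matrix, dtype=float)),
                            k_neighbors=1, bandwidth=1.0)


class TestEstimateVelocity:
    def test_steady_state_velocity_near_zero(self):
        """At constant transcription, u = (gamma/beta) s, so v ~ 0."""
        rng = np.random.default_rng(0)
        n, g = 400, 30
        gamma_over_beta = 0.5
        s = rng.poisson(20.0, size=(n, g)).astype(float)
        u = rng.poisson(20.0 * gamma_over_beta, size=(n, g)).astype(float)
        emb = rng.normal(size=(n, 3))
        model = vl.estimate_velocity(s, u, emb, k_smooth=30)
        mean_v = model.velocity.mean(axis=0)
        scale = model.smoothed_unspliced.mean(axis=0)
        assert np.abs(mean_v / scale).max() < 0.15

    def test_gamma_recovery_within_ten_percent(self):
        rng = np.random.default_rng(1)
        n, g = 2000, 10
        s_level = rng.uniform(5, 50, size=(n, 1)) * np.ones((1, g))
        gamma = 0.5
        s = rng.poisson(s_level)
        u = rng.poisson(s_level * gamma)
        emb = np.log1p(s_level[:, :3]) + rng.normal(0, 0.01, size=(n, 3))
        model = vl.estimate_velocity(s, u, emb, k_smooth=10)
        assert np.abs(model.gamma - gamma).max() / gamma < 0.10

    def test_induction_phase_positive_velocity(self, small_sim_norm):
        """Genes being induced (rising alpha) show unspliced excess."""
        adata = small_sim_norm
        E = as_dense(adata.layers["pearson"])
        pcs = cl.select_pcs(E, cl.variable_genes(E, 2000))
        model = vl.estimate_velocity(
            as_dense(adata.layers["spliced"]),
            as_dense(adata.layers["unspliced"]),
            pcs.scores, gene_names=adata.var_names)
        names = list(model.gene_names)
        # bifunctional genes are induced along the cardiac branch
        tt = adata.obs["truth_time"].to_numpy()
        cardiac = adata.obs["truth_branch"].isin(["A", "A1", "A2"]).to_numpy()
        inducting = cardiac & (tt > 0.45) & (tt < 0.9)
        cols = [names.index(g) for g in names if g.startswith("Bif")]
        frac_pos = (model.velocity[np.ix_(inducting, cols)] > 0).mean()
        assert frac_pos > 0.7

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            vl.estimate_velocity(np.ones((10, 3)), np.ones((10, 4)),
                                 np.ones((10, 2)))


class TestVelocityTransitions:
    def test_cosine_monotone_preference(self):
        # three cells on a line; middle cell's velocity points right
        emb = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        X = emb.copy()
        V = np.array([[1.0, 0], [1.0, 0], [1.0, 0]])
        model = vl.VelocityModel(gamma=np.ones(2), velocity=V,
                                 smoothed_spliced=X, smoothed_unspliced=X,
                                 fitted_genes=np.arange(2))
        tm = vl.velocity_transition_matrix(model, emb, k_neighbors=2)
        T = tm.T.toarray()
        assert T[1, 2] > T[1, 0]  # forward beats backward

    def test_zero_velocity_uniform_rows(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(30, 3))
        X = rng.normal(size=(30, 5))
        model = vl.VelocityModel(gamma=np.ones(5),
                                 velocity=np.zeros((30, 5)),
                                 smoothed_spliced=X, smoothed_unspliced=X,
                                 fitted_genes=np.arange(5))
        with pytest.warns(UserWarning, match="zero velocity"):
            tm = vl.velocity_transition_matrix(model, emb, k_neighbors=5)
        T = tm.T.toarray()
        nz = T[T > 0]
        np.testing.assert_allclose(nz, 0.2, atol=1e-12)

    def test_forward_flow_exceeds_reverse_on_simdata(self, small_sim_norm):
        adata = small_sim_norm
        E = as_dense(adata.layers["pearson"])
        pcs = cl.select_pcs(E, cl.variable_genes(E, 2000))
        model = vl.estimate_velocity(
            as_dense(adata.layers["spliced"]),
            as_dense(adata.layers["unspliced"]), pcs.scores)
        tm = vl.velocity_transition_matrix(model, pcs.scores, k_neighbors=15)
        tt = adata.obs["truth_time"].to_numpy()
        T = tm.T.tocoo()
        forward = T.data[tt[T.col] > tt[T.row] + 0.02].sum()
        backward = T.data[tt[T.col] < tt[T.row] - 0.02].sum()
        assert forward > backward


class TestAbsorption:
    def test_gamblers_ruin_symmetric(self):
        # states: A(absorbing), 1, B(absorbing); P(1->A)=P(1->B)=0.5
        T = [[1, 0, 0], [0.5, 0, 0.5], [0, 0, 1]]
        fate = vl.absorption_probabilities(_tm(T), np.array(["A", None, "B"],
                                                            dtype=object))
        np.testing.assert_allclose(fate.B[1], [0.5, 0.5], atol=1e-12)

    def test_two_state_chain_closed_form(self):
        # A <- 1 <-> 2 -> B with the hand-solved answer B[1] = (2/3, 1/3)
        T = [[1, 0, 0, 0],
             [0.5, 0, 0.5, 0],
             [0, 0.5, 0, 0.5],
             [0, 0, 0, 1]]
        fate = vl.absorption_probabilities(
            _tm(T), np.array(["A", None, None, "B"], dtype=object))
        np.testing.assert_allclose(fate.B[1], [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(fate.B[2], [1 / 3, 2 / 3], atol=1e-12)

    def test_rows_sum_to_one_and_terminal_identity(self):
        rng = np.random.default_rng(3)
        n = 40
        M = rng.random((n, n)) * (rng.random((n, n)) < 0.2)
        M[:, :2] += 0.05  # ensure reachability of terminals
        M /= M.sum(axis=1, keepdims=True)
        M[0] = 0; M[0, 0] = 1
        M[1] = 0; M[1, 1] = 1
        labels = np.array(["X", "Y"] + [None] * (n - 2), dtype=object)
        fate = vl.absorption_probabilities(_tm(M), labels)
        np.testing.assert_allclose(fate.B.sum(axis=1), 1.0, atol=1e-8)
        assert fate.B[0, 0] == 1.0 and fate.B[1, 1] == 1.0

    def test_unreachable_transient_errors(self):
        # the middle state loops onto itself and never reaches a terminal
        loop = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        labels = np.array(["A", None, "B"], dtype=object)
        with pytest.raises(ValueError, match="cannot reach"):
            vl.absorption_probabilities(_tm(loop), labels)


class TestRandomWalkOracle:
    def test_deterministic_chain_exact(self):
        T = [[0, 1, 0], [0, 0, 1], [0, 0, 1]]
        labels = np.array([None, None, "Z"], dtype=object)
        fate = vl.random_walk_oracle(_tm(T), labels, n_walks=50, seed=0)
        np.testing.assert_allclose(fate.B[:, 0], 1.0)

    def test_gamblers_ruin_close_to_half(self):
        T = [[1, 0, 0], [0.5, 0, 0.5], [0, 0, 1]]
        labels = np.array(["A", None, "B"], dtype=object)
        fate = vl.random_walk_oracle(_tm(T), labels, n_walks=10000, seed=1)
        assert abs(fate.B[1, 0] - 0.5) < 0.02

    def test_agrees_with_linear_solve_on_random_chain(self):
        rng = np.random.default_rng(4)
        n = 25
        M = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
        M[:, :3] += 0.05
        M /= M.sum(axis=1, keepdims=True)
        for i in range(3):
            M[i] = 0
            M[i, i] = 1
        labels = np.array(["A", "B", "C"] + [None] * (n - 3), dtype=object)
        exact = vl.absorption_probabilities(_tm(M), labels)
        mc = vl.random_walk_oracle(_tm(M), labels, n_walks=4000, seed=2)
        assert np.abs(exact.B - mc.B).max() < 0.03


class TestDrivers:
    def test_perfect_and_negated_copies(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        B = np.column_stack([p, 1 - p])
        fate = vl.FateProbabilities(B=B, fates=("F", "G"),
                                    terminal_mask=np.zeros(100, dtype=bool))
        E = np.column_stack([p, -p, np.full(100, 2.0)])
        table = vl.lineage_drivers(fate, E, "F",
                                   gene_names=["copy", "neg", "flat"])
        assert table.loc["copy", "rho"] == pytest.approx(1.0)
        assert table.loc["copy", "class"] == "driver"
        assert table.loc["neg", "rho"] == pytest.approx(-1.0)
        assert table.loc["neg", "class"] == "antidriver"
        assert table.loc["flat", "class"] == "neither"
        assert table.loc["flat", "constant"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        B = np.column_stack([p, 1 - p])
        fate = vl.FateProbabilities(B=B, fates=("F", "G"),
                                    terminal_mask=np.zeros(200, dtype=bool))
        x = rng.normal(size=200) + 2 * p
        t1 = vl.lineage_drivers(fate, x[:, None], "F", gene_names=["g"])
        t2 = vl.lineage_drivers(fate, np.exp(x)[:, None], "F", gene_names=["g"])
        assert t1.loc["g", "rho"] == pytest.approx(t2.loc["g", "rho"])


class TestBranchingSignature:
    def _table(self, genes, drivers, antidrivers):
        cls = ["driver" if g in drivers else
               "antidriver" if g in antidrivers else "neither" for g in genes]
        return pd.DataFrame({"class": cls, "rho": 0.0}, index=genes)

    def test_disjoint_sets_empty_signature(self):
        genes = list("abcdef")
        a = self._table(genes, {"a", "b"}, set())
        b = self._table(genes, set(), {"c", "d"})
        sig = vl.branching_signature(a, b)
        assert sig["signature"] == [] and sig["pct_of_antidrivers"] == 0.0

    def test_antidrivers_subset_of_drivers(self):
        genes = list("abcdef")
        a = self._table(genes, {"a", "b", "c"}, set())
        b = self._table(genes, set(), {"a", "b"})
        sig = vl.branching_signature(a, b)
        assert sig["pct_of_antidrivers"] == 100.0
        assert sig["n_shared"] == 2
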