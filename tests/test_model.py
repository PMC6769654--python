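import numpy as np
import pytest
import scipy.sparse as sp

import heterolink as hl
from heterolink import model as M
from heterolink.graph_io import GeneNetwork


def random_gene_net(rng, n):
    ids = [f"g{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.add((ids[i], ids[j]))
    if not edges:
        edges.add((ids[0], ids[1]))
    return GeneNetwork.from_edges(edges)


def dense_normalized(net):
    """Brute-force oracle: D^{-1/2}(A+I)D^{-1/2} with dense numpy."""
    a = net.adjacency.toarray() + np.eye(net.n_genes)
    d = a.sum(axis=1)
    return a / np.sqrt(np.outer(d, d))


class TestNormalizeAdjacency:
    def test_isolated_node(self):
        net = GeneNetwork(["g"], sp.csr_matrix((1, 1)))
        assert np.allclose(hl.normalize_adjacency(net).matrix.toarray(), [[1.0]])

    def test_single_edge(self):
        net = GeneNetwork.from_edges({("a", "b")})
        out = hl.normalize_adjacency(net).matrix.toarray()
        assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_path_graph_values(self):
        net = GeneNetwork.from_edges({("g0", "g1"), ("g1", "g2")})
        out = hl.normalize_adjacency(net).matrix.toarray()
        assert np.allclose(np.diag(out), [0.5, 1 / 3, 0.5])
        assert np.isclose(out[0, 1], 1 / np.sqrt(6))
        assert np.isclose(out[1, 2], 1 / np.sqrt(6))
        assert out[0, 2] == 0

    def test_matches_dense_oracle_and_spectrum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            net = random_gene_net(rng, int(rng.integers(2, 31)))
            out = hl.normalize_adjacency(net).matrix.toarray()
            assert np.allclose(out, dense_normalized(net), atol=1e-10)
            assert np.allclose(out, out.T, atol=1e-12)
            eig = np.linalg.eigvalsh(out)
            assert eig.max() <= 1 + 1e-12
            assert abs(eig).max() <= 1 + 1e-12


class TestLayerForward:
    def test_identity_propagation(self):
        a_hat = sp.identity(3, format="csr")
        h = np.arange(12.0).reshape(3, 4)
        out = hl.gene_layer_forward(a_hat, h, np.eye(4), activation="identity")
        assert np.allclose(out, h)

    def test_relu_clips_negative(self):
        a_hat = sp.identity(2, format="csr")
        h = -np.ones((2, 3))
        out = hl.gene_layer_forward(a_hat, h, np.eye(3), activation="relu")
        assert np.all(out == 0)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = random_gene_net(rng, 6)
            a_hat = hl.normalize_adjacency(net)
            h = rng.normal(size=(net.n_genes, 5))
            w = rng.normal(size=(5, 3))
            out = hl.gene_layer_forward(a_hat, h, w, activation="tanh")
            oracle = np.tanh(dense_normalized(net) @ h @ w)
            assert np.allclose(out, oracle, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            hl.gene_layer_forward(sp.identity(3, format="csr"), np.ones((3, 4)), np.ones((5, 2)))


class TestCrossLayer:
    def test_single_gene_mirna_copies_row(self):
        inc = sp.csr_matrix(np.array([[0.0, 1.0, 0.0]]))
        h = np.arange(9.0).reshape(3, 3)
        out = hl.cross_layer_forward(inc, h, np.eye(3))
        assert np.allclose(out[0], h[1])

    def test_row_normalization_averages(self):
        inc = sp.csr_matrix(np.array([[1.0, 1.0]]))
        h = np.array([[1.0, 0.0], [0.0, 2.0]])
        out = hl.cross_layer_forward(inc, h, np.eye(2))
        assert np.allclose(out[0], [0.5, 1.0])

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        inc = sp.csr_matrix((rng.random((4, 6)) < 0.5).astype(float))
        h = rng.normal(size=(6, 5))
        w = rng.normal(size=(5, 5))
        deg = np.maximum(inc.toarray().sum(axis=1), 1.0)
        oracle = (inc.toarray() / deg[:, None]) @ h @ w
        out = hl.cross_layer_forward(inc, h, w, activation="identity")
        assert np.allclose(out, oracle, atol=1e-10)

    def test_norm_none_is_raw_sum(self):
        inc = sp.csr_matrix(np.array([[1.0, 1.0]]))
        h = np.array([[1.0, 0.0], [0.0, 2.0]])
        out = hl.cross_layer_forward(inc, h, np.eye(2), norm="none")
        assert np.allclose(out[0], [1.0, 2.0])


class TestFinalEmbeddings:
    def test_single_layer_both_modes(self):
        m = np.ones((2, 3))
        d = np.zeros((4, 3))
        for mode in ("last", "mean"):
            z_d, z_m = hl.final_embeddings([m], [d], mode)
            assert np.allclose(z_m, m) and np.allclose(z_d, d)

    def test_mean_arithmetic(self):
        m = np.arange(6.0).reshape(2, 3)
        z_d, z_m = hl.final_embeddings([m, 3 * m], [m, 3 * m], "mean")
        assert np.allclose(z_m, 2 * m)

    def test_mean_width_mismatch(self):
        with pytest.raises(ValueError, match="widths"):
            hl.final_embeddings([np.ones((2, 3)), np.ones((2, 4))], [np.ones((1, 3))] * 2, "mean")


class TestDecoder:
    def test_zero_vector_scores_zero(self):
        assert hl.decode(np.zeros(4), np.ones((4, 4)), np.ones(4)) == 0.0

    def test_identity_relation_is_dot(self):
        rng = np.random.default_rng(3)
        zd, zm = rng.normal(size=4), rng.normal(size=4)
        assert np.isclose(hl.decode(zd, np.eye(4), zm), zd @ zm)

    def test_double_sum_oracle(self):
        rng = np.random.default_rng(4)
        zd, zm = rng.normal(size=4), rng.normal(size=4)
        m = rng.normal(size=(4, 4))
        oracle = sum(zd[a] * m[a, b] * zm[b] for a in range(4) for b in range(4))
        assert np.isclose(hl.decode(zd, m, zm), oracle, atol=1e-12)

    def test_decode_all_matches_pairwise(self):
        rng = np.random.default_rng(5)
        zd, zm, m = rng.normal(size=(3, 4)), rng.normal(size=(5, 4)), rng.normal(size=(4, 4))
        s = hl.decode_all(zd, m, zm)
        for i in range(3):
            for j in range(5):
                assert np.isclose(s[i, j], hl.decode(zd[i], m, zm[j]))

    def test_sigmoid_values_and_monotonicity(self):
        assert hl.edge_probability(0.0) == 0.5
        assert np.isclose(hl.edge_probability(np.log(3)), 0.75)
        g = np.linspace(-5, 5, 11)
        p = hl.edge_probability(g)
        assert np.all(np.diff(p) > 0)

    def test_sigmoid_stable_at_extremes(self):
        assert np.isfinite(hl.edge_probability(1e4))
        assert np.isfinite(hl.edge_probability(-1e4))
        assert 0.0 <= hl.edge_probability(-1e4) < hl.edge_probability(1e4) <= 1.0


class TestFullForward:
    def _setup(self, dataset, seed=0):
        from heterolink import training as T

        feats = hl.one_hot_features(dataset.gene_net)
        state = T.init_weights(feats.feature_dim, (4, 4), seed)
        ops = M.GraphOperators.from_dataset(dataset)
        return feats, state, ops

    def test_forward_deterministic(self, tiny_dataset):
        feats, state, ops = self._setup(tiny_dataset)
        a = M.forward(ops, feats.values, state)
        b = M.forward(ops, feats.values, state)
        assert np.array_equal(a.z_d, b.z_d) and np.array_equal(a.z_m, b.z_m)

    def test_permutation_equivariance(self, tiny_dataset):
        """Relabelling genes permutes activations and leaves scores unchanged."""
        from heterolink import graph_io

        feats, state, ops = self._setup(tiny_dataset)
        base = M.forward(ops, feats.values, state)
        base_scores = M.decode_all(base.z_d, state.M, base.z_m)

        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_dataset.n_genes)
        inv = np.argsort(perm)
        gnet = graph_io.GeneNetwork(
            [tiny_dataset.gene_net.gene_ids[i] for i in perm],
            sp.csr_matrix(tiny_dataset.gene_net.adjacency.toarray()[np.ix_(perm, perm)]),
        )
        mg = graph_io.BipartiteNetwork(
            tiny_dataset.mirna_gene.row_ids, gnet.gene_ids,
            sp.csr_matrix(tiny_dataset.mirna_gene.incidence.toarray()[:, perm]),
        )
        dg = graph_io.BipartiteNetwork(
            tiny_dataset.disease_gene.row_ids, gnet.gene_ids,
            sp.csr_matrix(tiny_dataset.disease_gene.incidence.toarray()[:, perm]),
        )
        ds2 = graph_io.HeteroDataset(gnet, mg, dg, tiny_dataset.associations)
        ops2 = M.GraphOperators.from_dataset(ds2)
        out = M.forward(ops2, feats.values[perm], state)
        assert np.allclose(out.h_gg[-1], base.h_gg[-1][perm], atol=1e-12)
        assert np.allclose(
            M.decode_all(out.z_d, state.M, out.z_m), base_scores, atol=1e-12
        )

    def test_one_hot_single_layer_is_canonical_gcn(self, tiny_dataset):
        """With one-hot H(0), one gene layer equals f(Â W) exactly."""
        from heterolink import training as T

        feats = hl.one_hot_features(tiny_dataset.gene_net)
        state = T.init_weights(5, (3,), 0)
        a_hat = hl.normalize_adjacency(tiny_dataset.gene_net)
        out = hl.gene_layer_forward(a_hat, feats.values, state.W_gg[0], "relu")
        oracle = np.maximum(a_hat.matrix.toarray() @ state.W_gg[0], 0.0)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_state_save_load_round_trip(self, tmp_path, tiny_dataset):
        from heterolink import training as T

        state = T.init_weights(5, (4, 4), 1)
        p = tmp_path / "ckpt.npz"
        hl.save_state(p, state, {"note": "test"})
        back, manifest = hl.load_state(p)
        for (n1, w1), (n2, w2) in zip(state.named_parameters(), back.named_parameters()):
            assert n1 == n2 and np.array_equal(w1, w2)
        assert manifest["config"]["note"] == "test"
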