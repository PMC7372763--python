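"""Encoder, decoder, loss terms and S-VGAE training."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from svgae import (EdgeList, RunConfig, build_propagation,
                   build_signed_adjacency, decode_pair, encode, gcn_layer,
                   kl_term, reconstruction_term, reparameterize, train_svgae)
from svgae.graph import HIGH_NEGATIVE, POSITIVE, SignedAdjacency
from svgae.model import (EncoderWeights, PropagationMatrix,
                         init_encoder_weights)

from _oracles import encoder_bruteforce, gcn_bruteforce, kl_montecarlo


def _random_adjacency(n, rng, p_pos=0.25, p_neg=0.15):
    ids = [f"p{i}" for i in range(n)]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            u = rng.random()
            if u < p_pos:
                pairs.append((ids[i], ids[j], POSITIVE))
            elif u < p_pos + p_neg:
                pairs.append((ids[i], ids[j], HIGH_NEGATIVE))
    return build_signed_adjacency(ids, EdgeList(pairs))


class TestPropagation:
    def test_raw_equals_adjacency(self, rng):
        adj = _random_adjacency(8, rng)
        p = build_propagation(adj, "raw")
        np.testing.assert_array_equal(p.matrix, adj.matrix)

    def test_signed_sym_norm_definition(self, rng):
        adj = _random_adjacency(8, rng)
        p = build_propagation(adj, "signed_sym_norm")
        d = np.abs(adj.matrix).sum(axis=1)
        expected = np.diag(d ** -0.5) @ adj.matrix @ np.diag(d ** -0.5)
        np.testing.assert_allclose(p.matrix, expected, atol=1e-12)


class TestGcnLayer:
    def test_zero_weights_annihilate(self, rng):
        adj = _random_adjacency(6, rng)
        p = build_propagation(adj)
        X = rng.standard_normal((6, 5))
        out = gcn_layer(X, p, np.zeros((5, 4)))
        np.testing.assert_array_equal(out, np.zeros((6, 4)))

    def test_identity_propagation_is_plain_linear(self, rng):
        p = PropagationMatrix(matrix=np.eye(4), mode="raw")
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 2))
        out = gcn_layer(X, p, W, activation="identity")
        np.testing.assert_allclose(out, X @ W, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        adj = _random_adjacency(6, rng)
        p = build_propagation(adj)
        X = rng.standard_normal((6, 7))
        W = rng.standard_normal((7, 3))
        expected = gcn_bruteforce(adj.matrix, X, W, use_relu=True)
        np.testing.assert_allclose(gcn_layer(X, p, W), expected, atol=1e-6)

    def test_dimension_mismatch_names_shapes(self, rng):
        adj = _random_adjacency(4, rng)
        p = build_propagation(adj)
        with pytest.raises(ValueError, match="rows"):
            gcn_layer(np.ones((5, 3)), p, np.ones((3, 2)))
        with pytest.raises(ValueError, match="columns"):
            gcn_layer(np.ones((4, 3)), p, np.ones((9, 2)))


class TestEncode:
    def test_zero_weights_collapse_to_prior(self, rng):
        adj = _random_adjacency(5, rng)
        p = build_propagation(adj)
        w = EncoderWeights(np.zeros((4, 3)), np.zeros((3, 2)),
                           np.zeros((3, 2)))
        mu, ls = encode(rng.standard_normal((5, 4)), p, w)
        np.testing.assert_array_equal(mu, 0)
        np.testing.assert_array_equal(ls, 0)  # sigma = 1, the prior

    def test_inference_is_deterministic(self, rng):
        adj = _random_adjacency(5, rng)
        p = build_propagation(adj)
        w = init_encoder_weights(4, 6, 3, seed=0)
        X = rng.standard_normal((5, 4))
        a = encode(X, p, w, dropout_rate=0.5, training=False)
        b = encode(X, p, w, dropout_rate=0.5, training=False)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_matches_two_layer_composition_oracle(self, rng):
        # 5-node chain graph
        ids = [f"c{i}" for i in range(5)]
        edges = EdgeList([(ids[i], ids[i + 1], POSITIVE) for i in range(4)])
        adj = build_signed_adjacency(ids, edges)
        p = build_propagation(adj)
        w = init_encoder_weights(4, 6, 3, seed=1)
        X = rng.standard_normal((5, 4))
        mu, ls = encode(X, p, w)
        mu_o, ls_o = encoder_bruteforce(adj.matrix, X, w.w0, w.w1_mu,
                                        w.w1_sigma)
        np.testing.assert_allclose(mu, mu_o, atol=1e-6)
        np.testing.assert_allclose(ls, ls_o, atol=1e-6)

    @pytest.mark.parametrize("n", [3, 9, 20])
    def test_oracle_equivalence_random_graphs(self, n, rng):
        adj = _random_adjacency(n, rng)
        for mode in ("raw", "signed_sym_norm"):
            p = build_propagation(adj, mode)
            w = init_encoder_weights(5, 7, 4, seed=n)
            X = rng.standard_normal((n, 5))
            mu, ls = encode(X, p, w)
            mu_o, ls_o = encoder_bruteforce(p.matrix, X, w.w0, w.w1_mu,
                                            w.w1_sigma)
            np.testing.assert_allclose(mu, mu_o, atol=1e-6)
            np.testing.assert_allclose(ls, ls_o, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        adj = _random_adjacency(7, rng)
        w = init_encoder_weights(4, 5, 3, seed=2)
        X = rng.standard_normal((7, 4))
        mu, _ = encode(X, build_propagation(adj), w)
        perm = rng.permutation(7)
        adj_p = SignedAdjacency(matrix=adj.matrix[np.ix_(perm, perm)],
                                confidence_mask=adj.confidence_mask[
                                    np.ix_(perm, perm)],
                                node_index=[adj.node_index[i] for i in perm])
        mu_p, _ = encode(X[perm], build_propagation(adj_p), w)
        np.testing.assert_allclose(mu_p, mu[perm], atol=1e-10)

    def test_nonfinite_input_raises(self, rng):
        adj = _random_adjacency(4, rng)
        w = init_encoder_weights(3, 4, 2, seed=0)
        X = np.full((4, 3), np.inf)
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            encode(X, build_propagation(adj), w)


class TestReparameterize:
    def test_deterministic_limit(self):
        mu = np.array([[1.5, -2.0]])
        z = reparameterize(mu, np.full_like(mu, -30.0), seed=0)
        np.testing.assert_allclose(z, mu, atol=1e-12)

    def test_standard_normal_moments(self):
        z = reparameterize(np.zeros((100_000, 1)), np.zeros((100_000, 1)),
                           seed=3)
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05

    def test_same_seed_identical(self, rng):
        mu = rng.standard_normal((10, 4))
        ls = rng.standard_normal((10, 4)) * 0.1
        np.testing.assert_array_equal(reparameterize(mu, ls, seed=5),
                                      reparameterize(mu, ls, seed=5))


class TestDecoder:
    def test_zero_vector_gives_half(self, rng):
        assert decode_pair(np.zeros(4), rng.standard_normal(4)) == 0.5

    def test_closed_form_sigmoid(self):
        # z_i = z_j = [1, 1] -> sigma(2)
        assert decode_pair(np.ones(2), np.ones(2)) == \
            pytest.approx(0.8807970779778823, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal(6), rng.standard_normal(6)
            assert decode_pair(a, b) == pytest.approx(decode_pair(b, a))


class TestKL:
    def test_prior_equals_posterior(self):
        assert kl_term(np.zeros((4, 3)), np.zeros((4, 3))) == 0.0

    def test_nonnegative(self, rng):
        for _ in range(20):
            mu = rng.uniform(-2, 2, (5, 3))
            ls = rng.uniform(-1, 1, (5, 3))
            assert kl_term(mu, ls) >= 0.0

    def test_closed_form_single_unit(self):
        assert kl_term(np.array([[1.0]]), np.array([[0.0]])) == \
            pytest.approx(0.5)

    def test_matches_monte_carlo(self, rng):
        mu = rng.uniform(-1, 1, (2, 3))
        ls = rng.uniform(-1, 1, (2, 3))
        exact = kl_term(mu, ls)
        mc = kl_montecarlo(mu, ls, n_samples=100_000, seed=7)
        assert abs(mc - exact) / exact < 0.02


class TestReconstruction:
    def test_empty_mask_is_error(self):
        adj = build_signed_adjacency(["a", "b"], EdgeList([]))
        with pytest.raises(ValueError, match="mask"):
            reconstruction_term(np.zeros((2, 3)), adj)

    def test_single_positive_cell_at_half_gives_ln2(self):
        # orthogonal latents -> logit 0 -> probability .5 -> BCE = ln 2
        adj = build_signed_adjacency(["a", "b"],
                                     EdgeList([("a", "b", POSITIVE)]))
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert reconstruction_term(Z, adj, pos_weight=1.0) == \
            pytest.approx(np.log(2.0))

    def test_balanced_weight_reduces_to_one_when_classes_balanced(self, rng):
        ids = ["a", "b", "c", "d"]
        edges = EdgeList([("a", "b", POSITIVE), ("c", "d", HIGH_NEGATIVE)])
        adj = build_signed_adjacency(ids, edges)
        Z = rng.standard_normal((4, 3))
        assert reconstruction_term(Z, adj, pos_weight="balanced") == \
            pytest.approx(reconstruction_term(Z, adj, pos_weight=1.0))

    def test_unmasked_nodes_do_not_contribute(self, rng):
        ids = ["a", "b", "c", "d"]
        adj = build_signed_adjacency(ids, EdgeList([("a", "b", POSITIVE)]))
        Z = rng.standard_normal((4, 3))
        base = reconstruction_term(Z, adj, pos_weight=1.0)
        Z2 = Z.copy()
        Z2[2:] += rng.standard_normal((2, 3))  # c, d untouched by the mask
        assert reconstruction_term(Z2, adj, pos_weight=1.0) == \
            pytest.approx(base)


def _two_block_dataset(n_per_block=15, seed=0):
    """Within-block +1 edges, cross-block -1 edges, block-informative
    features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    ids = [f"p{i}" for i in range(n)]
    block = np.array([0] * n_per_block + [1] * n_per_block)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if block[i] == block[j]:
                if rng.random() < 0.5:
                    pairs.append((ids[i], ids[j], POSITIVE))
            elif rng.random() < 0.3:
                pairs.append((ids[i], ids[j], HIGH_NEGATIVE))
    X = rng.standard_normal((n, 8)) * 0.3
    X[:, 0] += np.where(block == 0, 1.0, -1.0)
    return ids, EdgeList(pairs), X, block


class TestTraining:
    def test_zero_epochs_is_noop(self, rng):
        ids, edges, X, _ = _two_block_dataset()
        adj = build_signed_adjacency(ids, edges)
        cfg = RunConfig(seed=0, epochs=0, hidden1=8, embed_dim=4)
        w, emb, reports = train_svgae(X, adj, cfg)
        w0 = init_encoder_weights(X.shape[1], 8, 4,
                                  seed=cfg.stage_seed("svgae-init"))
        np.testing.assert_array_equal(w.w0, w0.w0)
        assert reports == []

    @pytest.mark.parametrize("mode", ["raw", "signed_sym_norm"])
    def test_loss_decreases_over_training(self, mode):
        descents = 0
        for seed in range(5):
            ids, edges, X, _ = _two_block_dataset(seed=seed)
            adj = build_signed_adjacency(ids, edges)
            cfg = RunConfig(seed=seed, hidden1=16, embed_dim=8,
                            propagation_mode=mode)
            _, _, reports = train_svgae(X, adj, cfg)
            if reports[-1].total < reports[0].total:
                descents += 1
        assert descents >= 4

    def test_deterministic_given_seed(self):
        ids, edges, X, _ = _two_block_dataset()
        adj = build_signed_adjacency(ids, edges)
        cfg = RunConfig(seed=3, hidden1=8, embed_dim=4)
        w1, e1, r1 = train_svgae(X, adj, cfg)
        w2, e2, r2 = train_svgae(X, adj, cfg)
        np.testing.assert_array_equal(w1.w0, w2.w0)
        np.testing.assert_array_equal(e1.mu, e2.mu)
        assert [r.total for r in r1] == [r.total for r in r2]

    def test_loss_report_identity(self):
        ids, edges, X, _ = _two_block_dataset()
        adj = build_signed_adjacency(ids, edges)
        cfg = RunConfig(seed=1, hidden1=8, embed_dim=4, epochs=5)
        _, _, reports = train_svgae(X, adj, cfg)
        for r in reports:
            assert r.kl >= 0
            assert r.total == pytest.approx(r.reconstruction + r.kl)

    def test_empty_mask_rejected(self):
        adj = build_signed_adjacency(["a", "b"], EdgeList([]))
        with pytest.raises(ValueError, match="mask"):
            train_svgae(np.zeros((2, 3)), adj, RunConfig(seed=0))


class TestLinkPredictionQuality:
    def test_heldout_auc_and_sign_ablation(self):
        """Held-out decoding on mu separates within-block from cross-block
        pairs (AUC >= 0.9); flattening signs with a full mask must not beat
        the signed model by more than noise."""
        rng = np.random.default_rng(42)
        ids, edges, X, block = _two_block_dataset(n_per_block=20, seed=42)
        # hold out 20% of labelled pairs
        pairs = list(edges)
        idx = rng.permutation(len(pairs))
        n_test = len(pairs) // 5
        test = [pairs[i] for i in idx[:n_test]]
        train = EdgeList([pairs[i] for i in idx[n_test:]])
        cfg = RunConfig(seed=42, hidden1=24, embed_dim=8)
        index = {pid: k for k, pid in enumerate(ids)}

        def heldout_auc(adj):
            _, emb, _ = train_svgae(X, adj, cfg)
            scores = [decode_pair(emb.mu[index[a]], emb.mu[index[b]])
                      for a, b, _ in test]
            truth = [1 if lab == POSITIVE else 0 for _, _, lab in test]
            return roc_auc_score(truth, scores)

        signed_adj = build_signed_adjacency(ids, train)
        auc_signed = heldout_auc(signed_adj)
        unsigned_adj = signed_adj.unsigned()
        unsigned_adj.confidence_mask = ~np.eye(len(ids), dtype=bool)
        auc_unsigned = heldout_auc(unsigned_adj)

        assert auc_signed >= 0.9
        assert auc_unsigned <= auc_signed + 0.05
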