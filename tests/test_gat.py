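import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import softmax

from sentistack import GATClassifier, reply_graph_adjacency
from sentistack.gat import (
    GATParams,
    _edge_arrays,
    _elu,
    _forward,
    _loss_and_grads,
    attention_logits,
    gat_forward,
    gat_loss,
    normalize_attention,
)
from sentistack.simulate import NON_NEGATIVE, SimulationConfig, generate_corpus, embedding_matrix


def _random_params(rng, K=2, D=3, Dp=2):
    return GATParams(
        M=rng.standard_normal((K, D, Dp)),
        a=rng.standard_normal((K, 2 * Dp)),
        W=rng.standard_normal((K * Dp, 2)),
        b=rng.standard_normal(2),
    )


def _chain_adjacency(n):
    edges = np.column_stack([np.arange(1, n), np.arange(n - 1)])
    return reply_graph_adjacency(edges, n)


class TestAttentionLogits:
    def test_zero_attention_vector(self, rng):
        H = rng.standard_normal((4, 3))
        e = attention_logits(H, rng.standard_normal((3, 2)), np.zeros(4), [[0, 1], [1, 0]])
        np.testing.assert_array_equal(e, 0.0)

    def test_zero_embeddings(self, rng):
        e = attention_logits(np.zeros((3, 2)), rng.standard_normal((2, 2)),
                             rng.standard_normal(4), [[0, 1], [2, 1]])
        np.testing.assert_array_equal(e, 0.0)

    def test_two_node_hand_computation(self):
        # h0 = [1,-1], h1 = [2,0.5], M = [[1,0],[1,1]]  =>  p0 = [0,-1], p1 = [2.5,0.5]
        # a_src = [0.3,-0.2], a_dst = [0.5,0.1]
        # s = [0.2, 0.65], t = [-0.1, 1.3]
        # e_01 = LeakyReLU(0.2+1.3) = 1.5 ; e_10 = LeakyReLU(0.65-0.1) = 0.55
        H = np.array([[1.0, -1.0], [2.0, 0.5]])
        M = np.array([[1.0, 0.0], [1.0, 1.0]])
        a = np.array([0.3, -0.2, 0.5, 0.1])
        e = attention_logits(H, M, a, [[0, 1], [1, 0]])
        np.testing.assert_allclose(e, [1.5, 0.55])
        # asymmetric by construction
        assert e[0] != e[1]

    def test_negative_logit_gets_leaky_slope(self):
        H = np.array([[1.0], [1.0]])
        M = np.array([[1.0]])
        a = np.array([-1.0, 0.0])  # raw = -1 -> LeakyReLU -> -0.2
        e = attention_logits(H, M, a, [[0, 1]], slope=0.2)
        np.testing.assert_allclose(e, [-0.2])


class TestNormalizeAttention:
    def test_rows_sum_to_one(self, rng):
        A = _chain_adjacency(8)
        rows, cols, indptr = _edge_arrays(A)
        e = rng.standard_normal(rows.size)
        alpha = normalize_attention(e, rows, indptr)
        sums = np.add.reduceat(alpha, indptr[:-1])
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_single_neighbor_gets_weight_one(self):
        A = sp.identity(3, format="csr")
        rows, cols, indptr = _edge_arrays(A)
        alpha = normalize_attention(np.array([2.0, -1.0, 0.3]), rows, indptr)
        np.testing.assert_allclose(alpha, 1.0)

    def test_uniform_logits_give_uniform_weights(self):
        A = _chain_adjacency(3)
        rows, cols, indptr = _edge_arrays(A)
        alpha = normalize_attention(np.zeros(rows.size), rows, indptr)
        expected = 1.0 / np.diff(indptr)
        np.testing.assert_allclose(alpha, expected[rows])

    def test_shift_invariance(self, rng):
        A = _chain_adjacency(5)
        rows, cols, indptr = _edge_arrays(A)
        e = rng.standard_normal(rows.size)
        a1 = normalize_attention(e, rows, indptr)
        a2 = normalize_attention(e + 7.3, rows, indptr)
        np.testing.assert_allclose(a1, a2, atol=1e-12)


class TestForward:
    def test_output_width(self, rng):
        params = _random_params(rng, K=3, D=4, Dp=5)
        H = rng.standard_normal((6, 4))
        Z = gat_forward(_chain_adjacency(6), H, params)
        assert Z.shape == (6, 15)

    def test_self_loop_identity_reproduces_embedding(self, rng):
        # lone node, M = I, identity activation => z_i = h_i repeated per head
        D = 3
        H = rng.standard_normal((4, D))
        params = GATParams(
            M=np.stack([np.eye(D)] * 2),
            a=rng.standard_normal((2, 2 * D)),
            W=np.zeros((2 * D, 2)),
            b=np.zeros(2),
        )
        Z = gat_forward(sp.identity(4, format="csr"), H, params, activation="identity")
        np.testing.assert_allclose(Z, np.hstack([H, H]), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        params = _random_params(rng)
        H = rng.standard_normal((6, 3))
        A = _chain_adjacency(6).toarray()
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        Z1 = gat_forward(sp.csr_matrix(A), H, params)
        Z2 = gat_forward(sp.csr_matrix(P @ A @ P.T), H[perm], params)
        np.testing.assert_allclose(Z1[perm], Z2, atol=1e-10)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        assert gat_loss(probs, y, neg_weight=2.0, l2=0.0) == pytest.approx(0.0, abs=1e-10)

    def test_unit_weight_reduces_to_mean_nll(self, rng):
        probs = softmax(rng.standard_normal((5, 2)), axis=1)
        y = np.array([0, 1, 1, 0, 1])
        expected = -np.mean(np.log(probs[np.arange(5), y]))
        assert gat_loss(probs, y, neg_weight=1.0, l2=0.0) == pytest.approx(expected)

    def test_hand_substitution_one_of_each_class(self):
        # one Negative + one non-Negative both predicted at p, r=2:
        # loss = -(1+2)^(-1) (log p + 2 log p) = -log p
        p = 0.3
        probs = np.array([[1 - p, p], [p, 1 - p]])  # true classes below
        y = np.array([1, 0])
        assert gat_loss(probs, y, neg_weight=2.0, l2=0.0) == pytest.approx(-np.log(p))

    def test_unlabeled_nodes_do_not_contribute(self, rng):
        probs = softmax(rng.standard_normal((4, 2)), axis=1)
        full = gat_loss(probs[:2], np.array([0, 1]), 2.0, 0.0)
        with_unlabeled = gat_loss(probs, np.array([0, 1, -1, -1]), 2.0, 0.0)
        assert full == pytest.approx(with_unlabeled)


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Loss gradient on a 5-node graph agrees with central differences."""
        X = rng.standard_normal((5, 3))
        A = GATClassifier()._prepare_adjacency(
            reply_graph_adjacency(np.array([[1, 0], [2, 0], [4, 3]]), 5), 5
        )
        y = np.array([0, 1, -1, 1, -1])
        params = _random_params(rng)
        _, grads = _loss_and_grads(X, A, y, params, 2.0, 0.05, 0.2, "elu")

        eps = 1e-6
        for arr, g in zip(params.as_list(), grads.as_list()):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = _loss_and_grads(X, A, y, params, 2.0, 0.05, 0.2, "elu")[0]
                arr[ix] = orig - eps
                lm = _loss_and_grads(X, A, y, params, 2.0, 0.05, 0.2, "elu")[0]
                arr[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[ix] == pytest.approx(fd, abs=1e-5, rel=1e-4)


class TestTraining:
    def test_loss_decreases_and_seed_determinism(self, small_corpus):
        corpus, edges, _ = small_corpus
        X = embedding_matrix(corpus)[:400]
        y = np.where(
            corpus["observed_label"].isna(),
            -1, (corpus["observed_label"] == NON_NEGATIVE).astype(int),
        ).astype(int)[:400]
        clf1 = GATClassifier(n_epochs=80, random_state=0).fit(X, y)
        clf2 = GATClassifier(n_epochs=80, random_state=0).fit(X, y)
        assert clf1.loss_history_[-1] <= clf1.loss_history_[0]
        np.testing.assert_array_equal(clf1.params_.M, clf2.params_.M)
        np.testing.assert_array_equal(clf1.params_.W, clf2.params_.W)

    def test_separable_corpus_high_training_accuracy(self):
        # separable embeddings AND thread-clustered sentiment, so neighbor
        # aggregation reinforces rather than dilutes the per-node signal
        cfg = SimulationConfig(
            messages_per_cell=120, class_separation=4.0, label_fraction=0.5,
            thread_persistence=0.9, root_fraction=0.1, seed=7,
        )
        corpus, edges, _ = generate_corpus(cfg)
        X = embedding_matrix(corpus)
        index_of = {m: i for i, m in enumerate(corpus["message_id"])}
        edge_idx = np.array(
            [[index_of[c], index_of[p]] for c, p in zip(edges["child_id"], edges["parent_id"])]
        )
        A = reply_graph_adjacency(edge_idx, len(corpus))
        labeled = corpus["observed_label"].notna().to_numpy()
        y = np.where(labeled, (corpus["observed_label"] == NON_NEGATIVE).astype(int), -1)
        clf = GATClassifier(n_epochs=200, random_state=1).fit(X, y, adjacency=A)
        pred = clf.predict(X, adjacency=A)
        acc = np.mean(pred[labeled] == y[labeled])
        assert acc >= 0.95

    def test_self_loop_only_equals_mlp(self, rng):
        """Without edges the GAT collapses to a per-node MLP on the embeddings."""
        X = rng.standard_normal((40, 4))
        y = (X[:, 0] > 0).astype(int)
        clf = GATClassifier(n_heads=2, head_dim=3, n_epochs=50, random_state=2).fit(X, y)
        p_gat = clf.predict_proba(X)
        # oracle: identical parameters pushed through the dense per-node formula
        prm = clf.params_
        Z = np.hstack([_elu(X @ prm.M[k]) for k in range(2)])
        p_mlp = softmax(Z @ prm.W + prm.b, axis=1)
        np.testing.assert_allclose(p_gat, p_mlp, atol=1e-12)

    def test_probabilities_normalized(self, rng):
        X = rng.standard_normal((30, 3))
        y = (X[:, 0] > 0).astype(int)
        clf = GATClassifier(n_epochs=30, random_state=3).fit(X, y)
        p = clf.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((p >= 0) & (p <= 1))

    def test_labels_validation(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            GATClassifier().fit(X, np.array([0, 1, 2, 0, 1]))
        with pytest.raises(ValueError):
            GATClassifier().fit(X, np.full(5, -1))


class TestGraphValue:
    def test_gat_beats_head_when_sentiment_clusters_in_threads(self):
        """With weak embeddings but thread-correlated sentiment, the reply
        graph carries signal the per-message head cannot see (3-seed median)."""
        from sentistack import EmbeddingHeadClassifier

        diffs = []
        for seed in (0, 1, 2):
            cfg = SimulationConfig(
                messages_per_cell=150, class_separation=1.5, label_fraction=0.5,
                thread_persistence=0.95, root_fraction=0.1, seed=seed,
            )
            corpus, edges, _ = generate_corpus(cfg)
            X = embedding_matrix(corpus)
            index_of = {m: i for i, m in enumerate(corpus["message_id"])}
            edge_idx = np.array(
                [[index_of[c], index_of[p]] for c, p in zip(edges["child_id"], edges["parent_id"])]
            )
            A = reply_graph_adjacency(edge_idx, len(corpus))
            labeled = np.flatnonzero(corpus["observed_label"].notna())
            rng = np.random.default_rng(seed)
            train = rng.choice(labeled, size=len(labeled) // 2, replace=False)
            test = np.setdiff1d(labeled, train)
            y_true = (corpus["true_sentiment"] == NON_NEGATIVE).astype(int).to_numpy()
            y_semi = np.full(len(corpus), -1)
            y_semi[train] = y_true[train]
            gat = GATClassifier(n_epochs=200, random_state=seed).fit(X, y_semi, adjacency=A)
            head = EmbeddingHeadClassifier().fit(X[train], y_true[train])
            acc_gat = np.mean(gat.predict(X, adjacency=A)[test] == y_true[test])
            acc_head = np.mean(head.predict(X[test]) == y_true[test])
            diffs.append(acc_gat - acc_head)
        assert np.median(diffs) >= 0
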