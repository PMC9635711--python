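"""Graph attention network for semi-supervised sentiment classification.

One multi-head attention layer over the message reply graph followed by a
dense softmax head, trained with a class-weighted, l2-regularized
cross-entropy on the labelled nodes only.  Unlabelled messages contribute
their embeddings and edges to every forward pass, which is what makes the
training semi-supervised.

The network is small enough that it is implemented directly in numpy with
analytic gradients and a hand-rolled Adam optimizer; the gradients are
checked against finite differences in the test suite.

Model, per attention head k with transformation ``M_k`` and attention vector
``a_k = [a_src | a_dst]``::

    e_ij = LeakyReLU(a_src . M_k h_i + a_dst . M_k h_j)   for j in N(i)
    alpha_ij = softmax_{j in N(i)}(e_ij)
    z_i = concat_k sigma( sum_j alpha_ij M_k h_j )        sigma = ELU

followed by ``softmax(W z_i + b)``.  The neighborhood N(i) comes from the
symmetric reply adjacency with self-loops added, so isolated messages fall
back to a plain per-node transformation of their own embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import softmax as dense_softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "reply_graph_adjacency",
    "attention_logits",
    "normalize_attention",
    "gat_forward",
    "gat_loss",
    "GATParams",
    "GATClassifier",
]

UNLABELED = -1


def reply_graph_adjacency(edges, n_nodes: int) -> sp.csr_matrix:
    """Symmetric binary adjacency with self-loops from a (child, parent) edge list."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n_nodes)])
    cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n_nodes)])
    A = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes))
    A.data[:] = 1.0
    return A


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))

_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class GATParams:
    """All trainable parameters: attention stage (M, a) plus output head (W, b).

    ``M`` has shape (K, D, head_dim); ``a`` (K, 2*head_dim) stores
    ``[a_src | a_dst]`` per head; ``W`` (K*head_dim, 2); ``b`` (2,).
    """

    M: np.ndarray
    a: np.ndarray
    W: np.ndarray
    b: np.ndarray

    def as_list(self):
        return [self.M, self.a, self.W, self.b]

    def sq_norm(self) -> float:
        return float(sum(np.sum(p * p) for p in self.as_list()))


def _edge_arrays(A: sp.csr_matrix):
    """CSR edge arrays: row index per edge, column index per edge, row pointer."""
    A = sp.csr_matrix(A)
    A.sort_indices()
    rows = np.repeat(np.arange(A.shape[0]), np.diff(A.indptr))
    return rows, A.indices, A.indptr


def attention_logits(H, M, a, edges, *, slope: float = 0.2) -> np.ndarray:
    """Raw attention scores e_ij for the given (i, j) edge pairs, one head.

    ``a`` is the concatenated attention vector ``[a_src | a_dst]``; the score
    is LeakyReLU(a . [M h_i || M h_j]).  Generally e_ij != e_ji because the
    source and destination halves of ``a`` differ.
    """
    H = np.asarray(H, dtype=float)
    M = np.asarray(M, dtype=float)
    a = np.asarray(a, dtype=float)
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    P = H @ M
    d = P.shape[1]
    s = P @ a[:d]
    t = P @ a[d:]
    return _leaky_relu(s[edges[:, 0]] + t[edges[:, 1]], slope)


def normalize_attention(e: np.ndarray, rows: np.ndarray, indptr: np.ndarray) -> np.ndarray:
    """Softmax of edge scores within each node's neighborhood (CSR segments)."""
    e = np.asarray(e, dtype=float)
    seg_max = np.maximum.reduceat(e, indptr[:-1])
    ex = np.exp(e - seg_max[rows])
    seg_sum = np.add.reduceat(ex, indptr[:-1])
    return ex / seg_sum[rows]


def _forward(X, A, params: GATParams, slope: float, activation: str):
    """Full forward pass; returns (probs, Z, cache-per-head)."""
    act, _ = _ACTIVATIONS[activation]
    rows, cols, indptr = _edge_arrays(A)
    K, D, Dp = params.M.shape
    caches = []
    Vs = []
    for k in range(K):
        P = X @ params.M[k]
        s = P @ params.a[k, :Dp]
        t = P @ params.a[k, Dp:]
        raw = s[rows] + t[cols]
        e = _leaky_relu(raw, slope)
        alpha = normalize_attention(e, rows, indptr)
        Aw = sp.csr_matrix((alpha, cols, indptr), shape=A.shape)
        U = Aw @ P
        Vs.append(act(U))
        caches.append((P, raw, alpha, U))
    Z = np.hstack(Vs)
    probs = dense_softmax(Z @ params.W + params.b, axis=1)
    return probs, Z, (rows, cols, indptr, caches)


def gat_forward(A, H, params: GATParams, *, slope: float = 0.2, activation: str = "elu") -> np.ndarray:
    """Node representations z_i: concatenated per-head attention aggregates."""
    _, Z, _ = _forward(np.asarray(H, dtype=float), A, params, slope, activation)
    return Z


def gat_loss(probs, y, neg_weight: float, l2: float, params: GATParams | None = None) -> float:
    """Class-weighted cross-entropy on labelled nodes plus l2 penalty.

    ``y`` uses 0 = Negative, 1 = non-Negative, -1 = unlabelled.  Negative
    cases are up-weighted by ``neg_weight`` (r), and the sum is normalized by
    (#non-Negative + r * #Negative), so with r = 1 this is the ordinary mean
    negative log-likelihood over the labelled set.
    """
    y = np.asarray(y)
    labeled = y != UNLABELED
    if not labeled.any():
        raise ValueError("no labelled nodes")
    yl = y[labeled]
    pl = np.asarray(probs)[labeled]
    w = np.where(yl == 0, neg_weight, 1.0)
    norm = w.sum()
    ce = -np.sum(w * np.log(np.clip(pl[np.arange(yl.size), yl], 1e-300, None))) / norm
    pen = l2 * params.sq_norm() if params is not None else 0.0
    return float(ce + pen)


def _loss_and_grads(X, A, y, params: GATParams, neg_weight, l2, slope, activation):
    _, act_grad = _ACTIVATIONS[activation]
    probs, Z, (rows, cols, indptr, caches) = _forward(X, A, params, slope, activation)
    K, D, Dp = params.M.shape
    N = X.shape[0]

    y = np.asarray(y)
    labeled = np.flatnonzero(y != UNLABELED)
    yl = y[labeled]
    w = np.where(yl == 0, neg_weight, 1.0)
    norm = w.sum()
    loss = gat_loss(probs, y, neg_weight, l2, params)

    G = np.zeros_like(probs)
    G[labeled] = probs[labeled]
    G[labeled, yl] -= 1.0
    G[labeled] *= (w / norm)[:, None]

    dW = Z.T @ G + 2 * l2 * params.W
    db = G.sum(axis=0) + 2 * l2 * params.b
    dZ = G @ params.W.T

    dM = np.empty_like(params.M)
    da = np.empty_like(params.a)
    for k in range(K):
        P, raw, alpha, U = caches[k]
        dU = dZ[:, k * Dp:(k + 1) * Dp] * act_grad(U)
        # aggregation U[i] = sum_j alpha_ij P[j]
        dalpha = np.einsum("ed,ed->e", dU[rows], P[cols])
        dP = sp.csr_matrix((alpha, cols, indptr), shape=A.shape).T @ dU
        # neighborhood-softmax backward
        inner = np.add.reduceat(alpha * dalpha, indptr[:-1])
        de = alpha * (dalpha - inner[rows])
        draw = de * _leaky_relu_grad(raw, slope)
        ds = np.bincount(rows, weights=draw, minlength=N)
        dt = np.bincount(cols, weights=draw, minlength=N)
        da[k, :Dp] = P.T @ ds
        da[k, Dp:] = P.T @ dt
        dP += ds[:, None] * params.a[k, :Dp] + dt[:, None] * params.a[k, Dp:]
        dM[k] = X.T @ dP + 2 * l2 * params.M[k]
    da += 2 * l2 * params.a
    return loss, GATParams(dM, da, dW, db)


class GATClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised graph-attention sentiment classifier.

    Parameters mirror the study configuration: ``n_heads`` K = 4,
    ``neg_weight`` r = 2 (the Negative class is up-weighted against the
    roughly 6:1 labelled imbalance), ``l2`` lambda = 0.08, Adam with learning
    rate 0.02.  ``head_dim`` (per-head output width) and the epoch budget are
    not pinned down by the study and default to 8 and 300.

    ``fit(X, y, adjacency=A)`` takes integer labels with 0 = Negative,
    1 = non-Negative and -1 = unlabelled (the semi-supervised convention of
    ``sklearn.semi_supervised``); all rows of ``X`` participate in message
    passing, only labelled rows enter the loss.  ``adjacency`` may be any
    (sparse) matrix; it is symmetrized, binarized and given self-loops.
    With ``adjacency=None`` only self-loops remain and the model reduces to
    a per-node MLP on the embeddings.
    """

    def __init__(
        self,
        n_heads: int = 4,
        head_dim: int = 8,
        neg_weight: float = 2.0,
        l2: float = 0.08,
        learning_rate: float = 0.02,
        n_epochs: int = 300,
        leaky_slope: float = 0.2,
        activation: str = "elu",
        random_state: int | None = None,
    ):
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.neg_weight = neg_weight
        self.l2 = l2
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.leaky_slope = leaky_slope
        self.activation = activation
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _init_params(self, D: int, rng: np.random.Generator) -> GATParams:
        K, Dp = self.n_heads, self.head_dim

        def glorot(*shape):
            fan = shape[-2] + shape[-1] if len(shape) > 1 else shape[-1]
            lim = np.sqrt(6.0 / fan)
            return rng.uniform(-lim, lim, size=shape)

        return GATParams(
            M=glorot(K, D, Dp),
            a=glorot(K, 2 * Dp) * 0.1,
            W=glorot(K * Dp, 2),
            b=np.zeros(2),
        )

    def _prepare_adjacency(self, A, n: int) -> sp.csr_matrix:
        if A is None:
            return sp.identity(n, format="csr")
        A = sp.csr_matrix(A)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} nodes")
        A = A.maximum(A.T) + sp.identity(n, format="csr")
        A.data[:] = 1.0
        return A

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, adjacency=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different lengths")
        if not set(np.unique(y)) <= {UNLABELED, 0, 1}:
            raise ValueError("labels must be 0, 1 or -1 (unlabelled)")
        if not np.any(y != UNLABELED):
            raise ValueError("at least one labelled node is required")
        A = self._prepare_adjacency(adjacency, X.shape[0])

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(X.shape[1], rng)

        # Adam state
        m = [np.zeros_like(p) for p in params.as_list()]
        v = [np.zeros_like(p) for p in params.as_list()]
        b1, b2, eps = 0.9, 0.999, 1e-8
        history = []
        for t in range(1, self.n_epochs + 1):
            loss, grads = _loss_and_grads(
                X, A, y, params, self.neg_weight, self.l2,
                self.leaky_slope, self.activation,
            )
            history.append(loss)
            plist, glist = params.as_list(), grads.as_list()
            for i, (p, g) in enumerate(zip(plist, glist)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mhat = m[i] / (1 - b1**t)
                vhat = v[i] / (1 - b2**t)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(
            _loss_and_grads(
                X, A, y, params, self.neg_weight, self.l2,
                self.leaky_slope, self.activation,
            )[0]
        )
        self.params_ = params
        self.loss_history_ = np.asarray(history)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X, adjacency=None) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        A = self._prepare_adjacency(adjacency, X.shape[0])
        probs, _, _ = _forward(X, A, self.params_, self.leaky_slope, self.activation)
        return probs

    def predict(self, X, adjacency=None) -> np.ndarray:
        return (self.predict_proba(X, adjacency)[:, 1] >= 0.5).astype(int)
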