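"""Text featurization and the softmax classification head (first base model).

The study architecture feeds message embeddings from a large pretrained
sentiment transformer into a softmax classification layer.  Here the
embedding step is a pluggable provider: a deterministic hashed-token
featurizer with a polarity-lexicon channel (always available, pure function
of the text) or precomputed embeddings from any external transformer.  The
head itself is an l2-penalized multinomial logistic layer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "POSITIVE_WORDS",
    "NEGATIVE_WORDS",
    "HashedTextFeaturizer",
    "EmbeddingHeadClassifier",
    "embed",
    "predict_head",
]

# small polarity lexicon; enough to give synthetic/toy text a signal channel
POSITIVE_WORDS = frozenset(
    """good great love happy excited awesome amazing thanks helpful fun
    best nice glad excellent enjoy wonderful cool win won congrats""".split()
)
NEGATIVE_WORDS = frozenset(
    """bad sad hate angry terrible awful worst stress stressed anxious
    depressed lonely fail failed sick tired worried scared cancel cancelled
    pandemic lockdown quarantine""".split()
)


class HashedTextFeaturizer(TransformerMixin, BaseEstimator):
    """Deterministic bag-of-words features: hashed token counts + polarity.

    Output has ``n_features`` hashed-count columns plus one channel with the
    difference between positive- and negative-lexicon word counts.  A pure
    function of each text string — no fitting, no vocabulary state — so rows
    for identical texts are identical and the empty string maps to the zero
    vector.
    """

    def __init__(self, n_features: int = 63):
        self.n_features = n_features

    def fit(self, X, y=None):
        return self

    def transform(self, texts) -> np.ndarray:
        hv = HashingVectorizer(
            n_features=self.n_features, alternate_sign=False, norm=None
        )
        counts = np.asarray(hv.transform(texts).todense(), dtype=float)
        polarity = np.array(
            [
                sum(w in POSITIVE_WORDS for w in str(t).lower().split())
                - sum(w in NEGATIVE_WORDS for w in str(t).lower().split())
                for t in texts
            ],
            dtype=float,
        )
        return np.hstack([counts, polarity[:, None]])


def embed(texts, provider: str = "featurizer", n_features: int = 63) -> np.ndarray:
    """Embed texts with the named provider.

    ``featurizer`` is the built-in deterministic provider.  Any other name is
    treated as an external transformer backend, which this package does not
    ship; the error points at the two supported routes (the featurizer or a
    precomputed-embedding file).
    """
    if provider == "featurizer":
        return HashedTextFeaturizer(n_features=n_features).transform(texts)
    raise ValueError(
        f"embedding provider {provider!r} is not available; use "
        "provider='featurizer' or supply precomputed embeddings"
    )


class EmbeddingHeadClassifier(ClassifierMixin, BaseEstimator):
    """Softmax classification layer on fixed embeddings.

    Maximizes the l2-penalized multinomial log-likelihood (lbfgs); this is
    the trained classification layer of the first base model.  ``classes_``
    follows sklearn convention; for sentiment use y=0 for Negative and y=1
    for non-Negative so that ``predict_proba(...)[:, 1]`` is the probability
    of non-Negative.
    """

    def __init__(self, l2_strength: float = 1.0, max_iter: int = 1000, random_state=None):
        self.l2_strength = l2_strength
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        self._lr = LogisticRegression(
            C=1.0 / self.l2_strength,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        self._lr.fit(X, y)
        self.classes_ = self._lr.classes_
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return self._lr.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return self._lr.predict(np.asarray(X, dtype=float))


def predict_head(embeddings: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Softmax-head probabilities from explicit parameters.

    ``weights`` is (D, 2), ``bias`` (2,); returns (n, 2) class probabilities.
    With all-zero parameters every probability is 0.5.  Exposed separately so
    head parameters can be inspected, serialized, or set by hand.
    """
    H = np.asarray(embeddings, dtype=float)
    W = np.asarray(weights, dtype=float)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"embedding dim {H.shape[1]} != weight rows {W.shape[0]}")
    return softmax(H @ W + np.asarray(bias, dtype=float), axis=1)
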