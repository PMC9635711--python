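"""Model stacking: cutoff optimization, probability rescaling, meta-model.

The two base classifiers output a probability p of non-Negative sentiment
per message.  Each gets its own decision cutoff c, chosen on the stacking
training split by maximizing the geometric mean of sensitivity (recall on
the non-Negative class) and positive predictive value.  Raw probabilities
are then rescaled so both classifiers share the cutoff 0.5::

    p' = 0.5 * (p - c) / (1 - c) + 0.5

(an affine map sending c -> 0.5 and 1 -> 1; not clamped, since p' is a
regression covariate, not a probability), and a per-school-year logistic
meta-model on (p'1, p'2) produces the final probability, thresholded at 0.5
with ties going to non-Negative.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "gmean_at_cutoff",
    "optimal_cutoff",
    "scale_probability",
    "StackedSentimentClassifier",
]


def gmean_at_cutoff(probs: np.ndarray, y: np.ndarray, c: float) -> float:
    """G-mean of recall and precision at cutoff c (positive = non-Negative).

    Messages with p < c are labelled Negative, otherwise non-Negative.
    Returns 0.0 when precision is undefined (nothing predicted positive).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    pred_pos = probs >= c
    tp = np.sum(pred_pos & (y == 1))
    if tp == 0:
        return 0.0
    recall = tp / np.sum(y == 1)
    precision = tp / np.sum(pred_pos)
    return float(np.sqrt(recall * precision))


def optimal_cutoff(probs: np.ndarray, y: np.ndarray) -> float:
    """ROC-style cutoff maximizing sqrt(recall x precision).

    Candidates are the midpoints between consecutive distinct sorted
    probabilities plus the endpoints 0 and 1, which makes the argmax
    well-defined; ties in G-mean break toward the smallest cutoff.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to optimize a cutoff")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    distinct = np.unique(probs)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    scores = np.array([gmean_at_cutoff(probs, y, c) for c in candidates])
    return float(candidates[np.argmax(scores)])  # argmax returns first (smallest c) on ties


def scale_probability(p, c: float):
    """Affine rescale so the classifier-specific cutoff c maps to 0.5.

    Fixed points: p = c -> 0.5 and p = 1 -> 1.  Strictly increasing in p and
    deliberately unclamped — for c > 0.5 small p map below 0.
    """
    if not 0 < c < 1:
        raise ValueError("cutoff must be strictly inside (0, 1)")
    p = np.asarray(p, dtype=float)
    out = 0.5 * (p - c) / (1.0 - c) + 0.5
    return float(out) if out.ndim == 0 else out


def _fit_logit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalized logistic fit; returns (intercept, coef...) as one vector."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable strata legitimately blow up coefs
        lr = LogisticRegression(penalty=None, max_iter=2000)
        lr.fit(X, y)
    return np.concatenate([lr.intercept_, lr.coef_.ravel()])


class StackedSentimentClassifier(ClassifierMixin, BaseEstimator):
    """Per-stratum logistic meta-model over two rescaled base probabilities.

    ``fit(X, y, strata=...)`` expects ``X`` with columns (p'1, p'2) already
    rescaled, binary ``y`` (1 = non-Negative) and a stratum key per row
    (school-year).  One unpenalized logistic model is fitted per stratum; a
    stratum with a single class or fewer than ``min_stratum_size`` rows falls
    back to the pooled model fitted on all rows (always available).  The
    final label is non-Negative iff the meta-probability is >= 0.5.
    """

    def __init__(self, min_stratum_size: int = 10):
        self.min_stratum_size = min_stratum_size

    def fit(self, X, y, strata=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        strata = np.zeros(len(y)) if strata is None else np.asarray(strata)
        self.pooled_coef_ = _fit_logit(X, y)
        self.coef_by_stratum_ = {}
        self.fallback_strata_ = []
        for s in np.unique(strata):
            mask = strata == s
            ys = y[mask]
            if mask.sum() < self.min_stratum_size or np.unique(ys).size < 2:
                self.fallback_strata_.append(s)
                continue
            self.coef_by_stratum_[s] = _fit_logit(X[mask], ys)
        self.classes_ = np.array([0, 1])
        return self

    def _coef_for(self, s) -> np.ndarray:
        return self.coef_by_stratum_.get(s, self.pooled_coef_)

    def predict_proba(self, X, strata=None) -> np.ndarray:
        check_is_fitted(self, "pooled_coef_")
        X = np.asarray(X, dtype=float)
        strata = np.zeros(len(X)) if strata is None else np.asarray(strata)
        eta = np.empty(len(X))
        for s in np.unique(strata):
            mask = strata == s
            beta = self._coef_for(s)
            eta[mask] = beta[0] + X[mask] @ beta[1:]
        p = expit(eta)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, strata=None) -> np.ndarray:
        return (self.predict_proba(X, strata)[:, 1] >= 0.5).astype(int)
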