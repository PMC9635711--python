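# Methods

## The pipeline in one paragraph

Each message carries an embedding (a stand-in for a pretrained transformer's
sentence representation) and sits in a reply forest inside one school-year
cell. Two base classifiers score every message with a probability of
non-Negative sentiment: a softmax head on the embeddings alone, and a
single-layer multi-head graph attention network (GAT) that also sees the
reply graph. Their probabilities are rescaled so each classifier's optimal
cutoff maps to 0.5 and combined by a per-school-year logistic meta-model.
The resulting Negative/non-Negative labels are aggregated to school-year
binomial counts and analyzed with a random-intercept logistic model to
estimate the pandemic-year and in-person-learning effects on the odds of
negative sentiment.

## Synthetic corpus generator

The generator (`sentistack.simulate`) emulates the statistical structure the
downstream analysis assumes, not the surface form of social-media text:

- **Design.** Eight schools on a full factorial of funding (private/public),
  location (small/large city) and in-person learning (yes/no); two years
  (2019, 2020). Balance (4/4 per factor) is what identifies the three fixed
  effects in the mixed model.
- **Threads.** Within each school-year cell, message 0 opens a thread; each
  later message is a new root with probability `root_fraction` (default 0.3
  — a free parameter, since the real thread-size distribution is unknown)
  and otherwise replies to a uniformly chosen earlier message in the same
  cell. This is the simplest process producing the observed reply-forest
  topology; cells are mutually disconnected, as in the real data.
- **Sentiment.** One normal random intercept per school (`sigma`, default
  0.26), then independent Bernoulli draws at the logistic probability
  implied by the school covariates and year. Default fixed effects
  (`b0 = 0.58`, `b_type = 0.24`, `b_location = −0.07`, `b_year = −0.23`, on
  the non-Negative logit scale) mirror the study-scale estimates: ~36%
  Negative overall and ~26% higher odds of Negative in 2020. With
  `thread_persistence > 0` a reply copies its parent's sentiment with that
  probability; this leaves marginal cell probabilities unchanged (parent and
  child share the same cell probability) but makes sentiment cluster within
  threads — the regime where the reply graph carries information. The
  default is 0 (conditionally independent messages), which is the cleanest
  setting for parameter-recovery experiments.
- **Embeddings.** Spherical unit-variance Gaussians per class with mean
  separation `class_separation` along the first axis (default 3.0, i.e. a
  Bayes-optimal linear accuracy of Φ(1.5) ≈ 0.93 — strong but imperfect,
  like a good pretrained sentiment model). Separation is deliberately a
  single dial: 0 makes classes unlearnable, 10 makes them separable.
- **Labels.** A per-cell stratified subsample of messages gets its true
  sentiment as an observed label. Defaults: `label_fraction = 0.2` of a
  1000-message cell, i.e. ~200 labels per school-year at a non-Negative :
  Negative ratio of 2.7 — the scale and imbalance of the study's manual
  labelling effort per cell. (The often-quoted 6:1 imbalance describes the
  one-school GAT training subset, not the labelled pool; at 6:1 the study's
  own 25+25 per-cell test and stacking splits would not fit.) Labelled
  splits are drawn without replacement and are disjoint by construction.

What the generator does **not** emulate: real text (the featurizer exists
for toy/text corpora, but embeddings are the operative input), user
identities and per-user correlation, vote counts, heterogeneous node/edge
types, and heavy-tailed cell sizes. Passing tests therefore demonstrate
correctness of the machinery and calibration of the inference under the
model's own assumptions — not classification accuracy on real Reddit data.

## GAT: choices the architecture leaves open

- **Self-loops** are added to the symmetric reply adjacency. Without them,
  isolated messages (most roots) would have empty neighborhoods and an
  undefined representation; with them, an edgeless graph reduces the GAT
  exactly to a per-node MLP (a limit the tests exploit as an oracle).
- **Aggregation activation** is ELU (the common GAT convention);
  configurable to identity for analytic checks.
- **Head width** `head_dim = 8` per head, K = 4 heads; the concatenated
  representation feeds a single dense softmax layer. One attention layer is
  enough because the graphs are shallow reply forests.
- **Penalty** is λ‖Θ‖² with λ = 0.08 over all parameters, with the
  class-weighted normalizer (|Y⁺| + r|Y⁻|)⁻¹ and r = 2.
- **Optimization**: full-batch Adam, learning rate 0.02, 300 epochs by
  default (the convergence budget is not pinned down externally; 300 epochs
  is past the loss plateau on corpora of the sizes used here and is logged
  in `loss_history_`). Initialization is seeded Glorot-uniform, with the
  attention vectors scaled down 10× so early attention is near-uniform.
- **Gradients** are analytic (hand-derived backpropagation through the
  neighborhood softmax) and are verified against central finite differences
  on a 5-node graph in the test suite.

The implementation is pure numpy. At the problem sizes this package targets
(10³–10⁴ nodes, D ≲ 10²) a full training run takes seconds.

## Embedding head

`EmbeddingHeadClassifier` maximizes the l2-penalized multinomial
log-likelihood (lbfgs). When an external 3-class sentiment transformer is
used as the embedding provider, its output can either feed this retrained
binary head, or be collapsed directly via
p(non-Negative) = p(neutral) + p(positive); both routes are supported
because the correct mapping is not externally determined.

## Stacking

- **Cutoff candidates** are midpoints between consecutive distinct sorted
  probabilities plus the endpoints {0, 1}; ties in the G-mean break toward
  the smallest cutoff. This makes the argmax well-defined where "a point on
  the ROC curve" is not.
- **Rescaled probabilities are not clamped** to [0, 1]: p′ is a covariate of
  the meta-model, not a probability, and clamping would destroy both the
  affine form and the exact equivalence "threshold p at c ⇔ threshold p′ at
  0.5".
- **Meta-model degeneracy.** With 50 training points per school-year a
  stratum can be single-class or separable. Single-class or undersized
  (< 10 rows) strata fall back to the pooled model fitted on all stacking
  data; separable strata are fitted anyway (large coefficients are harmless
  for 0.5-thresholding). Fallback strata are recorded on the fitted object.
- **Ties at the final threshold** go to non-Negative (p̄ ≥ 0.5).

## Metrics

Positive class is non-Negative everywhere: sensitivity = P(predict
non-Negative | non-Negative), specificity the same for Negative, PPV the
positive predictive value. F1 is the harmonic mean of sensitivity and PPV —
the same number whether one uses the standard precision/recall naming or
the swapped naming that sometimes appears in applied reports, since the
harmonic mean is symmetric in its arguments. Undefined ratios are NaN,
never 0. Cohen's kappa uses marginal-product chance agreement and is NaN
when both raters are constant and identical.

## GLMM estimation

- **Aggregation.** Covariates are constant within a school-year cell, so
  the message-level Bernoulli likelihood and the cell-level binomial
  likelihood are identical; the model is fitted to the 16-row (or 8-row)
  count table. A test asserts the equivalence explicitly.
- **Quadrature.** The per-school random-intercept integral uses adaptive
  Gauss–Hermite quadrature: a Newton solve for each school's conditional
  mode, curvature-based rescaling, then a 25-node Gauss–Hermite rule in the
  standardized variable, accumulated in log space. Orders 15 and 25 agree to
  < 1e−4 in all coefficients on the study table; 25 is the default because
  it is already far past the plateau at negligible cost.
- **Optimization.** σ is estimated on the log scale; β is warm-started from
  the σ = 0 (plain logistic) fit and the joint (β, log σ) surface is
  maximized by BFGS. The `converged` flag accepts BFGS's "precision loss"
  status when the final gradient is at finite-difference noise level.
- **Inference.** Wald tests from the numerically differentiated observed
  information. With 8 schools, the SEs of between-school terms (intercept,
  type, location) lean on the asymptotic behavior of σ̂ and should be read
  with small-cluster caution; the within-school contrasts (year, in-person)
  are insensitive to this. Exact p-values for between-school-correlated
  terms also depend on the integral approximation used, so third-decimal
  agreement with any particular software's p-values is not guaranteed —
  significance conclusions at the 0.05 level are stable across quadrature
  orders 1–25.
- **Outcome coding.** The model is fitted with Negative = 1 by default so
  exp(β) is directly the odds ratio of negative sentiment; the
  complementary coding gives exactly reciprocal odds ratios (asserted in
  tests).

## Problem sizes used in the test suite

Unit and property tests run on corpora of 10–400 messages. The recovery and
end-to-end checks use: parameter recovery at 2000 messages per cell over a
6×-replicated factorial (48 schools — enough clusters for the 3-SE Wald
check to be calibrated; at 8–24 clusters σ̂ is biased low and the nominal
z-scores overshoot), and a full pipeline run at 200 messages per cell across
the 8-school design with class separation 4.0. The whole suite completes in
about a minute on one CPU.

## Known limitations

- The GAT aggregates neighbors unconditionally; on corpora where thread
  sentiment is uncorrelated the graph dilutes rather than helps, and the
  embedding head wins. This matches the model's assumptions, not a bug.
- No per-user random effects (messages are exchangeable within school given
  the intercept).
- The deterministic featurizer is a testing vehicle; real-text performance
  requires an external embedding backend.
- Only the homogeneous message→reply-to graph is modelled; heterogeneous
  node/relation types are out of scope.
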