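"""Synthetic corpus generator with the statistical structure of the study data.

Generates message tables for an 8-school full-factorial design: reply forests
within each school-year, latent binary sentiment from a logistic model with
school random intercepts, class-conditional Gaussian embeddings standing in
for transformer output, and a sparse, imbalanced manually-labelled subset.
Every stage is driven by a single :class:`numpy.random.Generator` so corpora
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

NEGATIVE = "Negative"
NON_NEGATIVE = "nonNegative"
YEARS = (2019, 2020)

__all__ = [
    "NEGATIVE",
    "NON_NEGATIVE",
    "GlmmTruth",
    "SimulationConfig",
    "generate_design",
    "simulate_threads",
    "simulate_sentiments",
    "simulate_embeddings",
    "subsample_labeled",
    "generate_corpus",
    "embedding_matrix",
]


@dataclass(frozen=True)
class GlmmTruth:
    """True parameters of the sentiment model, on the non-Negative logit scale.

    ``logit Pr(non-Negative) = b0 + b_type*x_type + b_location*x_location
    + b_year*x_year + gamma_school``, with ``gamma_school ~ N(0, sigma**2)``.
    Covariates are coded 1 = private, 1 = small city, 1 = year 2020.  The
    defaults are the study-scale effects: a baseline around 36% Negative,
    odds of Negative ~26% higher in 2020, modest school effects.
    """

    b0: float = 0.58
    b_type: float = 0.24
    b_location: float = -0.07
    b_year: float = -0.23
    sigma: float = 0.26

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus.

    messages_per_cell
        Messages per school-year cell.  1000 keeps a full corpus (16 000
        messages) tractable while leaving per-cell counts large enough for
        the study's 25+25 per-cell test and stacking splits.
    root_fraction
        Probability a message opens a new thread (free parameter; the thread
        size distribution of the real corpus is unknown).
    thread_persistence
        Probability a reply inherits its parent's sentiment instead of
        drawing independently; 0 makes messages conditionally independent,
        larger values make sentiment cluster within threads (what gives the
        reply graph predictive value).
    class_separation
        Euclidean distance between the class-conditional embedding means
        (unit within-class scatter), i.e. a linear-separability dial.
    label_fraction / label_imbalance
        Size and non-Negative:Negative ratio of the manually-labelled subset
        per cell.  Defaults mirror the study's labelling effort: roughly 200
        labels per school-year at about 2.7 non-Negative per Negative.
    """

    messages_per_cell: int = 1000
    root_fraction: float = 0.3
    thread_persistence: float = 0.0
    embedding_dim: int = 16
    class_separation: float = 3.0
    glmm_truth: GlmmTruth = field(default_factory=GlmmTruth)
    label_fraction: float = 0.2
    label_imbalance: float = 2.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.messages_per_cell < 1:
            raise ValueError("messages_per_cell must be positive")
        if not 0 < self.root_fraction <= 1:
            raise ValueError("root_fraction must be in (0, 1]")
        if not 0 <= self.thread_persistence <= 1:
            raise ValueError("thread_persistence must be in [0, 1]")
        if not 0 <= self.label_fraction <= 1:
            raise ValueError("label_fraction must be in [0, 1]")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if self.label_imbalance < 1:
            raise ValueError("label_imbalance must be >= 1")


def generate_design() -> pd.DataFrame:
    """Full-factorial 2x2x2 design of eight synthetic schools.

    Factors: funding (private/public), location (small/large city), in_person
    (yes/no).  Every combination appears exactly once, so each factor is
    balanced 4/4 — the property that lets the downstream mixed model separate
    the three fixed effects.
    """
    rows = []
    i = 0
    for funding in ("public", "private"):
        for location in ("large", "small"):
            for in_person in ("no", "yes"):
                i += 1
                rows.append(
                    {
                        "school_id": f"S{i}",
                        "funding": funding,
                        "location": location,
                        "in_person": in_person,
                    }
                )
    return pd.DataFrame(rows)


def simulate_threads(n_messages: int, root_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Reply forest over messages ``0..n_messages-1``.

    Message 0 is always a thread root; each later message is a new root with
    probability ``root_fraction`` and otherwise replies to a uniformly chosen
    earlier message.  Returns an integer array of shape (n_edges, 2) with
    columns (child, parent); parents always have a smaller index, so the
    structure is a forest by construction.
    """
    if n_messages < 1:
        raise ValueError("n_messages must be >= 1")
    if not 0 < root_fraction <= 1:
        raise ValueError("root_fraction must be in (0, 1]")
    is_root = rng.random(n_messages) < root_fraction
    is_root[0] = True
    children = np.flatnonzero(~is_root)
    if children.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    parents = (rng.random(children.size) * children).astype(np.int64)
    return np.column_stack([children, parents])


def _cell_logit(truth: GlmmTruth, x_type: int, x_location: int, x_year: int) -> float:
    return truth.b0 + truth.b_type * x_type + truth.b_location * x_location + truth.b_year * x_year


def simulate_sentiments(
    design: pd.DataFrame,
    truth: GlmmTruth,
    messages_per_cell: int,
    rng: np.random.Generator,
    *,
    edges_by_cell: dict | None = None,
    thread_persistence: float = 0.0,
) -> pd.DataFrame:
    """Latent sentiment per message for every school-year cell.

    One random intercept per school is drawn first; each message's sentiment
    is then a Bernoulli draw at the logistic probability implied by its
    school covariates, year and intercept.  With ``thread_persistence`` > 0
    a reply copies its parent's sentiment with that probability (its marginal
    distribution is unchanged because the parent shares the same cell
    probability).
    """
    gammas = {s: rng.normal(0.0, truth.sigma) for s in design["school_id"]}
    frames = []
    for _, school in design.iterrows():
        x_type = int(school["funding"] == "private")
        x_location = int(school["location"] == "small")
        for year in YEARS:
            x_year = int(year == YEARS[1])
            p_nonneg = expit(_cell_logit(truth, x_type, x_location, x_year) + gammas[school["school_id"]])
            nonneg = rng.random(messages_per_cell) < p_nonneg
            if thread_persistence > 0 and edges_by_cell is not None:
                edges = edges_by_cell.get((school["school_id"], year))
                if edges is not None and len(edges):
                    copy = rng.random(len(edges)) < thread_persistence
                    # children index > parent index, so a single ordered pass
                    # propagates sentiment down whole threads
                    for (child, parent), c in zip(np.asarray(edges), copy):
                        if c:
                            nonneg[child] = nonneg[parent]
            frames.append(
                pd.DataFrame(
                    {
                        "school_id": school["school_id"],
                        "year": year,
                        "true_sentiment": np.where(nonneg, NON_NEGATIVE, NEGATIVE),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_embeddings(
    true_sentiments: np.ndarray,
    embedding_dim: int,
    class_separation: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class-conditional spherical Gaussian embeddings.

    The two class means sit ``class_separation`` apart along the first axis
    with identity covariance, so a Bayes-optimal linear classifier has
    accuracy ``Phi(class_separation / 2)``.
    """
    if embedding_dim < 2:
        raise ValueError("embedding_dim must be >= 2")
    sent = np.asarray(true_sentiments)
    n = sent.shape[0]
    X = rng.standard_normal((n, embedding_dim))
    shift = np.where(sent == NON_NEGATIVE, 0.5, -0.5) * class_separation
    X[:, 0] += shift
    return X


def subsample_labeled(
    corpus: pd.DataFrame,
    requests,
    rng: np.random.Generator,
    *,
    exclude=(),
) -> np.ndarray:
    """Stratified label subsets: exact per-cell class composition.

    ``requests`` maps ``(school_id, year)`` to ``(n_negative, n_nonnegative)``,
    or is a single such pair applied to every cell.  Sampling is without
    replacement within each school-year-class stratum and never touches row
    positions in ``exclude``, so successive calls with accumulated exclusions
    yield disjoint train/stacking/test splits by construction.  A cell with
    too few available messages of a class raises a ``ValueError`` naming it.
    """
    if not isinstance(requests, dict):
        n_neg, n_nonneg = requests
        requests = {
            (s, y): (n_neg, n_nonneg)
            for s in corpus["school_id"].unique()
            for y in sorted(corpus["year"].unique())
        }
    excluded = np.zeros(len(corpus), dtype=bool)
    ex = np.asarray(list(exclude), dtype=np.int64)
    if ex.size:
        excluded[ex] = True
    chosen: list[np.ndarray] = []
    for (school, year), (n_neg, n_nonneg) in requests.items():
        in_cell = (corpus["school_id"].to_numpy() == school) & (corpus["year"].to_numpy() == year)
        for cls, want in ((NEGATIVE, n_neg), (NON_NEGATIVE, n_nonneg)):
            if want == 0:
                continue
            pool = np.flatnonzero(in_cell & (corpus["true_sentiment"].to_numpy() == cls) & ~excluded)
            if pool.size < want:
                raise ValueError(
                    f"cell ({school}, {year}, {cls}): requested {want} labelled "
                    f"messages but only {pool.size} available"
                )
            chosen.append(rng.choice(pool, size=want, replace=False))
    if not chosen:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(chosen))


def generate_corpus(config: SimulationConfig, design: pd.DataFrame | None = None):
    """Full synthetic corpus: messages, reply edges, and design table.

    Returns ``(corpus, edges, design)``.  ``corpus`` has one row per message
    with ``message_id``, ``parent_id`` (missing for thread roots),
    ``school_id``, ``year``, ``true_sentiment``, ``observed_label`` (missing
    outside the labelled subset) and an ``embedding`` list column; ``edges``
    has columns ``child_id, parent_id``.
    """
    rng = np.random.default_rng(config.seed)
    if design is None:
        design = generate_design()

    # thread topology first, so sentiment can optionally cluster in threads
    edges_by_cell: dict = {}
    for school in design["school_id"]:
        for year in YEARS:
            edges_by_cell[(school, year)] = simulate_threads(
                config.messages_per_cell, config.root_fraction, rng
            )

    corpus = simulate_sentiments(
        design,
        config.glmm_truth,
        config.messages_per_cell,
        rng,
        edges_by_cell=edges_by_cell,
        thread_persistence=config.thread_persistence,
    )

    # per-cell local indices -> stable global message ids
    local = corpus.groupby(["school_id", "year"]).cumcount().to_numpy()
    corpus["message_id"] = [
        f"{s}-{y}-{i:06d}" for s, y, i in zip(corpus["school_id"], corpus["year"], local)
    ]
    id_of = {}
    for (school, year), grp in corpus.groupby(["school_id", "year"], sort=False):
        id_of[(school, year)] = grp["message_id"].to_numpy()
    parent = np.full(len(corpus), None, dtype=object)
    edge_rows = []
    offset_index = {k: np.flatnonzero((corpus["school_id"] == k[0]) & (corpus["year"] == k[1]))
                    for k in edges_by_cell}
    for key, edges in edges_by_cell.items():
        cell_ids = id_of[key]
        rows = offset_index[key]
        for child, par in np.asarray(edges, dtype=np.int64).reshape(-1, 2):
            parent[rows[child]] = cell_ids[par]
            edge_rows.append((cell_ids[child], cell_ids[par]))
    corpus["parent_id"] = parent
    edges_df = pd.DataFrame(edge_rows, columns=["child_id", "parent_id"])

    X = simulate_embeddings(
        corpus["true_sentiment"].to_numpy(),
        config.embedding_dim,
        config.class_separation,
        rng,
    )
    corpus["embedding"] = [row.tolist() for row in X]

    # sparse, imbalanced labelled subset per cell
    n_lab = int(round(config.label_fraction * config.messages_per_cell))
    n_neg_lab = int(round(n_lab / (1.0 + config.label_imbalance)))
    n_nonneg_lab = n_lab - n_neg_lab
    labels = np.full(len(corpus), None, dtype=object)
    if n_lab > 0:
        # cap each cell's request at what the cell actually contains: with
        # thread-correlated sentiment a cell can be nearly single-class
        requests = {}
        for (school, year), grp in corpus.groupby(["school_id", "year"], sort=False):
            avail_neg = int((grp["true_sentiment"] == NEGATIVE).sum())
            avail_nonneg = len(grp) - avail_neg
            requests[(school, year)] = (
                min(n_neg_lab, avail_neg),
                min(n_nonneg_lab, avail_nonneg),
            )
        idx = subsample_labeled(corpus, requests, rng)
        labels[idx] = corpus["true_sentiment"].to_numpy()[idx]
    corpus["observed_label"] = labels

    cols = [
        "message_id",
        "parent_id",
        "school_id",
        "year",
        "true_sentiment",
        "observed_label",
        "embedding",
    ]
    return corpus[cols], edges_df, design


def embedding_matrix(corpus: pd.DataFrame) -> np.ndarray:
    """Stack the ``embedding`` list column into an (n_messages, D) array."""
    return np.asarray(corpus["embedding"].tolist(), dtype=float)
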