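"""End-to-end orchestration of the sentiment-analysis pipeline.

Stages, mirroring the study workflow: (optionally) simulate a corpus ->
embed messages -> train the two base classifiers (softmax head on the
embeddings; semi-supervised GAT on the reply graph) -> optimize per-model
cutoffs on the stacking split -> rescale probabilities and fit the
per-school-year logistic meta-model -> label every message -> aggregate to
school-year counts -> fit the two random-intercept GLMMs (year effect on the
full table; in-person effect on the pandemic year).  Every randomized stage
draws a logged sub-seed from the global seed, so a (config, seed) pair fully
determines the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .features import EmbeddingHeadClassifier, embed
from .gat import GATClassifier, reply_graph_adjacency
from .glmm import aggregate_counts, fit_glmm, report
from .metrics import classification_metrics, confusion_table
from .simulate import (
    NEGATIVE,
    NON_NEGATIVE,
    SimulationConfig,
    embedding_matrix,
    generate_corpus,
    subsample_labeled,
)
from .stacking import StackedSentimentClassifier, optimal_cutoff, scale_probability

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; classifier defaults are the study values.

    Either ``simulation`` is set (a synthetic corpus is generated) or
    ``corpus_path``/``edges_path``/``design_path`` point at input files.
    ``gat_train_school``: when set, the GAT/head training labels come from
    that school only (the study trained on a single school's labels);
    otherwise all labelled messages outside the test and stacking splits are
    used.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: dict | None = None
    corpus_path: str | None = None
    edges_path: str | None = None
    design_path: str | None = None
    embedding_provider: str = "precomputed"  # or "featurizer" (text column)
    gat: dict = field(
        default_factory=lambda: {
            "n_heads": 4,
            "head_dim": 8,
            "neg_weight": 2.0,
            "l2": 0.08,
            "learning_rate": 0.02,
            "n_epochs": 300,
        }
    )
    head_l2: float = 1.0
    test_per_cell: tuple = (25, 25)  # (Negative, non-Negative) per school-year
    stack_per_cell: tuple = (25, 25)
    gat_train_school: str | None = None
    meta_cutoff: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.test_per_cell, list):
            cfg.test_per_cell = tuple(cfg.test_per_cell)
        if isinstance(cfg.stack_per_cell, list):
            cfg.stack_per_cell = tuple(cfg.stack_per_cell)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sub_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the global seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dict(config.simulation)
        sim.setdefault("seed", _sub_seed(config.seed, "simulate"))
        from .simulate import GlmmTruth

        if isinstance(sim.get("glmm_truth"), dict):
            sim["glmm_truth"] = GlmmTruth(**sim["glmm_truth"])
        corpus, edges, design = generate_corpus(SimulationConfig(**sim))
        return corpus, edges, design
    if not (config.corpus_path and config.design_path):
        raise ValueError("either simulation or corpus/design paths must be configured")
    corpus = sio.read_corpus(config.corpus_path)
    edges = (
        sio.read_edges(config.edges_path)
        if config.edges_path
        else pd.DataFrame(columns=["child_id", "parent_id"])
    )
    design = sio.read_design(config.design_path)
    return corpus, edges, design


def _embeddings(config: PipelineConfig, corpus: pd.DataFrame) -> np.ndarray:
    if config.embedding_provider == "precomputed":
        if corpus["embedding"].isna().any():
            raise ValueError("corpus lacks embeddings; use the featurizer provider")
        return embedding_matrix(corpus)
    if config.embedding_provider == "featurizer":
        return embed(corpus["text"].fillna("").tolist(), provider="featurizer")
    raise ValueError(f"unknown embedding provider {config.embedding_provider!r}")


def _splits(config: PipelineConfig, corpus: pd.DataFrame):
    """Disjoint test / stacking / classifier-training label splits."""
    rng = np.random.default_rng(_sub_seed(config.seed, "splits"))
    labeled = corpus["observed_label"].notna().to_numpy()
    unlabeled_idx = np.flatnonzero(~labeled)
    test_idx = subsample_labeled(
        corpus, tuple(config.test_per_cell), rng, exclude=unlabeled_idx
    )
    stack_idx = subsample_labeled(
        corpus, tuple(config.stack_per_cell), rng,
        exclude=np.concatenate([unlabeled_idx, test_idx]),
    )
    train_mask = labeled.copy()
    train_mask[test_idx] = False
    train_mask[stack_idx] = False
    if config.gat_train_school is not None:
        train_mask &= (corpus["school_id"] == config.gat_train_school).to_numpy()
    train_idx = np.flatnonzero(train_mask)
    if train_idx.size == 0:
        raise ValueError("no labelled messages left for classifier training")
    return train_idx, stack_idx, test_idx


def _as01(labels) -> np.ndarray:
    return (np.asarray(labels) == NON_NEGATIVE).astype(int)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write per-stage artifacts; return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    log.info("pipeline start %s", stamp)

    corpus, edges, design = _load_inputs(config)
    sio.write_corpus(corpus, out / "corpus.jsonl")
    sio.write_edges(edges, out / "edges.csv")
    sio.write_design(design, out / "design.csv")

    X = _embeddings(config, corpus)
    train_idx, stack_idx, test_idx = _splits(config, corpus)
    y_obs = _as01(corpus["observed_label"].to_numpy())

    # base classifier 1: softmax head on embeddings
    head = EmbeddingHeadClassifier(
        l2_strength=config.head_l2, random_state=_sub_seed(config.seed, "head")
    )
    head.fit(X[train_idx], y_obs[train_idx])
    p1 = head.predict_proba(X)[:, 1]

    # base classifier 2: semi-supervised GAT on the reply graph
    index_of = {m: i for i, m in enumerate(corpus["message_id"])}
    edge_idx = np.array(
        [[index_of[c], index_of[p]] for c, p in zip(edges["child_id"], edges["parent_id"])],
        dtype=np.int64,
    ).reshape(-1, 2)
    A = reply_graph_adjacency(edge_idx, len(corpus))
    y_semi = np.full(len(corpus), -1, dtype=int)
    y_semi[train_idx] = y_obs[train_idx]
    gat = GATClassifier(random_state=_sub_seed(config.seed, "gat"), **config.gat)
    gat.fit(X, y_semi, adjacency=A)
    p2 = gat.predict_proba(X, adjacency=A)[:, 1]

    # cutoffs on the stacking split only
    y_stack = y_obs[stack_idx]
    c1 = optimal_cutoff(p1[stack_idx], y_stack)
    c2 = optimal_cutoff(p2[stack_idx], y_stack)
    c1 = min(max(c1, 1e-6), 1 - 1e-6)
    c2 = min(max(c2, 1e-6), 1 - 1e-6)
    p1s = scale_probability(p1, c1)
    p2s = scale_probability(p2, c2)

    strata = (corpus["school_id"].astype(str) + ":" + corpus["year"].astype(str)).to_numpy()
    meta = StackedSentimentClassifier()
    meta.fit(np.column_stack([p1s, p2s])[stack_idx], y_stack, strata=strata[stack_idx])
    p_bar = meta.predict_proba(np.column_stack([p1s, p2s]), strata=strata)[:, 1]
    final01 = (p_bar >= config.meta_cutoff).astype(int)
    final_label = np.where(final01 == 1, NON_NEGATIVE, NEGATIVE)

    preds = pd.DataFrame(
        {
            "message_id": corpus["message_id"],
            "p1": p1,
            "p2": p2,
            "p1_scaled": p1s,
            "p2_scaled": p2s,
            "p_bar": p_bar,
            "final_label": final_label,
        }
    )
    preds.to_csv(out / "predictions.csv", index=False)

    # held-out evaluation of all three classifiers
    y_test = y_obs[test_idx]
    evaluation = {}
    for name, scores, cutoff in (
        ("head", p1, c1),
        ("gat", p2, c2),
        ("meta", p_bar, config.meta_cutoff),
    ):
        pred = (scores[test_idx] >= cutoff).astype(int)
        evaluation[name] = classification_metrics(confusion_table(y_test, pred))

    counts = aggregate_counts(
        corpus.assign(final_label=final_label), design, label_col="final_label"
    )
    counts.to_csv(out / "counts.csv", index=False)

    glmm_reports = {}
    fit_year = fit_glmm(counts, ["x_type", "x_location", "x_year"])
    glmm_reports["year_model"] = _fit_dict(fit_year)
    pandemic = counts[counts["x_year"] == 1]
    if pandemic["x_in_person"].nunique() > 1:
        fit_ip = fit_glmm(pandemic, ["x_type", "x_location", "x_in_person"])
        glmm_reports["in_person_model"] = _fit_dict(fit_ip)

    result = {
        **stamp,
        "cutoffs": {"head": c1, "gat": c2, "meta": config.meta_cutoff},
        "splits": {
            "train": int(train_idx.size),
            "stack": int(stack_idx.size),
            "test": int(test_idx.size),
        },
        "evaluation": evaluation,
        "counts_summary": {
            "total_messages": int(counts["total"].sum()),
            "pct_negative_overall": float(
                100.0 * counts["n_negative"].sum() / counts["total"].sum()
            ),
        },
        "glmm": glmm_reports,
    }
    (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    log.info("pipeline done -> %s", out / "report.json")
    return result


def _fit_dict(fit) -> dict:
    table = report(fit)
    return {
        "terms": {
            row["term"]: {
                "coef": row["coef"],
                "se": row["se"],
                "odds_ratio": row["odds_ratio"],
                "pvalue": row["pvalue"],
            }
            for _, row in table.iterrows()
        },
        "sigma": fit.sigma,
        "loglik": fit.loglik,
        "n_quad": fit.n_quad,
        "converged": fit.converged,
    }
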