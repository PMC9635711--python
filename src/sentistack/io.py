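"""File formats: JSON-lines corpus, delimited edge lists and tables.

A corpus file has one JSON object per message with keys ``message_id``,
``school_id``, ``year`` (required), and optionally ``parent_id``, ``text``,
``true_sentiment``, ``observed_label``, ``embedding``.  Validation reports
the offending line number for missing keys and lists all dangling parent
references.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

VALID_YEARS = (2019, 2020)
_REQUIRED = ("message_id", "school_id", "year")
_OPTIONAL = ("parent_id", "text", "true_sentiment", "observed_label", "embedding")

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_edges",
    "write_edges",
    "read_design",
    "write_design",
]


def write_corpus(corpus: pd.DataFrame, path) -> None:
    """Write one JSON object per message; missing optional fields are omitted."""
    path = Path(path)
    with path.open("w") as fh:
        for _, row in corpus.iterrows():
            rec = {k: row[k] for k in _REQUIRED}
            rec["year"] = int(rec["year"])
            for k in _OPTIONAL:
                if k in corpus.columns and row[k] is not None and not (
                    np.isscalar(row[k]) and pd.isna(row[k])
                ):
                    rec[k] = row[k]
            fh.write(json.dumps(rec) + "\n")


def read_corpus(path) -> pd.DataFrame:
    """Read and validate a JSON-lines corpus.

    Errors name the first line with a missing required key or duplicate
    message id; parent references to unknown messages are collected and
    reported together.
    """
    records = []
    seen = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            for key in _REQUIRED:
                if key not in rec:
                    raise ValueError(f"line {lineno}: missing required key {key!r}")
            if rec["message_id"] in seen:
                raise ValueError(f"line {lineno}: duplicate message_id {rec['message_id']!r}")
            if int(rec["year"]) not in VALID_YEARS:
                raise ValueError(f"line {lineno}: year {rec['year']} outside {VALID_YEARS}")
            seen.add(rec["message_id"])
            records.append(rec)
    corpus = pd.DataFrame(records)
    for k in _OPTIONAL:
        if k not in corpus.columns:
            corpus[k] = None
    corpus = corpus.where(pd.notna(corpus), None)
    corpus["year"] = corpus["year"].astype(int)
    dangling = [
        (mid, pid)
        for mid, pid in zip(corpus["message_id"], corpus["parent_id"])
        if pid is not None and pid not in seen
    ]
    if dangling:
        raise ValueError(f"parent_id references unknown messages: {dangling}")
    return corpus[list(_REQUIRED) + list(_OPTIONAL)]


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["child_id", "parent_id"]].to_csv(path, index=False)


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, dtype=str)
    if list(edges.columns) != ["child_id", "parent_id"]:
        raise ValueError("edge list must have columns child_id, parent_id")
    return edges


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    required = {"school_id", "funding", "location", "in_person"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design
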