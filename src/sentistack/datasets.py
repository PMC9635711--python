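"""Bundled study tables: eight university subreddits, 2019 vs 2020.

The study design covers eight R1-university subreddit communities chosen on a
full-factorial 2x2x2 design (funding type x city size x in-person learning in
fall 2020).  ``load_study_design`` returns that design together with the
per-school message counts for August-November of 2019 and 2020;
``load_study_counts`` returns the final labelled sentiment frequencies per
school-year (Negative vs non-Negative) produced by the stacked classifier on
the full corpus.  Both tables are small CSVs shipped with the package and are
the inputs to the descriptive summaries and the mixed-model inference.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_study_design", "load_study_counts", "load_study_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("sentistack.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_study_design() -> pd.DataFrame:
    """Eight-school design table with factor levels and message counts.

    Columns: ``school_id``, ``funding`` (private/public), ``location``
    (small/large city), ``in_person`` (yes/no, fall 2020), ``messages_2019``,
    ``messages_2020``.
    """
    return _read("study_design.csv")


def load_study_counts() -> pd.DataFrame:
    """Per school-year Negative / non-Negative message counts (16 rows).

    Columns: ``school_id``, ``year``, ``n_negative``, ``n_nonnegative``,
    plus derived ``total`` and ``pct_negative`` (in percent).
    """
    counts = _read("study_counts.csv")
    counts["total"] = counts["n_negative"] + counts["n_nonnegative"]
    counts["pct_negative"] = 100.0 * counts["n_negative"] / counts["total"]
    return counts


def load_study_table() -> pd.DataFrame:
    """Study counts joined to the design covariates, ready for the GLMM.

    Adds the 0/1 covariate codings used throughout: ``x_type`` (1 = private),
    ``x_location`` (1 = small city), ``x_year`` (1 = 2020), ``x_in_person``
    (1 = in-person learning).
    """
    from .glmm import join_design

    return join_design(load_study_counts(), load_study_design())
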