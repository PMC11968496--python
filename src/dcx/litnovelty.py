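"""TF-IDF literature-novelty scoring of candidate drugs.

Given per-drug article counts (articles mentioning the drug; articles
co-mentioning the drug and the target disease), each drug is scored by

* ``TF   = n_disease_articles / sum_j n_disease_articles`` over the candidate
  table (0 when no candidate has any co-mention),
* ``IDF  = log10(sum_j n_articles / n_articles)``,
* ``TF-IDF = TF * IDF``.

A TF-IDF of 0 — equivalently, zero disease co-mentions — flags the drug as a
novel repurposing candidate for the target disease.  A reference count table
of 20 candidate drugs for a motor-neuron disease (co-mention total 335,
article total 661,680) ships with the package; the recomputed TF/IDF columns
reproduce its published scores.

Counting can be done offline against any local corpus of (id, text) records
with case-insensitive whole-phrase matching; no live literature service is on
the scoring path.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "load_table1",
    "count_comentions",
    "score_novelty",
    "novelty_report",
]

COUNT_COLUMNS = ["drug", "n_articles", "n_disease_articles"]


def load_table1() -> pd.DataFrame:
    """Packaged reference count table (with the published score columns)."""
    with resources.files("dcx.data").joinpath("table1_literature_counts.csv").open() as fh:
        return pd.read_csv(fh)


def _phrase(term: str) -> re.Pattern:
    return re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", re.IGNORECASE)


def count_comentions(
    corpus: Iterable[tuple[str, str] | Mapping[str, str]],
    drug_terms: Sequence[str],
    disease_terms: Sequence[str],
) -> pd.DataFrame:
    """Co-mention counts of each drug term with any disease term over a corpus.

    ``corpus`` yields (id, text) pairs or mappings with ``id``/``text`` keys.
    Matching is case-insensitive whole-phrase.
    """
    if not drug_terms or not disease_terms:
        raise ParameterError("drug and disease term lists must be non-empty")
    texts = []
    for record in corpus:
        text = record["text"] if isinstance(record, Mapping) else record[1]
        texts.append(text)
    disease_patterns = [_phrase(t) for t in disease_terms]
    rows = []
    for drug in drug_terms:
        pattern = _phrase(drug)
        hits = [t for t in texts if pattern.search(t)]
        co = sum(1 for t in hits if any(p.search(t) for p in disease_patterns))
        rows.append((drug, len(hits), co))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def score_novelty(counts: pd.DataFrame) -> pd.DataFrame:
    """TF, IDF, TF-IDF and the novelty flag for a candidate count table.

    Drugs with zero total articles are excluded with a warning (their IDF is
    undefined).  No internal rounding; round only when formatting output.
    """
    if counts.empty:
        raise ParameterError("empty count table")
    df = counts.copy()
    df["n_articles"] = df["n_articles"].astype(int)
    df["n_disease_articles"] = df["n_disease_articles"].astype(int)
    if (df["n_disease_articles"] > df["n_articles"]).any():
        raise ParameterError("n_disease_articles exceeds n_articles for some drug")
    zero = df["n_articles"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} drugs with zero articles excluded from scoring", stacklevel=2
        )
        df = df[~zero]
    if df.empty:
        raise ParameterError("no scorable drugs (all have zero articles)")
    total_articles = int(df["n_articles"].sum())
    total_co = int(df["n_disease_articles"].sum())
    tf = (
        df["n_disease_articles"] / total_co
        if total_co > 0
        else pd.Series(0.0, index=df.index)
    )
    idf = np.log10(total_articles / df["n_articles"])
    out = pd.DataFrame(
        {
            "drug": df["drug"],
            "n_articles": df["n_articles"],
            "n_disease_articles": df["n_disease_articles"],
            "tf": tf.astype(float),
            "idf": idf.astype(float),
        }
    )
    out["tfidf"] = out["tf"] * out["idf"]
    out["novel"] = out["n_disease_articles"] == 0
    return out.reset_index(drop=True)


def novelty_report(scores: pd.DataFrame) -> pd.DataFrame:
    """Ranked report: novel drugs first, then ascending TF-IDF, ties by label."""
    ordered = scores.sort_values(
        ["novel", "tfidf", "drug"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return ordered[["drug", "n_articles", "n_disease_articles", "tf", "idf", "tfidf", "novel"]]
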