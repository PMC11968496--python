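"""Over-representation analysis of cluster genes against GMT gene-set collections.

Per gene set the upper-tail hypergeometric probability P(X >= overlap) is
computed with population = universe size, successes = set size, draws = query
size; q-values come from Benjamini–Hochberg across the collection.  The rich
factor is overlap / set size.  The universe defaults to the union of all genes
in the collection (logged, since p-values depend on it) and can be overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .degstage import bh_adjust
from .errors import ParameterError, ValidationError

__all__ = ["GeneSetCollection", "read_gmt", "hypergeom_ora", "enrich_cluster"]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValidationError(f"empty gene sets: {empty[:5]}")

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene...), tolerant of CRLF."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name = fields[0]
        genes = {g for g in fields[2:] if g}
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
    return GeneSetCollection(sets, source or Path(path).stem)


def hypergeom_ora(query: set, gene_set: set, universe: set) -> tuple[int, float]:
    """Overlap and upper-tail hypergeometric p-value P(X >= overlap)."""
    if not universe:
        raise ParameterError("empty universe")
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped", stacklevel=2)
        query = query & universe
    gene_set = gene_set & universe
    overlap = len(query & gene_set)
    if overlap == 0:
        return 0, 1.0
    p = float(hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(query)))
    return overlap, min(p, 1.0)


def enrich_cluster(
    cluster_genes: set,
    collection: GeneSetCollection,
    universe: set | None = None,
    q_alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of the cluster genes against every set in the collection.

    One row per gene set with overlap >= 1, columns: set_name, overlap,
    set_size, query_size, universe_size, p_value, q_value, rich_factor,
    significant.  Sorted by (q_value, p_value).
    """
    if not cluster_genes:
        raise ParameterError("empty cluster gene set")
    if not collection.sets:
        warnings.warn("empty gene-set collection", stacklevel=2)
        return pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "query_size", "universe_size",
                     "p_value", "q_value", "rich_factor", "significant"]
        )
    if universe is None:
        universe = collection.universe()
        log.info("universe defaulted to collection union (%d genes)", len(universe))
    query = cluster_genes & universe
    if len(query) < len(cluster_genes):
        warnings.warn(
            f"{len(cluster_genes) - len(query)} cluster genes outside the universe dropped",
            stacklevel=2,
        )
    rows = []
    for name, genes in collection.sets.items():
        overlap, p = hypergeom_ora(query, genes, universe)
        if overlap >= 1:
            set_size = len(genes & universe)
            rows.append((name, overlap, set_size, len(query), len(universe), p, overlap / set_size))
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size",
                       "universe_size", "p_value", "rich_factor"]
    )
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_alpha
    out = out.sort_values(["q_value", "p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out[["set_name", "overlap", "set_size", "query_size", "universe_size",
                "p_value", "q_value", "rich_factor", "significant"]]
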