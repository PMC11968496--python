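"""Differential-expression filtering and cross-dataset intersection.

Consumes precomputed per-dataset DE tables (gene, linear fold change,
BH-adjusted p) and applies the standard two-sided fold-change filter:
a gene is a DEG iff adj_p < 0.05 and fc > 1.5 (up) or fc < 0.67 (down).
DEG sets from several datasets of the same tissue are intersected by
identifier only — a gene up in one dataset and down in another is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError

__all__ = ["DEGSet", "read_de_table", "filter_degs", "intersect_degs", "bh_adjust"]


@dataclass
class DEGSet:
    """Genes passing the DE filters for one dataset, with per-gene direction."""

    genes: set[str]
    directions: dict[str, str] = field(default_factory=dict)
    source_dataset: str = ""

    def __post_init__(self) -> None:
        missing = self.genes - set(self.directions)
        if missing:
            raise ValidationError(f"genes without direction: {sorted(missing)[:5]}")


def read_de_table(path: str | Path, log2: bool = False, dataset_id: str | None = None) -> pd.DataFrame:
    """Read a DE table (CSV or TSV) with columns gene, fc (or log2fc), adj_p.

    ``log2=True`` (or a ``log2fc`` column) converts fold changes via fc=2**log2fc.
    Multi-probe genes are collapsed to the minimum-adj_p row per gene.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if "log2fc" in df.columns and "fc" not in df.columns:
        log2 = True
        df = df.rename(columns={"log2fc": "fc"})
    required = {"gene", "fc", "adj_p"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path} missing columns {sorted(required - set(df.columns))}")
    if log2:
        df["fc"] = 2.0 ** df["fc"].astype(float)
    df = df.sort_values("adj_p", kind="stable").drop_duplicates("gene", keep="first")
    df = df.sort_index().reset_index(drop=True)
    df.attrs["dataset_id"] = dataset_id or path.stem
    return df


def _validate_table(table: pd.DataFrame) -> None:
    bad = table.index[table["fc"].astype(float) <= 0]
    if len(bad):
        row = bad[0]
        raise ValidationError(f"non-positive fold change in row {row}: gene={table.loc[row, 'gene']}")
    p = table["adj_p"].astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("adj_p outside [0, 1]")


def filter_degs(
    table: pd.DataFrame,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    readjust: bool = False,
) -> DEGSet:
    """Apply the DEG filter: adj_p < alpha and fc strictly outside [fc_down, fc_up].

    Genes with fold change inside the dead zone are excluded regardless of
    significance.  ``readjust=True`` re-runs BH on the adj_p column first (off
    by default: inputs are assumed pre-adjusted).
    """
    if not fc_down < 1 < fc_up:
        raise ParameterError(f"need fc_down < 1 < fc_up, got {fc_down}, {fc_up}")
    _validate_table(table)
    fc = table["fc"].astype(float).to_numpy()
    p = table["adj_p"].astype(float).to_numpy()
    if readjust:
        p = bh_adjust(p)
    keep = (p < alpha) & ((fc > fc_up) | (fc < fc_down))
    genes = table["gene"].astype(str).to_numpy()
    directions = {
        g: ("up" if f > fc_up else "down")
        for g, f in zip(genes[keep], fc[keep])
    }
    return DEGSet(
        genes=set(genes[keep]),
        directions=directions,
        source_dataset=table.attrs.get("dataset_id", ""),
    )


def intersect_degs(sets: list[DEGSet]) -> set[str]:
    """Genes present in every DEG set, by identifier only (direction ignored)."""
    if len(sets) < 2:
        raise ParameterError(f"need at least 2 DEG sets, got {len(sets)}")
    common = set(sets[0].genes)
    for s in sets[1:]:
        common &= s.genes
    return common


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
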