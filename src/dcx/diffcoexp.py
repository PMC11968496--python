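"""Condition-specific correlation and differential co-expression edges.

For the common DEGs of a tissue, pairwise correlations are computed per
condition (disease, healthy).  The method is chosen per pair by normality:
Pearson when a Shapiro–Wilk test fails to reject normality for *both* genes'
expression vectors, Spearman otherwise.  Spearman correlations are always
computed as well, because the differential comparison is defined on rank
correlations (SCC).

Two data-driven thresholds define a differentially co-expressed pair:

* ``p_critic = mean|r| + 1.96 * sd|r|`` — a magnitude threshold computed per
  condition over the absolute coefficients of all pairs (sample sd, ddof=1);
* ``|SCC_disease - SCC_healthy| > epsilon`` with ``epsilon = 0.5`` by default.

A pair is emitted as a differential edge iff it is significantly co-expressed
in at least one condition (correlation p < 0.05 and |r| > that condition's
p_critic; the gate is configurable) and the Spearman difference exceeds
epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "CorrelationSummary",
    "zscore_normalize",
    "select_method",
    "pairwise_correlations",
    "compute_p_critic",
    "differential_edges",
]

Condition = Literal["disease", "healthy"]


@dataclass(frozen=True)
class CorrelationSummary:
    """Per-condition summary of the |coefficient| distribution (magnitude threshold)."""

    condition: str
    mean_scc: float
    std_scc: float

    @property
    def p_critic(self) -> float:
        return self.mean_scc + 1.96 * self.std_scc


def zscore_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each gene row to mean 0 and sample sd 1 (ddof=1).

    Returns the normalized matrix and the list of zero-variance genes, which
    are excluded from the output (they carry no correlation information).
    """
    if matrix.shape[1] < 2:
        raise ParameterError("need at least 2 samples to normalize")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    excluded = list(matrix.index[flat])
    kept = values[~flat]
    kept = (kept - kept.mean(axis=1, keepdims=True)) / sd[~flat, None]
    return pd.DataFrame(kept, index=matrix.index[~flat], columns=matrix.columns), excluded


def select_method(values_a, values_b, alpha: float = 0.05) -> str:
    """'pearson' iff Shapiro–Wilk fails to reject normality for both vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ParameterError("need at least 3 observations for the normality test")
    pa = stats.shapiro(a).pvalue
    pb = stats.shapiro(b).pvalue
    return "pearson" if (pa > alpha and pb > alpha) else "spearman"


def _pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t distribution on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pairwise_correlations(
    matrix: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered gene-pair correlations for one condition.

    Normality is tested per gene on the raw values; correlation coefficients
    are computed on the same values (both Pearson and Spearman are invariant
    under the per-gene affine z-score transform).  Output columns:
    gene_a, gene_b, coefficient, p_value, method, condition, significant,
    scc, scc_p (the Spearman pair, kept for the differential stage).
    Pairs are stored once with gene_a < gene_b.
    """
    n_genes, n_samples = matrix.shape
    if n_samples < 4:
        raise ParameterError(f"need at least 4 samples, got {n_samples}")
    if n_genes < 2:
        raise ParameterError(f"need at least 2 genes, got {n_genes}")
    values = matrix.to_numpy(dtype=float)
    genes = matrix.index.to_numpy(dtype=object)

    # per-gene normality; a pair is "normal" only if both genes pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns on n > 5000 / ties
        normal = np.array(
            [stats.shapiro(row).pvalue > normality_alpha for row in values]
        )

    rho, rho_p = stats.spearmanr(values, axis=1)
    if n_genes == 2:  # scipy collapses the 2x2 case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        rho_p = np.array([[0.0, float(rho_p)], [float(rho_p), 0.0]])
    pear = np.corrcoef(values)
    pear_p = _pearson_pvalues(pear, n_samples)

    ia, ib = np.triu_indices(n_genes, 1)
    pair_normal = normal[ia] & normal[ib]
    coef = np.where(pair_normal, pear[ia, ib], rho[ia, ib])
    pval = np.where(pair_normal, pear_p[ia, ib], rho_p[ia, ib])
    out = pd.DataFrame(
        {
            "gene_a": genes[ia],
            "gene_b": genes[ib],
            "coefficient": coef,
            "p_value": pval,
            "method": np.where(pair_normal, "pearson", "spearman"),
            "condition": condition,
            "significant": pval < alpha,
            "scc": rho[ia, ib],
            "scc_p": rho_p[ia, ib],
        }
    )
    # canonical unordered-pair ordering
    swap = out["gene_a"] > out["gene_b"]
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    return out


def compute_p_critic(correlations: pd.DataFrame) -> CorrelationSummary:
    """Magnitude threshold mean|r| + 1.96*sd|r| over one condition's pairs."""
    if len(correlations) == 0:
        raise ParameterError("empty correlation list")
    conditions = set(correlations["condition"])
    if len(conditions) != 1:
        raise ParameterError(f"expected a single condition, got {sorted(conditions)}")
    magnitudes = correlations["coefficient"].abs().to_numpy(dtype=float)
    if magnitudes.size == 1:
        warnings.warn("single correlation: std set to 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(magnitudes.std(ddof=1))
    return CorrelationSummary(conditions.pop(), float(magnitudes.mean()), sd)


def differential_edges(
    disease: pd.DataFrame,
    healthy: pd.DataFrame,
    epsilon: float = 0.5,
    alpha: float = 0.05,
    pcritic_gate: Literal["any", "both", "none"] = "any",
) -> pd.DataFrame:
    """Differentially co-expressed pairs: gated significance plus the epsilon rule.

    ``scc_d``/``scc_h`` are the chosen coefficients when both conditions used
    the same method for the pair, otherwise both fall back to Spearman (the
    differential statistic is defined on rank correlations).  Pairs present in
    only one condition (e.g. a zero-variance gene) are dropped.
    """
    if not epsilon > 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    key = ["gene_a", "gene_b"]
    merged = disease.merge(healthy, on=key, suffixes=("_d", "_h"), how="inner")
    if merged.empty:
        return pd.DataFrame(columns=key + ["scc_d", "scc_h", "delta"])

    same_method = merged["method_d"] == merged["method_h"]
    scc_d = np.where(same_method, merged["coefficient_d"], merged["scc_d"])
    scc_h = np.where(same_method, merged["coefficient_h"], merged["scc_h"])
    delta = np.abs(scc_d - scc_h)

    pc_d = compute_p_critic(disease).p_critic
    pc_h = compute_p_critic(healthy).p_critic
    sig_d = (merged["p_value_d"] < alpha) & (merged["coefficient_d"].abs() > pc_d)
    sig_h = (merged["p_value_h"] < alpha) & (merged["coefficient_h"].abs() > pc_h)
    if pcritic_gate == "any":
        gate = sig_d | sig_h
    elif pcritic_gate == "both":
        gate = sig_d & sig_h
    elif pcritic_gate == "none":
        gate = (merged["p_value_d"] < alpha) | (merged["p_value_h"] < alpha)
    else:
        raise ParameterError(f"unknown pcritic_gate {pcritic_gate!r}")

    keep = gate.to_numpy() & (delta > epsilon)
    out = pd.DataFrame(
        {
            "gene_a": merged["gene_a"],
            "gene_b": merged["gene_b"],
            "scc_d": scc_d,
            "scc_h": scc_h,
            "delta": delta,
        }
    )[keep]
    return out.reset_index(drop=True)
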