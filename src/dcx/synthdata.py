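"""Synthetic two-condition expression data with planted differential co-expression.

The generator emulates the statistical regime the downstream analysis assumes:
a block of "module" genes that is equicorrelated (pairwise correlation
``rho_disease``) in the disease condition and (``rho_healthy``) in the healthy
condition, a background of mutually independent genes, a mean shift on the
differentially expressed genes in the disease condition, drug signatures whose
fold changes reverse those shifts, and literature co-mention count tables that
contain zero-co-mention (novel) drugs.

Expression values are Gaussian on a log-like scale.  Because every correlation
step downstream is rank-based (or affine-invariant), only the correlation
structure and mean shifts matter, not marginal shapes.

All generators take an explicit seed and own a single ``numpy.random.Generator``
stream; identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_expression",
    "generate_drug_signatures",
    "generate_literature_counts",
    "generate_de_tables",
    "generate_gene_sets",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-structure expression generator.

    Defaults mirror the small-cohort regime of the study design this emulates:
    13 disease vs 8 healthy samples, a 15-gene module inside a 100-gene
    background, strong disease-specific co-expression and a 2-fold mean shift.
    """

    n_genes: int = 100
    n_module_genes: int = 15
    n_disease_samples: int = 13
    n_healthy_samples: int = 8
    rho_disease: float = 0.85
    rho_healthy: float = 0.05
    de_log2_effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_module_genes < 0:
            raise ParameterError("gene counts must be non-negative")
        if self.n_module_genes > self.n_genes:
            raise ParameterError(
                f"n_module_genes={self.n_module_genes} exceeds n_genes={self.n_genes}"
            )
        for name in ("rho_disease", "rho_healthy"):
            rho = getattr(self, name)
            if not abs(rho) < 1:
                raise ParameterError(f"|{name}| must be < 1, got {rho}")
            # an equicorrelated m-block is a valid covariance only for rho >= -1/(m-1)
            if self.n_module_genes >= 2 and rho < -1.0 / (self.n_module_genes - 1):
                raise ParameterError(
                    f"{name}={rho} below -1/(m-1) for m={self.n_module_genes}"
                )
        if not self.noise_sd > 0:
            raise ParameterError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass
class GroundTruth:
    """Planted structure: which genes/drugs carry signal.

    ``reversing_drugs`` and ``novel_drugs`` start empty and are filled in by
    :func:`generate_drug_signatures` / :func:`generate_literature_counts`,
    since drug identifiers do not exist until those tables are generated.
    """

    module_genes: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    reversing_drugs: set[str] = field(default_factory=set)
    novel_drugs: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {k: sorted(v) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: set(v) for k, v in payload.items()})


def _equicorrelated(m: int, n: int, rho: float, sd: float,
                    generator: np.random.Generator) -> np.ndarray:
    """Draw an m-gene x n-sample block with pairwise correlation rho."""
    cov = np.full((m, m), rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    cov *= sd * sd
    chol = np.linalg.cholesky(cov)
    z = generator.standard_normal((m, n))
    return chol @ z


def generate_expression(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate disease and healthy expression matrices (genes x samples).

    Module genes are drawn from an equicorrelated Gaussian block with pairwise
    correlation ``rho_disease`` (disease) / ``rho_healthy`` (healthy);
    background genes are i.i.d. noise.  DE genes (= the module genes) receive
    a ``de_log2_effect`` mean shift in the disease matrix.  Gene and sample
    identifiers are stable across the two matrices.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    m = config.n_module_genes
    module = genes[:m]
    # the DE set is larger than the dense module, as in real cohorts where the
    # common DEGs far outnumber any single co-expression module: the module
    # genes plus (up to) twice as many independent background genes
    n_extra = min(2 * m, config.n_genes - m)
    de_genes = genes[: m + n_extra]
    truth = GroundTruth(module_genes=set(module), de_genes=set(de_genes))

    def one_condition(rho: float, n_samples: int, shifted: bool) -> pd.DataFrame:
        cols = [f"s{j:03d}" for j in range(n_samples)]
        data = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        if m >= 2 and n_samples > 0:
            data[:m, :] = _equicorrelated(m, n_samples, rho, config.noise_sd, rng)
        if shifted and de_genes:
            data[: len(de_genes), :] += config.de_log2_effect
        return pd.DataFrame(data, index=genes, columns=cols)

    disease = one_condition(config.rho_disease, config.n_disease_samples, True)
    healthy = one_condition(config.rho_healthy, config.n_healthy_samples, False)
    disease.columns = [f"d{j:03d}" for j in range(config.n_disease_samples)]
    healthy.columns = [f"h{j:03d}" for j in range(config.n_healthy_samples)]
    disease.index.name = healthy.index.name = "gene"
    return disease, healthy, truth


def generate_drug_signatures(
    truth: GroundTruth,
    n_drugs: int,
    seed: int,
    n_reversing: int = 3,
) -> pd.DataFrame:
    """Per-(drug, gene) signature table emulating a perturbation-database export.

    Reversing drugs carry fold changes opposite in direction to the planted DE
    shift on every DE gene, with p and q below 0.05; non-reversing drugs stay
    inside the (0.67, 1.5) dead zone.  Columns: drug, gene, drug_fc, p_value,
    q_value, specificity, source_id.

    If ``truth.reversing_drugs`` is empty it is populated in place with
    ``n_reversing`` planted drug identifiers.
    """
    if n_drugs < 0:
        raise ParameterError("n_drugs must be non-negative")
    if not truth.reversing_drugs:
        truth.reversing_drugs = {f"drug_r{i:02d}" for i in range(min(n_reversing, n_drugs))}
    if n_drugs < len(truth.reversing_drugs):
        raise ParameterError(
            f"n_drugs={n_drugs} smaller than the {len(truth.reversing_drugs)} reversing drugs"
        )
    rng = np.random.default_rng(seed)
    reversing = sorted(truth.reversing_drugs)
    others = [f"drug_b{i:03d}" for i in range(n_drugs - len(reversing))]
    genes = sorted(truth.de_genes)
    rows = []
    for drug in reversing + others:
        is_rev = drug in truth.reversing_drugs
        for gene in genes:
            if is_rev:
                # DE genes are shifted up in disease; a reversing drug pushes them down
                fc = rng.uniform(0.3, 0.6)
                p = rng.uniform(1e-4, 0.04)
                q = rng.uniform(p, 0.049)
            else:
                fc = rng.uniform(0.8, 1.3)
                p = rng.uniform(1e-3, 1.0)
                q = min(1.0, p * rng.uniform(1.0, 2.0))
            rows.append(
                (drug, gene, fc, p, q, rng.uniform(0, 1), f"sig_{drug}_{gene}")
            )
    return pd.DataFrame(
        rows,
        columns=["drug", "gene", "drug_fc", "p_value", "q_value", "specificity", "source_id"],
    )


def generate_literature_counts(
    drugs: list[str], n_novel: int, seed: int
) -> pd.DataFrame:
    """Literature co-mention counts with exactly ``n_novel`` zero-co-mention drugs.

    Columns: drug, n_articles, n_disease_articles.  Every drug has at least one
    article; novel drugs have zero disease co-mentions, the rest at least one.
    """
    if n_novel > len(drugs):
        raise ParameterError(f"n_novel={n_novel} exceeds the {len(drugs)} drugs given")
    rng = np.random.default_rng(seed)
    novel = set(rng.choice(np.array(drugs, dtype=object), size=n_novel, replace=False)) if n_novel else set()
    rows = []
    for drug in drugs:
        n_articles = int(np.rint(rng.lognormal(mean=6.0, sigma=1.5))) + 1
        if drug in novel:
            n_disease = 0
        else:
            n_disease = min(n_articles, 1 + rng.poisson(5))
        rows.append((drug, n_articles, n_disease))
    return pd.DataFrame(rows, columns=["drug", "n_articles", "n_disease_articles"])


def generate_de_tables(
    truth: GroundTruth,
    config: SynthConfig,
    dataset_ids: tuple[str, ...] = ("ds1", "ds2"),
    n_unique: int = 5,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-dataset DE result tables consistent with the planted truth.

    Plumbing for the end-to-end pipeline: every planted DE gene is significant
    with fold change 2**de_log2_effect (jittered) in every dataset; each
    dataset also gets ``n_unique`` private pseudo-DEGs so that cross-dataset
    intersection is a non-trivial operation.  Columns: gene, fc, adj_p.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    available = [g for g in genes if g not in truth.de_genes]
    tables: dict[str, pd.DataFrame] = {}
    for ds in dataset_ids:
        # private pseudo-DEGs are disjoint across datasets so the planted
        # intersection is exactly the shared DE set
        uniq = set(
            rng.choice(np.array(available, dtype=object),
                       size=min(n_unique, len(available)), replace=False)
        )
        available = [g for g in available if g not in uniq]
        rows = []
        for g in genes:
            if g in truth.de_genes or g in uniq:
                fc = 2.0 ** (config.de_log2_effect + rng.normal(0, 0.1))
                fc = max(fc, 1.6)  # keep planted DEGs above the up threshold
                adj_p = rng.uniform(1e-5, 0.01)
            else:
                fc = 2.0 ** rng.normal(0, 0.1)
                adj_p = rng.uniform(0.06, 1.0)
            rows.append((g, fc, adj_p))
        tables[ds] = pd.DataFrame(rows, columns=["gene", "fc", "adj_p"])
    return tables


def generate_gene_sets(
    truth: GroundTruth,
    config: SynthConfig,
    n_decoy_sets: int = 10,
    decoy_size: int = 15,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """A synthetic gene-set collection: the planted module plus decoy sets."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = np.array([f"g{i:04d}" for i in range(config.n_genes)], dtype=object)
    sets = {"planted_module": set(truth.module_genes)}
    background = np.array([g for g in genes if g not in truth.module_genes], dtype=object)
    for i in range(n_decoy_sets):
        size = min(decoy_size, len(background))
        if size == 0:
            break
        sets[f"decoy_{i:02d}"] = set(rng.choice(background, size=size, replace=False))
    return sets
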