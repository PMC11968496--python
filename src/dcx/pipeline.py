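"""End-to-end orchestration: DEGs -> differential co-expression -> clusters ->
enrichment -> ML validation -> drug repurposing -> literature novelty.

The pipeline runs per named tissue group on synthetic inputs generated from a
:class:`~dcx.synthdata.SynthConfig` (real tables can be substituted stage by
stage through the library API), then intersects candidate drugs across tissues
and scores their literature novelty.  Every stage's parameters, output-file
digests and wall time are recorded in a run manifest so identical (config,
seed) reruns are verifiable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import degstage, diffcoexp, enrich, litnovelty, mlvalidate, netmod, repurpose, synthdata
from .errors import ParameterError

__all__ = ["PipelineConfig", "StageFailure", "run_pipeline"]

log = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    tissues: dict[str, synthdata.SynthConfig] = field(default_factory=dict)
    degs: dict = field(default_factory=lambda: {"fc_up": 1.5, "fc_down": 0.67, "alpha": 0.05})
    edges: dict = field(default_factory=lambda: {"epsilon": 0.5, "alpha": 0.05, "pcritic_gate": "any"})
    mcode: dict = field(default_factory=lambda: {"node_score_cutoff": 0.2, "degree_cutoff": 2, "k_core": 2})
    cluster_select: dict = field(default_factory=lambda: {"min_score": 10.0, "max_keep": 1})
    drugs: dict = field(default_factory=lambda: {"n_drugs": 20, "n_reversing": 3})
    novelty: dict = field(default_factory=lambda: {"n_novel": 2})
    ml: dict = field(default_factory=lambda: {"models": list(mlvalidate.FAST_MODELS)})

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.tissues:
            # default two-tissue layout mirroring a muscle / motor-neuron design,
            # at a cohort size where the epsilon filter has power
            self.tissues = {
                "muscle": synthdata.SynthConfig(
                    n_disease_samples=40, n_healthy_samples=40, seed=self.seed
                ),
                "motor_neuron": synthdata.SynthConfig(
                    n_disease_samples=40, n_healthy_samples=40, seed=self.seed + 1
                ),
            }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tissues = {
            name: synthdata.SynthConfig(**params)
            for name, params in (raw.pop("tissues", {}) or {}).items()
        }
        if "outdir" not in raw:
            raise ParameterError("config must set outdir")
        return cls(tissues=tissues, **raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self) -> None:
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, params: dict, outputs: list[Path], wall: float) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {str(p): _digest(p) for p in outputs},
            "wall_time_s": round(wall, 4),
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.stages, indent=2, default=str) + "\n")


def _stage(manifest: _Manifest, name: str, params: dict):
    """Context manager: time a stage, record outputs, convert failures."""

    class _Ctx:
        def __init__(self) -> None:
            self.outputs: list[Path] = []

        def __enter__(self):
            self._t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageFailure(name, exc) from exc
            manifest.record(name, params, self.outputs, time.perf_counter() - self._t0)
            log.info("stage %s: done (%.2fs)", name, time.perf_counter() - self._t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Any stage failure aborts with :class:`StageFailure` naming the stage;
    partial outputs are kept and a FAILED marker file names the failed stage.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest()
    candidate_sets: dict[str, set[str]] = {}
    all_truths: dict[str, synthdata.GroundTruth] = {}
    try:
        for tissue, synth_cfg in config.tissues.items():
            tdir = out / tissue
            tdir.mkdir(exist_ok=True)

            with _stage(manifest, f"{tissue}/simulate", synth_cfg.__dict__) as st:
                disease, healthy, truth = synthdata.generate_expression(synth_cfg)
                all_truths[tissue] = truth
                d_path, h_path = tdir / "expression_disease.tsv", tdir / "expression_healthy.tsv"
                disease.to_csv(d_path, sep="\t")
                healthy.to_csv(h_path, sep="\t")
                truth.to_json(tdir / "ground_truth.json")
                st.outputs += [d_path, h_path, tdir / "ground_truth.json"]

            with _stage(manifest, f"{tissue}/degs", config.degs) as st:
                tables = synthdata.generate_de_tables(truth, synth_cfg)
                sets = [
                    degstage.filter_degs(tbl, **config.degs) for tbl in tables.values()
                ]
                common = sorted(degstage.intersect_degs(sets))
                (tdir / "common_degs.txt").write_text("\n".join(common) + "\n")
                st.outputs.append(tdir / "common_degs.txt")

            with _stage(manifest, f"{tissue}/coexpress", {"alpha": config.edges["alpha"]}) as st:
                sub_d = disease.loc[common]
                sub_h = healthy.loc[common]
                norm_d, dropped_d = diffcoexp.zscore_normalize(sub_d)
                norm_h, dropped_h = diffcoexp.zscore_normalize(sub_h)
                kept = sorted(set(norm_d.index) & set(norm_h.index))
                if dropped_d or dropped_h:
                    log.warning("zero-variance genes dropped: %s", dropped_d + dropped_h)
                corr_d = diffcoexp.pairwise_correlations(sub_d.loc[kept], "disease", config.edges["alpha"])
                corr_h = diffcoexp.pairwise_correlations(sub_h.loc[kept], "healthy", config.edges["alpha"])
                for name, corr in (("disease", corr_d), ("healthy", corr_h)):
                    p = tdir / f"correlations_{name}.tsv"
                    corr.to_csv(p, sep="\t", index=False)
                    st.outputs.append(p)

            with _stage(manifest, f"{tissue}/edges", config.edges) as st:
                edges = diffcoexp.differential_edges(corr_d, corr_h, **config.edges)
                p = tdir / "differential_edges.tsv"
                edges.to_csv(p, sep="\t", index=False)
                st.outputs.append(p)
                if edges.empty:
                    log.warning("%s: no differential edges at epsilon=%s",
                                tissue, config.edges["epsilon"])

            with _stage(manifest, f"{tissue}/cluster", {**config.mcode, **config.cluster_select}) as st:
                graph = netmod.graph_from_edges(edges)
                clusters = netmod.mcode_cluster(graph, **config.mcode)
                selected = netmod.select_significant(clusters, **config.cluster_select)
                netmod.clusters_to_json(clusters, tdir / "clusters.json")
                netmod.clusters_to_json(selected, tdir / "clusters_selected.json")
                st.outputs += [tdir / "clusters.json", tdir / "clusters_selected.json"]
                cluster_genes = set(selected[0].member_nodes) if selected else set()

            if cluster_genes:
                with _stage(manifest, f"{tissue}/enrich", {}) as st:
                    collection = enrich.GeneSetCollection(
                        synthdata.generate_gene_sets(truth, synth_cfg), source="synthetic"
                    )
                    results = enrich.enrich_cluster(cluster_genes, collection)
                    p = tdir / "enrichment.tsv"
                    results.to_csv(p, sep="\t", index=False)
                    st.outputs.append(p)

                with _stage(manifest, f"{tissue}/validate", config.ml) as st:
                    genes = sorted(cluster_genes & set(disease.index))
                    features = pd.concat([disease.loc[genes], healthy.loc[genes]], axis=1)
                    labels = ["disease"] * disease.shape[1] + ["healthy"] * healthy.shape[1]
                    reports = mlvalidate.evaluate_panel(
                        features, labels, config.ml["models"], seed=config.seed
                    )
                    p = tdir / "classification.tsv"
                    mlvalidate.reports_to_frame(reports).to_csv(p, sep="\t", index=False)
                    st.outputs.append(p)

                with _stage(manifest, f"{tissue}/repurpose", config.drugs) as st:
                    signatures = synthdata.generate_drug_signatures(
                        truth, config.drugs["n_drugs"], seed=synth_cfg.seed,
                        n_reversing=config.drugs["n_reversing"],
                    )
                    p = tdir / "drug_signatures.csv"
                    signatures.to_csv(p, index=False)
                    candidates = repurpose.filter_drug_candidates(
                        signatures, cluster_genes=cluster_genes
                    )
                    candidate_sets[tissue] = candidates
                    cp = tdir / "drug_candidates.txt"
                    cp.write_text("\n".join(sorted(candidates)) + "\n")
                    st.outputs += [p, cp]
            else:
                log.warning("%s: no significant cluster; downstream stages skipped", tissue)
                candidate_sets[tissue] = set()

        with _stage(manifest, "common_candidates", {}) as st:
            names = list(candidate_sets)
            common_drugs = set.union(set(), *candidate_sets.values()) if candidate_sets else set()
            if len(names) >= 2:
                common_drugs = repurpose.common_candidates(
                    candidate_sets[names[0]], candidate_sets[names[1]]
                )
                for extra in names[2:]:
                    common_drugs &= candidate_sets[extra]
            p = out / "common_candidates.txt"
            p.write_text("\n".join(sorted(common_drugs)) + "\n")
            st.outputs.append(p)

        if common_drugs:
            with _stage(manifest, "novelty", config.novelty) as st:
                counts = synthdata.generate_literature_counts(
                    sorted(common_drugs),
                    min(config.novelty["n_novel"], len(common_drugs)),
                    seed=config.seed,
                )
                scores = litnovelty.score_novelty(counts)
                report = litnovelty.novelty_report(scores)
                p = out / "novelty_report.tsv"
                report.to_csv(p, sep="\t", index=False)
                st.outputs.append(p)
        else:
            log.warning("no common candidate drugs; novelty stage skipped")
    except StageFailure as failure:
        (out / "FAILED").write_text(failure.stage + "\n")
        raise
    finally:
        manifest.write(out / "manifest.json")
    return manifest.stages
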