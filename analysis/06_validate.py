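"""Classifier-panel validation: how well do the cluster genes separate
disease from healthy samples, per cluster and per gene?
"""

import json

import pandas as pd
from common import SEED, TISSUES, tissue_dir

from dcx import mlvalidate


def main() -> None:
    for tissue in TISSUES:
        out = tissue_dir(tissue)
        selected = json.loads((out / "clusters_selected.json").read_text())
        if not selected:
            print(f"{tissue}: no significant cluster, skipping validation")
            continue
        genes = selected[0]["members"]
        disease = pd.read_csv(out / "expression_disease.tsv", sep="\t", index_col=0)
        healthy = pd.read_csv(out / "expression_healthy.tsv", sep="\t", index_col=0)
        features = pd.concat([disease.loc[genes], healthy.loc[genes]], axis=1)
        labels = ["disease"] * disease.shape[1] + ["healthy"] * healthy.shape[1]

        reports = mlvalidate.evaluate_panel(features, labels, seed=SEED)
        frame = mlvalidate.reports_to_frame(reports)
        frame.to_csv(out / "classification.tsv", sep="\t", index=False)
        best = frame.sort_values("accuracy", ascending=False).iloc[0]
        print(f"{tissue}: cluster of {len(genes)} genes; best model "
              f"{best['model_name']} accuracy={best['accuracy']:.3f} "
              f"f1={best['f1']:.3f} recall={best['recall']:.3f}")

        per_gene = mlvalidate.per_gene_panel(
            features, labels, models=list(mlvalidate.FAST_MODELS), seed=SEED)
        per_gene.to_csv(out / "per_gene_accuracy.tsv", sep="\t", index=False)
        top = per_gene.sort_values("accuracy", ascending=False).iloc[0]
        print(f"  best single gene: {top['gene']} ({top['model_name']}, "
              f"accuracy={top['accuracy']:.2f})")


if __name__ == "__main__":
    main()
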