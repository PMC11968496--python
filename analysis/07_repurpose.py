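"""Drug repurposing: filter signatures that perturb cluster genes, intersect
candidates across tissues, and benchmark the fold-change regression panel.
"""

import json

import pandas as pd
from common import RESULTS, SEED, TISSUES, tissue_dir

from dcx import degstage, repurpose, synthdata


def main() -> None:
    candidate_sets = {}
    for tissue, cfg in TISSUES.items():
        out = tissue_dir(tissue)
        selected = json.loads((out / "clusters_selected.json").read_text())
        if not selected:
            print(f"{tissue}: no cluster, skipping")
            candidate_sets[tissue] = set()
            continue
        cluster_genes = set(selected[0]["members"])
        truth = synthdata.GroundTruth.from_json(out / "ground_truth.json")
        signatures = synthdata.generate_drug_signatures(truth, n_drugs=20, seed=cfg.seed)
        signatures.to_csv(out / "drug_signatures.csv", index=False)
        candidates = repurpose.filter_drug_candidates(signatures, cluster_genes=cluster_genes)
        candidate_sets[tissue] = candidates
        (out / "drug_candidates.txt").write_text("\n".join(sorted(candidates)) + "\n")
        print(f"{tissue}: {len(candidates)} candidate drugs "
              f"(planted reversing: {sorted(truth.reversing_drugs)})")

        # regression panel: predict drug FC from gene disease-FC + gene identity
        gene_fcs = {}
        for path in sorted(out.glob("de_table_*.csv")):
            for _, row in degstage.read_de_table(path).iterrows():
                gene_fcs.setdefault(row["gene"], []).append(row["fc"])
        gene_fcs = {g: sum(v) / len(v) for g, v in gene_fcs.items()}
        sub = signatures[signatures["gene"].isin(cluster_genes)]
        X, y = repurpose.build_design(sub, {g: gene_fcs[g] for g in cluster_genes})
        predictions = repurpose.predict_fc_panel(X, y, seed=SEED)
        predictions.to_csv(out / "drug_fc_predictions.tsv", sep="\t", index=False)
        errors = predictions.groupby("model_name")["cv_error"].first().sort_values()
        print("  cv MAE by model: "
              + ", ".join(f"{m}={e:.3f}" for m, e in errors.items()))

    names = list(candidate_sets)
    common = repurpose.common_candidates(candidate_sets[names[0]], candidate_sets[names[1]])
    (RESULTS / "common_candidates.txt").write_text("\n".join(sorted(common)) + "\n")
    print(f"common candidates across tissues: {sorted(common)}")


if __name__ == "__main__":
    main()
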