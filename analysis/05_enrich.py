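"""Over-representation analysis of each tissue's significant cluster against a
synthetic gene-set collection (the planted module among decoy sets).
"""

import json

from common import TISSUES, tissue_dir

from dcx import enrich, synthdata


def main() -> None:
    for tissue, cfg in TISSUES.items():
        out = tissue_dir(tissue)
        selected = json.loads((out / "clusters_selected.json").read_text())
        if not selected:
            print(f"{tissue}: no significant cluster, skipping enrichment")
            continue
        cluster_genes = set(selected[0]["members"])
        truth = synthdata.GroundTruth.from_json(out / "ground_truth.json")
        collection = enrich.GeneSetCollection(
            synthdata.generate_gene_sets(truth, cfg), source="synthetic"
        )
        results = enrich.enrich_cluster(cluster_genes, collection)
        results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        top = results.iloc[0]
        print(f"{tissue}: top set {top['set_name']!r} overlap={top['overlap']}/"
              f"{top['set_size']} q={top['q_value']:.3g} rich_factor={top['rich_factor']:.2f}; "
              f"{int(results['significant'].sum())} significant sets")


if __name__ == "__main__":
    main()
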