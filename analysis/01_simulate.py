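"""Generate the two synthetic tissue cohorts and their per-dataset DE tables.

Writes, per tissue: expression matrices (disease / healthy), the planted
ground truth, and two DE result tables whose shared significant genes are the
planted DE set.
"""

from common import TISSUES, tissue_dir

from dcx import synthdata


def main() -> None:
    for tissue, cfg in TISSUES.items():
        out = tissue_dir(tissue)
        disease, healthy, truth = synthdata.generate_expression(cfg)
        disease.to_csv(out / "expression_disease.tsv", sep="\t")
        healthy.to_csv(out / "expression_healthy.tsv", sep="\t")
        truth.to_json(out / "ground_truth.json")
        for ds, table in synthdata.generate_de_tables(truth, cfg).items():
            table.to_csv(out / f"de_table_{ds}.csv", index=False)
        print(f"{tissue}: {cfg.n_genes} genes, "
              f"{cfg.n_disease_samples}+{cfg.n_healthy_samples} samples, "
              f"module of {cfg.n_module_genes}, {len(truth.de_genes)} DE genes -> {out}")


if __name__ == "__main__":
    main()
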