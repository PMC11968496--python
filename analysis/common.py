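"""Shared settings for the numbered analysis scripts.

Two synthetic tissue cohorts (muscle, motor neuron) with a planted 15-gene
differential co-expression module each, 40 samples per condition, and a
2-fold mean shift on the DE genes.  All scripts read and write under
``results/`` relative to the repository root.
"""

from pathlib import Path

from dcx import synthdata

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1

TISSUES = {
    "muscle": synthdata.SynthConfig(
        n_genes=100, n_module_genes=15, n_disease_samples=40, n_healthy_samples=40,
        rho_disease=0.85, rho_healthy=0.05, de_log2_effect=1.0, seed=SEED,
    ),
    "motor_neuron": synthdata.SynthConfig(
        n_genes=100, n_module_genes=15, n_disease_samples=40, n_healthy_samples=40,
        rho_disease=0.85, rho_healthy=0.05, de_log2_effect=1.0, seed=SEED + 1,
    ),
}


def tissue_dir(tissue: str) -> Path:
    d = RESULTS / tissue
    d.mkdir(parents=True, exist_ok=True)
    return d
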