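import numpy as np
import pytest

from dcx import diffcoexp, netmod, synthdata

RECOVERY_SEED = 1


@pytest.fixture(scope="session")
def recovery_run():
    """Planted-module regime: 15-gene module, rho 0.85 vs 0.05, 40 samples/condition."""
    cfg = synthdata.SynthConfig(
        n_genes=60, n_module_genes=15, n_disease_samples=40, n_healthy_samples=40,
        rho_disease=0.85, rho_healthy=0.05, seed=RECOVERY_SEED,
    )
    disease, healthy, truth = synthdata.generate_expression(cfg)
    corr_d = diffcoexp.pairwise_correlations(disease, "disease")
    corr_h = diffcoexp.pairwise_correlations(healthy, "healthy")
    edges = diffcoexp.differential_edges(corr_d, corr_h)
    clusters = netmod.mcode_cluster(netmod.graph_from_edges(edges))
    return {"config": cfg, "truth": truth, "corr_d": corr_d, "corr_h": corr_h,
            "edges": edges, "clusters": clusters}


@pytest.fixture(scope="session")
def null_run():
    """No planted structure anywhere: rho 0 in both conditions, 100 samples each."""
    cfg = synthdata.SynthConfig(
        n_genes=60, n_module_genes=15, n_disease_samples=100, n_healthy_samples=100,
        rho_disease=0.0, rho_healthy=0.0, seed=RECOVERY_SEED,
    )
    disease, healthy, _ = synthdata.generate_expression(cfg)
    corr_d = diffcoexp.pairwise_correlations(disease, "disease")
    corr_h = diffcoexp.pairwise_correlations(healthy, "healthy")
    edges = diffcoexp.differential_edges(corr_d, corr_h)
    n_pairs = cfg.n_genes * (cfg.n_genes - 1) // 2
    return {"edges": edges, "n_pairs": n_pairs}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
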