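"""Correlation machinery: normalization, method choice, p_critic, the epsilon filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcx import diffcoexp
from dcx.errors import ParameterError


def matrix(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(rows.shape[1])])


class TestZscoreNormalize:
    def test_symmetric_row(self):
        out, excluded = diffcoexp.zscore_normalize(matrix([[1, 2, 3]]))
        np.testing.assert_allclose(out.iloc[0], [-1, 0, 1])
        assert excluded == []

    def test_constant_row_flagged_and_excluded(self):
        out, excluded = diffcoexp.zscore_normalize(matrix([[5, 5, 5], [1, 2, 3]]))
        assert excluded == ["g0"]
        assert list(out.index) == ["g1"]

    def test_output_moments(self, rng):
        out, _ = diffcoexp.zscore_normalize(matrix(rng.normal(size=(10, 25))))
        values = out.to_numpy()
        np.testing.assert_allclose(values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            diffcoexp.zscore_normalize(matrix([[1.0]]))


class TestSelectMethod:
    def test_gaussian_pair_rate_matches_shapiro_size(self):
        # P(pearson) for two Gaussian vectors ~ (1 - alpha)^2
        rng = np.random.default_rng(42)
        picks = [
            diffcoexp.select_method(rng.normal(size=50), rng.normal(size=50))
            for _ in range(1000)
        ]
        rate = picks.count("pearson") / len(picks)
        assert rate == pytest.approx(0.95**2, abs=0.03)

    def test_exponential_vector_forces_spearman(self):
        rng = np.random.default_rng(7)
        picks = [
            diffcoexp.select_method(rng.exponential(size=100), rng.normal(size=100))
            for _ in range(500)
        ]
        assert picks.count("spearman") / len(picks) >= 0.99

    def test_invariant_under_joint_permutation(self, rng):
        a, b = rng.normal(size=12), rng.exponential(size=12)
        perm = rng.permutation(12)
        assert diffcoexp.select_method(a, b) == diffcoexp.select_method(a[perm], b[perm])

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            diffcoexp.select_method([1, 2, 3], [1, 2])


class TestPairwiseCorrelations:
    def test_perfect_monotone_pair(self):
        out = diffcoexp.pairwise_correlations(
            matrix([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]]), "disease")
        assert out["coefficient"].iloc[0] == pytest.approx(1.0)

    def test_anti_monotone_pair(self):
        out = diffcoexp.pairwise_correlations(
            matrix([[1, 2, 3, 4, 5], [10, 8, 6, 4, 2]]), "disease")
        assert out["coefficient"].iloc[0] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self):
        # one swap away from a perfect anti-ranking; closed form 1 - 6*sum(d^2)/(n(n^2-1))
        a = [1, 2, 3, 4, 5, 6]
        b = [6, 5, 4, 3, 1, 2]
        d2 = sum((ra - rb) ** 2 for ra, rb in zip(
            stats.rankdata(a), stats.rankdata(b)))
        expected = 1 - 6 * d2 / (6 * 35)
        out = diffcoexp.pairwise_correlations(matrix([a, b]), "disease")
        value = float(stats.spearmanr(a, b).statistic)
        assert value == pytest.approx(expected)
        assert out["scc"].iloc[0] == pytest.approx(expected)

    def test_symmetry_under_sample_permutation(self, rng):
        m = matrix(rng.normal(size=(5, 12)))
        base = diffcoexp.pairwise_correlations(m, "disease")
        perm = rng.permutation(12)
        permuted = diffcoexp.pairwise_correlations(m.iloc[:, perm], "disease")
        np.testing.assert_allclose(base["coefficient"], permuted["coefficient"], atol=1e-12)

    def test_scale_invariance_of_spearman_branch(self, rng):
        m = matrix(rng.exponential(size=(4, 15)))  # exponential rows -> spearman
        base = diffcoexp.pairwise_correlations(m, "disease")
        scaled = diffcoexp.pairwise_correlations(m * 7.3, "disease")
        assert (base["method"] == "spearman").all()
        np.testing.assert_allclose(base["scc"], scaled["scc"], atol=1e-12)

    def test_canonical_pair_ordering(self, rng):
        m = matrix(rng.normal(size=(6, 10)), genes=["z", "c", "q", "a", "m", "b"])
        out = diffcoexp.pairwise_correlations(m, "healthy")
        assert (out["gene_a"] < out["gene_b"]).all()

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            diffcoexp.pairwise_correlations(matrix([[1, 2, 3], [3, 2, 1]]), "disease")


def correlations(coefs, condition="disease", pvals=None, method="spearman"):
    n = len(coefs)
    return pd.DataFrame(
        {
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "coefficient": coefs,
            "p_value": pvals if pvals is not None else [0.01] * n,
            "method": [method] * n,
            "condition": [condition] * n,
            "significant": [True] * n,
            "scc": coefs,
            "scc_p": pvals if pvals is not None else [0.01] * n,
        }
    )


class TestPCritic:
    def test_zero_dispersion(self):
        summary = diffcoexp.compute_p_critic(correlations([0.4, 0.4, 0.4]))
        assert summary.p_critic == pytest.approx(0.4)

    def test_hand_arithmetic(self):
        summary = diffcoexp.compute_p_critic(correlations([0.2, -0.4, 0.6]))
        assert summary.mean_scc == pytest.approx(0.4)
        assert summary.std_scc == pytest.approx(0.2)
        assert summary.p_critic == pytest.approx(0.792)

    def test_identity_holds_exactly(self, rng):
        summary = diffcoexp.compute_p_critic(correlations(rng.uniform(-1, 1, size=50)))
        assert summary.p_critic == summary.mean_scc + 1.96 * summary.std_scc

    def test_never_below_mean(self, rng):
        summary = diffcoexp.compute_p_critic(correlations(rng.uniform(-1, 1, size=9)))
        assert summary.p_critic >= summary.mean_scc

    def test_empty_rejected_and_singleton_warns(self):
        with pytest.raises(ParameterError):
            diffcoexp.compute_p_critic(correlations([]))
        with pytest.warns(UserWarning):
            summary = diffcoexp.compute_p_critic(correlations([0.3]))
        assert summary.std_scc == 0.0


class TestDifferentialEdges:
    def run(self, d_coefs, h_coefs, d_p=None, h_p=None, **kwargs):
        d = correlations(d_coefs, "disease", d_p)
        h = correlations(h_coefs, "healthy", h_p)
        return diffcoexp.differential_edges(d, h, **kwargs)

    def test_clear_pass(self):
        # many moderate pairs keep p_critic low; one strong differential pair
        d = [0.9] + [0.3] * 10
        h = [0.2] + [0.3] * 10
        out = self.run(d, h)
        assert len(out) == 1
        assert out["delta"].iloc[0] == pytest.approx(0.7)

    def test_delta_below_epsilon_dropped(self):
        out = self.run([0.6] + [0.1] * 10, [0.3] + [0.1] * 10)
        assert out.empty

    def test_retention_monotone_in_epsilon(self, rng):
        d = rng.uniform(-1, 1, size=80)
        h = rng.uniform(-1, 1, size=80)
        sizes = [len(self.run(list(d), list(h), epsilon=e)) for e in (0.2, 0.5, 0.8, 1.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_epsilon(self):
        with pytest.raises(ParameterError):
            self.run([0.9], [0.1], epsilon=0.0)

    def test_pairs_missing_in_one_condition_dropped(self):
        d = correlations([0.9, 0.8], "disease")
        h = correlations([0.1], "healthy")
        out = diffcoexp.differential_edges(d, h)
        assert set(out["gene_a"]) <= set(h["gene_a"])

    def test_planted_structure_separation(self):
        """Module pairs are retained, background pairs almost never are.

        Strong-signal regime: rho 0.9 vs 0.0, 100 samples per condition.
        """
        from dcx import synthdata

        cfg = synthdata.SynthConfig(
            n_genes=60, n_module_genes=15, n_disease_samples=100, n_healthy_samples=100,
            rho_disease=0.9, rho_healthy=0.0, seed=1,
        )
        d, h, truth = synthdata.generate_expression(cfg)
        edges = diffcoexp.differential_edges(
            diffcoexp.pairwise_correlations(d, "disease"),
            diffcoexp.pairwise_correlations(h, "healthy"),
        )
        module = truth.module_genes
        in_module = edges["gene_a"].isin(module) & edges["gene_b"].isin(module)
        n_module_pairs = len(module) * (len(module) - 1) // 2
        assert in_module.sum() / n_module_pairs >= 0.9
        n_total = 60 * 59 // 2
        background_rate = (~in_module).sum() / (n_total - n_module_pairs)
        assert background_rate <= 0.01
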