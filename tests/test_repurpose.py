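"""Drug candidate filtering and fold-change regression panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcx import repurpose, synthdata
from dcx.errors import ParameterError, ValidationError


def signature_rows(rows):
    return pd.DataFrame(
        [
            {"drug": d, "gene": g, "drug_fc": fc, "p_value": p, "q_value": q,
             "specificity": 0.5, "source_id": f"{d}_{g}"}
            for d, g, fc, p, q in rows
        ]
    )


class TestFilterDrugCandidates:
    def test_all_gates_passed(self):
        sig = signature_rows([("X", "g1", 0.4, 0.01, 0.02)])
        assert repurpose.filter_drug_candidates(sig) == {"X"}

    def test_fc_dead_zone_blocks(self):
        sig = signature_rows([("Y", "g1", 1.2, 0.001, 0.001)])
        assert repurpose.filter_drug_candidates(sig) == set()

    @pytest.mark.parametrize("p,q", [(0.06, 0.01), (0.01, 0.06)])
    def test_significance_gates(self, p, q):
        sig = signature_rows([("Z", "g1", 2.0, p, q)])
        assert repurpose.filter_drug_candidates(sig) == set()

    def test_malformed_fc_names_row(self):
        sig = signature_rows([("X", "g1", 2.0, 0.01, 0.01), ("X", "g2", -3.0, 0.01, 0.01)])
        with pytest.raises(ValidationError, match="row 1"):
            repurpose.filter_drug_candidates(sig)

    def test_planted_round_trip(self):
        truth = synthdata.GroundTruth(de_genes={f"g{i}" for i in range(6)})
        sig = synthdata.generate_drug_signatures(truth, n_drugs=30, seed=9, n_reversing=5)
        recovered = repurpose.filter_drug_candidates(sig)
        truth_set = truth.reversing_drugs
        precision = len(recovered & truth_set) / len(recovered)
        recall = len(recovered & truth_set) / len(truth_set)
        assert precision == 1.0 and recall == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 0.05),
        st.floats(1.5, 3.0),
        st.floats(0.2, 0.67),
    )
    def test_monotone_in_thresholds(self, alpha, fc_up, fc_down):
        rng = np.random.default_rng(4)
        sig = signature_rows([
            (f"d{i}", "g1", float(rng.uniform(0.1, 3.0)),
             float(rng.uniform(0, 0.1)), float(rng.uniform(0, 0.1)))
            for i in range(30)
        ])
        strict = repurpose.filter_drug_candidates(sig, fc_up=fc_up, fc_down=fc_down, alpha=alpha)
        relaxed = repurpose.filter_drug_candidates(sig, fc_up=1.5, fc_down=0.67, alpha=0.05)
        # fc_up >= 1.5, fc_down <= 0.67, alpha <= 0.05: stricter gates never add drugs
        assert strict <= relaxed


class TestCommonCandidates:
    def test_intersection(self):
        assert repurpose.common_candidates({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}

    def test_disjoint(self):
        assert repurpose.common_candidates({"a"}, {"b"}) == set()

    def test_cardinality_bound(self, rng):
        pool = [f"d{i}" for i in range(20)]
        a = set(rng.choice(pool, 8, replace=False))
        b = set(rng.choice(pool, 12, replace=False))
        assert len(repurpose.common_candidates(a, b)) <= min(len(a), len(b))


def linear_design(n_drugs=10, genes=("gA", "gB", "gC", "gD"), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    gene_fcs = {g: float(rng.uniform(0.5, 3.0)) for g in genes}
    offsets = {g: float(rng.uniform(-1, 1)) for g in genes}
    rows = []
    for i in range(n_drugs):
        for g in genes:
            fc = 2.0 * gene_fcs[g] + offsets[g] + rng.normal(0, noise)
            rows.append({"drug": f"d{i:02d}", "gene": g, "drug_fc": fc,
                         "p_value": 0.01, "q_value": 0.01, "specificity": 0.5,
                         "source_id": f"d{i}_{g}"})
    return pd.DataFrame(rows), gene_fcs


class TestBuildDesign:
    def test_shape_contract(self):
        sig, gene_fcs = linear_design(n_drugs=2, genes=("a", "b", "c"))
        X, y = repurpose.build_design(sig, gene_fcs)
        assert X.shape == (6, 1 + 3)
        assert len(y) == 6

    def test_one_hot_columns_sum_to_n_drugs(self):
        sig, gene_fcs = linear_design(n_drugs=5, genes=("a", "b"))
        X, _ = repurpose.build_design(sig, gene_fcs)
        onehot = X.drop(columns="gene_fc_z")
        np.testing.assert_allclose(onehot.sum(axis=0), 5)

    def test_numeric_column_standardized(self):
        sig, gene_fcs = linear_design()
        X, _ = repurpose.build_design(sig, gene_fcs)
        assert X["gene_fc_z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_unknown_gene_rejected(self):
        sig, gene_fcs = linear_design()
        del gene_fcs["gA"]
        with pytest.raises(ValidationError):
            repurpose.build_design(sig, gene_fcs)

    def test_row_order_deterministic(self):
        sig, gene_fcs = linear_design()
        shuffled = sig.sample(frac=1.0, random_state=1)
        X1, y1 = repurpose.build_design(sig, gene_fcs)
        X2, y2 = repurpose.build_design(shuffled, gene_fcs)
        pd.testing.assert_frame_equal(X1, X2)
        pd.testing.assert_series_equal(y1, y2)


class TestPredictFcPanel:
    def test_linear_target_recovered_exactly(self):
        sig, gene_fcs = linear_design(noise=0.0)
        X, y = repurpose.build_design(sig, gene_fcs)
        out = repurpose.predict_fc_panel(X, y, models=("linear",), seed=0)
        assert out["cv_error"].iloc[0] <= 1e-6

    def test_pure_noise_target_bounded_by_null_model(self):
        sig, gene_fcs = linear_design(n_drugs=12)
        X, y = repurpose.build_design(sig, gene_fcs)
        rng = np.random.default_rng(8)
        y_shuffled = pd.Series(rng.permutation(rng.normal(size=len(y))), index=y.index)
        from sklearn.model_selection import KFold

        null_pred = np.empty(len(y_shuffled))
        folds = list(KFold(5, shuffle=True, random_state=0).split(X))
        for train, test in folds:
            null_pred[test] = y_shuffled.iloc[train].mean()
        null_mae = np.abs(null_pred - y_shuffled.to_numpy()).mean()
        out = repurpose.predict_fc_panel(
            X, y_shuffled, models=("linear", "svr", "gradient_boosting"), seed=0)
        for model, group in out.groupby("model_name"):
            assert group["cv_error"].iloc[0] >= 0.9 * null_mae, model

    def test_deterministic_at_fixed_seed(self):
        sig, gene_fcs = linear_design(noise=0.3)
        X, y = repurpose.build_design(sig, gene_fcs)
        a = repurpose.predict_fc_panel(X, y, models=("linear", "random_forest"), seed=2)
        b = repurpose.predict_fc_panel(X, y, models=("linear", "random_forest"), seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_fold_disjointness(self):
        from sklearn.model_selection import KFold

        X = np.zeros((23, 2))
        folds = list(KFold(5, shuffle=True, random_state=0).split(X))
        for train, test in folds:
            assert not set(train) & set(test)
        covered = sorted(np.concatenate([t for _, t in folds]))
        assert covered == list(range(23))

    def test_too_few_rows(self):
        sig, gene_fcs = linear_design(n_drugs=1, genes=("a",))
        X, y = repurpose.build_design(sig, gene_fcs)
        with pytest.raises(ParameterError):
            repurpose.predict_fc_panel(X, y, models=("linear",), k_folds=5)

    def test_unknown_model_rejected(self):
        sig, gene_fcs = linear_design()
        X, y = repurpose.build_design(sig, gene_fcs)
        with pytest.raises(ParameterError):
            repurpose.predict_fc_panel(X, y, models=("catapult",))
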