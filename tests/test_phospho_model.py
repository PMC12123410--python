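"""Phospho LASSO: eligibility rules, planted recovery, score partitioning.

The fixture model with the thirteen published coefficients checks the
sign-partition contract: eleven positive-coefficient sites summed into the
positive score and two negative ones into the negative score.
"""

import numpy as np
import pandas as pd
import pytest

from tfact.io_formats import PathwayCollection, PhosphoTable
from tfact.phospho_model import (
    PhosphoModel,
    eligible_predictors,
    fit_tf_model,
    phospho_scores,
)
from tfact.synthetic_data import generate_lasso_problem

POSITIVE_SITES = {
    "MYH9_S1943": 1.209, "MYH11_S1954": 1.100, "ALB_S82": 0.881,
    "NEXN_S16": 0.637, "PRKCE_T710": 0.503, "MYH11_S23": 0.282,
    "FGA_S609": 0.203, "ALB_T551": 0.122, "SSR3_S105": 0.100,
    "PRKCD_S683": 0.091, "FHOD1_S549": 0.044,
}
NEGATIVE_SITES = {"CTNND1_S847": -1.208, "IQGAP1_S330": -1.380}


def _phospho(values: np.ndarray, sites: list[str], patients: list[str]) -> PhosphoTable:
    proteins = {s: s.rsplit("_", 1)[0] for s in sites}
    return PhosphoTable(
        log2fc=pd.DataFrame(values, index=sites, columns=patients),
        protein_of_site=proteins,
    )


class TestEligiblePredictors:
    def _table(self):
        pats = [f"p{i}" for i in range(3)]
        vals = np.ones((3, 3))
        vals[2, 1] = np.nan  # protA_S2 incomplete
        return _phospho(vals, ["protA_S1", "protB_S5", "protA_S2"], pats)

    def test_shared_pathway_complete_site_eligible(self):
        ph = self._table()
        pw = PathwayCollection({"P1": frozenset({"TF", "protA"})})
        assert eligible_predictors("TF", ph, pw) == ["protA_S1"]

    def test_no_shared_pathway_excluded(self):
        ph = self._table()
        pw = PathwayCollection({"P1": frozenset({"TF", "protA"}),
                                "P2": frozenset({"protB"})})
        assert "protB_S5" not in eligible_predictors("TF", ph, pw)

    def test_incomplete_site_excluded(self):
        ph = self._table()
        pw = PathwayCollection({"P1": frozenset({"TF", "protA"})})
        assert "protA_S2" not in eligible_predictors("TF", ph, pw)

    def test_tf_in_no_pathway_yields_empty(self):
        ph = self._table()
        pw = PathwayCollection({"P1": frozenset({"protA"})})
        assert eligible_predictors("TF", ph, pw) == []


class TestFitTfModel:
    def test_empty_eligible_set_is_no_predictors(self):
        """Mirrors TFs whose pathways contain no quantified substrate."""
        pats = [f"p{i}" for i in range(30)]
        ph = _phospho(np.random.default_rng(0).normal(0, 1, (2, 30)),
                      ["protA_S1", "protB_S2"], pats)
        pw = PathwayCollection({"P1": frozenset({"TF"})})
        y = pd.Series(np.arange(30.0), index=pats)
        m = fit_tf_model("TF", y, ph, pw, seed=1)
        assert m.status == "no_predictors" and m.selected == {}

    def test_planted_single_site_recovered(self):
        """Response proportional to one site's fold change: that site is
        selected with a positive coefficient, few decoys enter."""
        rng = np.random.default_rng(7)
        pats = [f"p{i}" for i in range(100)]
        sites = ["protA_S1"] + [f"dec{i}_S1" for i in range(50)]
        vals = rng.normal(0, 1, (51, 100))
        ph = _phospho(vals, sites, pats)
        pw = PathwayCollection(
            {"P1": frozenset({"TF"} | {s.rsplit("_", 1)[0] for s in sites})})
        y = pd.Series(3.0 * vals[0], index=pats)
        m = fit_tf_model("TF", y, ph, pw, seed=7)
        assert m.status == "fitted"
        assert m.selected.get("protA_S1", 0) > 0
        assert len(set(m.selected) - {"protA_S1"}) <= 2

    def test_pure_noise_mostly_all_zero(self):
        """Noise response vs noise predictors selects nothing in >= 90% of 50 reps."""
        n_zero = 0
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            y, ph, pw = generate_lasso_problem(
                n_true_sites=1, n_decoy_sites=49, seed=seed)
            y_noise = pd.Series(rng.normal(0, 1, len(y)), index=y.index)
            m = fit_tf_model("TF01", y_noise, ph, pw, seed=seed)
            n_zero += m.status == "all_zero"
        assert n_zero >= 45

    def test_too_few_patients_rejected(self):
        pats = [f"p{i}" for i in range(10)]
        ph = _phospho(np.ones((1, 10)), ["protA_S1"], pats)
        pw = PathwayCollection({"P1": frozenset({"TF", "protA"})})
        with pytest.raises(ValueError, match="usable patients"):
            fit_tf_model("TF", pd.Series(np.arange(10.0), index=pats), ph, pw)

    def test_column_order_invariance(self):
        y, ph, pw = generate_lasso_problem(n_decoy_sites=40, seed=3)
        m1 = fit_tf_model("TF01", y, ph, pw, seed=3)
        shuffled = PhosphoTable(
            log2fc=ph.log2fc.iloc[::-1], protein_of_site=ph.protein_of_site)
        m2 = fit_tf_model("TF01", y, shuffled, pw, seed=3)
        assert set(m1.selected) == set(m2.selected)
        # coordinate descent tolerance leaves tiny order-dependent residue
        for s in m1.selected:
            assert m1.selected[s] == pytest.approx(m2.selected[s], rel=1e-3)

    def test_lasso_path_mostly_monotone(self):
        """Sparsity is non-increasing in lambda on >= 95% of adjacent grid pairs."""
        from tfact.phospho_model import _centered_path, _lambda_grid

        y, ph, pw = generate_lasso_problem(n_decoy_sites=60, seed=5)
        x = ph.log2fc.to_numpy().T
        alphas = _lambda_grid(x, y.to_numpy())
        coefs = _centered_path(x, y.to_numpy(), alphas)
        sizes = (coefs != 0).sum(axis=0)  # grid descends -> sizes should ascend
        ok = (np.diff(sizes) >= 0).mean()
        assert ok >= 0.95

    def test_response_scaling_scales_coefficients(self):
        """Doubling the response doubles coefficients at fixed lambda ratio."""
        from tfact.phospho_model import _centered_path, _lambda_grid

        y, ph, pw = generate_lasso_problem(n_decoy_sites=30, seed=6)
        x = ph.log2fc.to_numpy().T
        a1 = _lambda_grid(x, y.to_numpy())
        a2 = _lambda_grid(x, 2 * y.to_numpy())
        assert np.allclose(a2, 2 * a1)
        c1 = _centered_path(x, y.to_numpy(), a1)
        c2 = _centered_path(x, 2 * y.to_numpy(), a2)
        assert np.allclose(c2, 2 * c1, atol=1e-6)


class TestPhosphoScores:
    def _fixture_model_and_table(self):
        coeffs = {**POSITIVE_SITES, **NEGATIVE_SITES}
        sites = list(coeffs)
        model = PhosphoModel(tf="ERG", status="fitted", selected=coeffs,
                             eligible_sites=sites)
        rng = np.random.default_rng(42)
        pats = [f"p{i}" for i in range(10)]
        ph = _phospho(rng.normal(0, 1, (13, 10)), sites, pats)
        return model, ph

    def test_published_coefficient_sign_partition(self):
        model, _ = self._fixture_model_and_table()
        assert model.positive_sites == set(POSITIVE_SITES)
        assert model.negative_sites == {"CTNND1_S847", "IQGAP1_S330"}

    def test_loop_oracle_equality(self):
        model, ph = self._fixture_model_and_table()
        sc = phospho_scores(model, ph)
        for p in ph.patient_ids:
            plus = sum(ph.log2fc.loc[s, p] for s in POSITIVE_SITES)
            minus = sum(ph.log2fc.loc[s, p] for s in NEGATIVE_SITES)
            assert sc.p_plus[p] == pytest.approx(plus, rel=1e-12)
            assert sc.p_minus[p] == pytest.approx(minus, rel=1e-12)

    def test_all_zero_fc_patient(self):
        model, ph = self._fixture_model_and_table()
        ph.log2fc.iloc[:, 0] = 0.0
        sc = phospho_scores(model, ph)
        assert sc.p_plus.iloc[0] == 0 and sc.p_minus.iloc[0] == 0

    def test_unfitted_model_rejected(self):
        m = PhosphoModel(tf="X", status="all_zero")
        with pytest.raises(ValueError, match="all_zero"):
            phospho_scores(m, self._fixture_model_and_table()[1])
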