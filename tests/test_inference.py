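"""Association-model fitting, AIC order selection, and symmetrization."""

import numpy as np
import pytest

from conftest import expression_from_values
from coremark.inference import (
    CollinearityError,
    aic_order_select,
    aic_value,
    build_interaction_matrix,
    coefficient_ttest,
    fit_association_model,
    infer_ppin,
    prune_association_model,
)
from coremark.types import AssociationFit, RunConfig, canonical_edge


class TestFit:
    def test_null_model_residual_is_mean_square(self, rng):
        y = rng.normal(size=30)
        expr = expression_from_values(np.vstack([y, rng.normal(size=30)]))
        fit = fit_association_model(expr, "P00", [])
        assert fit.retained == ()
        yc = y - y.mean()
        assert fit.residual_variance == pytest.approx((yc @ yc) / 30)

    def test_identity_regression_recovers_unit_coefficient(self, rng):
        x = rng.normal(size=40)
        expr = expression_from_values(np.vstack([x, x]))
        fit = fit_association_model(expr, "P00", ["P01"])
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.residual_variance < 1e-20

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        xa, xb = rng.normal(size=(2, n))
        y = 0.7 * xa - 0.3 * xb + rng.normal(0, 0.1, n)
        expr = expression_from_values(np.vstack([y, xa, xb]))
        fit = fit_association_model(expr, "P00", ["P01", "P02"])
        # explicit (X'X)^{-1} X'y on centered data
        X = np.column_stack([xa - xa.mean(), xb - xb.mean()])
        yc = y - y.mean()
        beta = np.linalg.inv(X.T @ X) @ X.T @ yc
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)

    def test_pvalues_match_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 60
        X = rng.normal(size=(n, 3))
        y = X @ [0.5, 0.0, -0.4] + rng.normal(0, 0.5, n)
        expr = expression_from_values(np.vstack([y, X.T]))
        fit = fit_association_model(expr, "P00", ["P01", "P02", "P03"])
        Xc = X - X.mean(axis=0)
        res = sm.OLS(y - y.mean(), Xc).fit()
        np.testing.assert_allclose(fit.coefficients, res.params, atol=1e-10)
        got = [fit.coefficient_pvalues[f"P0{j}"] for j in (1, 2, 3)]
        np.testing.assert_allclose(got, res.pvalues, atol=1e-8)

    def test_rejects_collinear_candidates_by_name(self, rng):
        x = rng.normal(size=30)
        expr = expression_from_values(np.vstack([rng.normal(size=30), x, 2 * x]))
        with pytest.raises(CollinearityError, match="P0"):
            fit_association_model(expr, "P00", ["P01", "P02"])

    def test_rejects_too_few_samples_and_self_candidate(self, rng):
        expr = expression_from_values(rng.normal(size=(4, 4)))
        with pytest.raises(ValueError, match="insufficient|n_samples"):
            fit_association_model(expr, "P00", ["P01", "P02", "P03"])
        with pytest.raises(ValueError, match="own candidate"):
            fit_association_model(expr, "P00", ["P00"])


class TestAicSelection:
    def test_direct_formula_value(self):
        assert aic_value(50.0, 100, 2) == pytest.approx(100 * np.log(0.5) + 4)
        assert aic_value(50.0, 100, 2) == pytest.approx(-65.3147, abs=1e-4)

    def test_null_candidate_usually_dropped(self):
        """A candidate with true coefficient 0 at n=500 should rarely survive."""
        empty = 0
        reps = 200
        rng = np.random.default_rng(77)
        for _ in range(reps):
            x = rng.normal(size=500)
            y = rng.normal(size=500)
            expr = expression_from_values(np.vstack([y, x]))
            retained, _ = aic_order_select(expr, "P00", ["P01"])
            empty += retained == ()
        assert empty / reps > 0.8

    def test_recovers_true_pair_and_matches_exhaustive(self, rng):
        n = 200
        X = rng.normal(size=(5, n))
        y = 0.7 * X[0] - 0.7 * X[1] + rng.normal(0, 1.0, n)
        expr = expression_from_values(np.vstack([y, X]))
        cands = [f"P0{j}" for j in range(1, 6)]
        fwd, trace = aic_order_select(expr, "P00", cands)
        exh, _ = aic_order_select(expr, "P00", cands, exhaustive=True)
        assert set(fwd) == {"P01", "P02"}
        assert set(fwd) == set(exh)
        sizes = [k for k, _ in trace]
        assert sizes == sorted(sizes)  # forward trace grows monotonically

    def test_exhaustive_limit(self, rng):
        expr = expression_from_values(rng.normal(size=(17, 40)))
        with pytest.raises(ValueError, match="exhaustive"):
            aic_order_select(expr, "P00", [f"P{i:02d}" for i in range(1, 17)],
                             exhaustive=True)


class TestCoefficientTtest:
    def _fit(self, pvals):
        names = tuple(f"P{i}" for i in range(1, len(pvals) + 1))
        return AssociationFit(target="P0", candidates=names, retained=names,
                              coefficients=np.ones(len(pvals)),
                              coefficient_pvalues=dict(zip(names, pvals)),
                              residual_variance=1.0)

    def test_threshold_behaviour(self):
        assert coefficient_ttest(self._fit([0.0, 0.0])) == ("P1", "P2")
        assert coefficient_ttest(self._fit([1.0, 1.0])) == ()
        assert coefficient_ttest(self._fit([0.01, 0.2]), alpha=0.05) == ("P1",)


class TestSymmetrization:
    def _fit(self, target, coefs):
        names = tuple(coefs)
        return AssociationFit(target=target, candidates=names, retained=names,
                              coefficients=np.array(list(coefs.values())),
                              coefficient_pvalues={c: 0.0 for c in names},
                              residual_variance=0.1)

    def test_larger_magnitude_wins_keeping_sign(self):
        fits = [self._fit("A", {"B": 0.5}), self._fit("B", {"A": -0.8})]
        mat = build_interaction_matrix(fits, ["A", "B"])
        assert mat.A[0, 1] == mat.A[1, 0] == -0.8

    def test_one_directional_estimate_is_mirrored(self):
        fits = [self._fit("A", {"B": 0.4}), self._fit("B", {})]
        mat = build_interaction_matrix(fits, ["A", "B"])
        assert mat.A[0, 1] == mat.A[1, 0] == 0.4

    def test_pruned_pair_is_zero_and_symmetric_input_unchanged(self):
        fits = [self._fit("A", {}), self._fit("B", {}),
                self._fit("C", {"A": 0.3}), ]
        mat = build_interaction_matrix(fits, ["A", "B", "C"])
        assert mat.A[0, 1] == 0.0
        assert mat.A[0, 2] == mat.A[2, 0] == 0.3
        again = build_interaction_matrix(fits, ["A", "B", "C"])
        np.testing.assert_array_equal(mat.A, again.A)

    def test_duplicate_fits_rejected(self):
        fits = [self._fit("A", {}), self._fit("A", {})]
        with pytest.raises(ValueError, match="duplicate"):
            build_interaction_matrix(fits, ["A"])


class TestInferPpin:
    def test_single_true_edge_gives_single_nonzero_block(self, rng):
        n = 200
        w = rng.normal(0, 1.0, size=(3, n))
        x1 = w[0]
        x2 = 0.6 * x1 + w[1]
        x3 = w[2]
        expr = expression_from_values(np.vstack([x1, x2, x3]))
        net = {canonical_edge("P00", "P01")}
        mat = infer_ppin(expr, net)
        assert mat.A[0, 1] != 0.0
        assert mat.A[0, 2] == mat.A[1, 2] == 0.0

    def test_empty_network_warns_and_returns_zero_matrix(self, rng, caplog):
        expr = expression_from_values(rng.normal(size=(3, 20)))
        with caplog.at_level("WARNING"):
            mat = infer_ppin(expr, set())
        assert not mat.A.any()
        assert "empty candidate network" in caplog.text

    def test_output_always_symmetric_zero_diagonal(self):
        from coremark.synthetic import (generate_ground_truth,
                                        make_candidate_network,
                                        simulate_expression)
        for seed in range(3):
            truth = generate_ground_truth(M=12, edge_density=0.25, n_cancers=1,
                                          core_size=2, specific_size=0, seed=seed)
            cand, _ = make_candidate_network(truth, 5, seed=seed + 50)
            expr = simulate_expression(truth.A_normal, 80, 0.3, seed=seed + 90,
                                       protein_ids=truth.protein_ids)
            mat = infer_ppin(expr, cand)
            np.testing.assert_array_equal(mat.A, mat.A.T)
            assert not np.diag(mat.A).any()
            # nonzeros only on candidate pairs
            iu, ju = np.nonzero(np.triu(mat.A, 1))
            ids = mat.protein_ids
            for i, j in zip(iu, ju):
                assert canonical_edge(ids[i], ids[j]) in cand


def test_prune_refits_on_survivors(rng):
    n = 300
    X = rng.normal(size=(3, n))
    y = 0.8 * X[0] + rng.normal(0, 0.5, n)
    expr = expression_from_values(np.vstack([y, X]))
    fit = prune_association_model(expr, "P00", ["P01", "P02", "P03"])
    assert set(fit.retained) == {"P01"}
    assert fit.coefficients[0] == pytest.approx(0.8, abs=0.1)
    assert fit.aic_trace[0][0] == 0
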