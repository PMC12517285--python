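import math

import numpy as np
import pytest

from pathsem.expression_io import ExpressionMatrix
from pathsem.graphs import PathwayGraph
from pathsem.sem import (
    IdentificationError,
    add_paths_refit,
    build_sem_model,
    fit_indices,
    fit_ml,
    fit_ml_cov,
    modification_indices,
    parameter_table,
    rmsea_from_chisq,
    zscore_rows,
)
from pathsem.simulate import chain_spec, simulate_from_sem


def _chain_graph(names="ABC"):
    g = PathwayGraph(name="chain")
    for a, b in zip(names[:-1], names[1:]):
        g.add_edge(a, b, 1)
    return g


def _implied(B, Psi):
    A = np.linalg.inv(np.eye(B.shape[0]) - B)
    return A @ Psi @ A.T


def _fork_graph():
    """A->B, A->C, B->D, C->E; the omitted-path tests add a true B->E effect.

    On this shape the B->E path is not covariance-equivalent to any other
    single addition, so its modification index is strictly the largest
    (pure chains admit many equivalent one-parameter augmentations).
    """
    g = PathwayGraph(name="fork")
    g.add_edge("A", "B", 1)
    g.add_edge("A", "C", 1)
    g.add_edge("B", "D", 1)
    g.add_edge("C", "E", 1)
    return g


def _omitted_path_fit(seed, beta_extra=0.7, n=500):
    """Data from the fork plus a direct B->E path; fitted model omits B->E."""
    names = list("ABCDE")
    B = np.zeros((5, 5))
    B[1, 0] = 0.6   # A->B
    B[2, 0] = 0.6   # A->C
    B[3, 1] = 0.6   # B->D
    B[4, 2] = 0.6   # C->E
    B[4, 1] = beta_extra  # B->E, omitted from the fitted model
    Psi = np.diag([1.0, 1.0, 1.0, 1.0, 2.0])
    A = np.linalg.inv(np.eye(5) - B)
    rng = np.random.default_rng(seed)
    y = rng.multivariate_normal(np.zeros(5), A @ Psi @ A.T, size=n).T
    m = ExpressionMatrix(names, [f"s{j}" for j in range(n)], y)
    return fit_ml(build_sem_model(_fork_graph()), m)


class TestBuildModel:
    def test_chain3_counts(self):
        model = build_sem_model(_chain_graph("ABC"))
        assert model.t == 5
        assert model.df == 1

    def test_edgeless_df(self):
        g = PathwayGraph(name="iso")
        for n in "ABCD":
            g.add_node(n)
        model = build_sem_model(g)
        p = 4
        assert model.df == p * (p + 1) // 2 - p

    def test_overparameterized_rejected(self):
        g = PathwayGraph(name="over")
        g.add_edge("A", "B", 1)
        g.add_bidirected("A", "B")
        with pytest.raises(IdentificationError, match="t=4"):
            build_sem_model(g)

    def test_bidirected_frees_psi(self):
        g = _chain_graph("ABC")
        g.add_bidirected("A", "C")
        model = build_sem_model(g)
        assert model.psi_free[2, 0] and model.psi_free[0, 2]


class TestFitMl:
    def test_saturated_model_chisq_zero(self):
        rng = np.random.default_rng(0)
        g = PathwayGraph(name="sat")
        for n in "AB":
            g.add_node(n)
        g.add_bidirected("A", "B")
        model = build_sem_model(g)
        assert model.df == 0
        m = ExpressionMatrix(["A", "B"], [f"s{j}" for j in range(30)],
                             rng.normal(size=(2, 30)))
        fit = fit_ml(model, m)
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        # implied covariance reproduces S
        np.testing.assert_allclose(fit.sigma, fit.samples[0][0], atol=1e-8)

    def test_perfect_fit_recovers_parameters(self):
        # covariance input exactly equal to Sigma(theta*) for a 3-chain
        beta = 0.7
        B = np.zeros((3, 3))
        B[1, 0] = beta
        B[2, 1] = beta
        Psi = np.diag([1.0, 1 - beta**2, 1 - beta**2])
        S = _implied(B, Psi)
        model = build_sem_model(_chain_graph("ABC"))
        fit = fit_ml_cov(model, [(S, 100)])
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.B[1, 0], beta, atol=1e-6)
        np.testing.assert_allclose(fit.B[2, 1], beta, atol=1e-6)

    def test_ols_equivalence_recursive_diagonal(self):
        spec = chain_spec(np.array([0.8, 0.5, 0.6, 0.7]),
                          np.array([0.8, 0.5, 0.6, 0.7]), n0=100, n1=100, seed=4)
        matrix, _ = simulate_from_sem(spec)
        model = build_sem_model(_chain_graph("ABCDE"))
        fit = fit_ml(model, matrix)
        z = zscore_rows(matrix.subset_genes(model.variables).values)
        for k, (i, j) in enumerate(model.b_idx):
            ols = (z[j] @ z[i]) / (z[j] @ z[j])
            assert fit.theta[k] == pytest.approx(ols, abs=1e-6)

    def test_cyclic_model_fits(self):
        # feedback loop: convergence without acyclicity requirement
        g = PathwayGraph(name="loop")
        g.add_edge("A", "B", 1)
        g.add_edge("B", "C", 1)
        g.add_edge("C", "A", -1)
        B = np.zeros((3, 3))
        B[1, 0], B[2, 1], B[0, 2] = 0.5, 0.5, -0.3
        S = _implied(B, np.eye(3) * 0.5)
        fit = fit_ml_cov(build_sem_model(g), [(S, 200)])
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.B[0, 2] == pytest.approx(-0.3, abs=1e-5)

    def test_not_pd_sample_cov_rejected(self):
        model = build_sem_model(_chain_graph("ABC"))
        S = np.ones((3, 3))  # rank 1
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml_cov(model, [(S, 50)])

    def test_f_nonnegative_and_sigma_pd(self):
        spec = chain_spec(np.full(4, 0.4), np.full(4, 0.4), n0=40, n1=40, seed=9)
        matrix, _ = simulate_from_sem(spec)
        fit = fit_ml(build_sem_model(_chain_graph("ABCDE")), matrix)
        assert fit.f_ml >= -1e-10
        assert np.all(np.linalg.eigvalsh(fit.sigma) > 0)


class TestFitIndices:
    def test_rmsea_published_values(self):
        assert round(rmsea_from_chisq(118.92, 36, 27), 3) == 0.292
        assert round(rmsea_from_chisq(36.71, 30, 27), 3) == 0.091

    def test_rmsea_clamped_at_zero(self):
        assert rmsea_from_chisq(10.0, 20, 50) == 0.0

    def test_df_zero_conventions(self):
        rng = np.random.default_rng(3)
        g = PathwayGraph(name="sat")
        g.add_node("A")
        g.add_node("B")
        g.add_bidirected("A", "B")
        m = ExpressionMatrix(["A", "B"], [f"s{j}" for j in range(25)],
                             rng.normal(size=(2, 25)))
        idx = fit_indices(fit_ml(build_sem_model(g), m))
        assert idx.rmsea == 0.0 and idx.pvalue == 1.0

    def test_index_ranges(self):
        spec = chain_spec(np.full(4, 0.6), np.full(4, 0.6), n0=50, n1=50, seed=5)
        matrix, _ = simulate_from_sem(spec)
        idx = fit_indices(fit_ml(build_sem_model(_chain_graph("ABCDE")), matrix))
        assert idx.rmsea >= 0 and idx.srmr >= 0
        assert 0 <= idx.cfi <= 1
        assert 0 <= idx.pvalue <= 1
        assert idx.bic > idx.aic  # ln(100) > 2


class TestParameterTable:
    def test_column_identities(self):
        spec = chain_spec(np.full(4, 0.5), np.full(4, 0.5), n0=80, n1=80, seed=6)
        matrix, _ = simulate_from_sem(spec)
        fit = fit_ml(build_sem_model(_chain_graph("ABCDE")), matrix)
        tbl = parameter_table(fit)
        np.testing.assert_allclose(tbl["z"], tbl["est"] / tbl["se"], atol=1e-9)
        np.testing.assert_allclose(tbl["ci_upper"] - tbl["est"], 1.959964 * tbl["se"], atol=1e-9)
        assert set(tbl["op"]) == {"~", "~~"}

    def test_ci_coverage(self):
        # true standardized beta = 0.5 on A->B; 100 replicates at n=500
        hits = 0
        R = 100
        for seed in range(R):
            spec = chain_spec(np.full(4, 0.5), np.full(4, 0.5), n0=250, n1=250, seed=seed)
            matrix, _ = simulate_from_sem(spec)
            fit = fit_ml(build_sem_model(_chain_graph("ABCDE")), matrix)
            tbl = parameter_table(fit)
            row = tbl[(tbl.lhs == "B") & (tbl.op == "~") & (tbl.rhs == "A")].iloc[0]
            hits += row.ci_lower <= 0.5 <= row.ci_upper
        assert 0.90 <= hits / R <= 0.98


class TestModificationIndices:
    def test_free_parameter_not_listed(self):
        fit = _omitted_path_fit(0)
        mis = modification_indices(fit)
        assert not any(m.op == "~" and m.lhs == "B" and m.rhs == "A" for m in mis)

    def test_omitted_path_top_ranked(self):
        top_hits = 0
        for seed in range(10):
            fit = _omitted_path_fit(seed)
            mis = modification_indices(fit)
            top = mis[0]
            top_hits += top.lhs == "E" and top.rhs == "B"
        assert top_hits >= 9

    def test_mi_predicts_chisq_drop(self):
        fit = _omitted_path_fit(1)
        mis = modification_indices(fit, candidates=[("E", "~", "B")])
        mi = mis[0]
        refit = add_paths_refit(fit, [("E", "~", "B")])
        drop = fit.chisq - refit.chisq
        assert abs(drop - mi.mi) / drop < 0.2

    def test_epc_sign_and_magnitude(self):
        fit = _omitted_path_fit(2)
        mi = modification_indices(fit, candidates=[("E", "~", "B")])[0]
        refit = add_paths_refit(fit, [("E", "~", "B")])
        k = refit.model.param_labels().index(("E", "~", "B"))
        assert math.copysign(1, mi.epc) == math.copysign(1, refit.theta[k])

    def test_sorted_descending(self):
        fit = _omitted_path_fit(3)
        mis = modification_indices(fit)
        assert all(a.mi >= b.mi for a, b in zip(mis, mis[1:]))


class TestAddPathsRefit:
    def _fit(self, seed=0):
        spec = chain_spec(np.full(4, 0.5), np.full(4, 0.5), n0=60, n1=60, seed=seed)
        matrix, _ = simulate_from_sem(spec)
        return fit_ml(build_sem_model(_chain_graph("ABCDE")), matrix)

    def test_empty_addition_identity(self):
        fit = self._fit()
        refit = add_paths_refit(fit, [])
        assert refit.chisq == pytest.approx(fit.chisq, abs=1e-8)

    def test_nesting_chisq_and_df(self):
        fit = self._fit()
        refit = add_paths_refit(fit, [("C", "~", "A"), ("E", "~~", "A")])
        assert refit.chisq <= fit.chisq + 1e-8
        assert refit.df == fit.df - 2

    def test_duplicate_rejected(self):
        fit = self._fit()
        with pytest.raises(ValueError, match="already free"):
            add_paths_refit(fit, [("B", "~", "A")])

    def test_identification_violation_rejected(self):
        fit = self._fit()
        additions = [("C", "~", "A"), ("D", "~", "A"), ("E", "~", "A"),
                     ("D", "~", "B"), ("E", "~", "B"), ("E", "~", "C"),
                     ("A", "~~", "C")]
        with pytest.raises(IdentificationError):
            add_paths_refit(fit, additions)

    def test_successive_additions_monotone(self):
        fit = _omitted_path_fit(5)
        chisqs = [fit.chisq]
        current = fit
        for addition in [("E", "~", "B"), ("D", "~~", "C")]:
            current = add_paths_refit(current, [addition])
            chisqs.append(current.chisq)
        assert all(a >= b - 1e-8 for a, b in zip(chisqs, chisqs[1:]))
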