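"""Observed-variable linear structural equation models, fit by maximum likelihood.

A model is ``y = B y + zeta`` with ``Cov(zeta) = Psi``; the implied
covariance is ``Sigma = (I-B)^-1 Psi (I-B)^-T``.  Fitting minimizes the ML
discrepancy ``F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p`` by Fisher scoring
with an analytic gradient; ``chisq = N * F`` (covariance divisor N).
Supports multiple sample groups sharing one parameter vector
(``F = sum_g (n_g/N) F_g``), modification indices, and iterative path
addition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from pathsem.expression_io import ExpressionMatrix
from pathsem.graphs import PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SemModel",
    "SemFit",
    "FitIndices",
    "ModificationIndex",
    "IdentificationError",
    "build_sem_model",
    "fit_ml",
    "fit_ml_cov",
    "fit_indices",
    "parameter_table",
    "modification_indices",
    "add_paths_refit",
    "zscore_rows",
]

Z95 = 1.959964


class IdentificationError(ValueError):
    """Model has more free parameters than distinct covariance moments."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the gradient tolerance."""


@dataclass
class SemModel:
    """Pattern of free path coefficients and residual (co)variances.

    ``b_free[i, j]`` frees the coefficient of variable j in the equation of
    variable i (edge j → i).  ``psi_free`` is symmetric; the diagonal is free
    except for variables in *fixed_variance_idx*, whose variance is fixed at
    the corresponding entry of *psi_fixed* (used for exogenous indicator
    variables whose sample variance is known, e.g. a 0/1 group code).
    """

    variables: list[str]
    b_free: np.ndarray
    psi_free: np.ndarray
    psi_fixed: np.ndarray
    fixed_variance_idx: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        p = len(self.variables)
        self.b_free = np.asarray(self.b_free, bool)
        self.psi_free = np.asarray(self.psi_free, bool)
        self.psi_fixed = np.asarray(self.psi_fixed, float)
        if self.b_free.shape != (p, p) or self.psi_free.shape != (p, p):
            raise ValueError("pattern shapes must be p x p")
        if not np.array_equal(self.psi_free, self.psi_free.T):
            raise ValueError("psi_free must be symmetric")
        if np.any(np.diag(self.b_free)):
            raise ValueError("diagonal of B cannot be free (self-loop)")
        if self.df < 0:
            raise IdentificationError(
                f"model not identified: t={self.t} free parameters exceed "
                f"{self.n_moments} moments for p={p} variables"
            )

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def b_idx(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.b_free)]

    @property
    def psi_idx(self) -> list[tuple[int, int]]:
        # lower triangle incl. diagonal, row-major
        return [(i, j) for i in range(self.p) for j in range(i + 1) if self.psi_free[i, j]]

    @property
    def t(self) -> int:
        return len(self.b_idx) + len(self.psi_idx)

    @property
    def n_moments(self) -> int:
        """Moments available for testing: p(p+1)/2 minus those pinned to sample values."""
        return self.p * (self.p + 1) // 2 - len(self.fixed_variance_idx)

    @property
    def df(self) -> int:
        return self.n_moments - self.t

    def param_labels(self) -> list[tuple[str, str, str]]:
        v = self.variables
        rows = [(v[i], "~", v[j]) for i, j in self.b_idx]
        rows += [(v[i], "~~", v[j]) for i, j in self.psi_idx]
        return rows

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        B = np.zeros((p, p))
        Psi = self.psi_fixed.copy()
        k = 0
        for i, j in self.b_idx:
            B[i, j] = theta[k]
            k += 1
        for i, j in self.psi_idx:
            Psi[i, j] = theta[k]
            Psi[j, i] = theta[k]
            k += 1
        return B, Psi

    def start_values(self, samples: list[tuple[np.ndarray, int]]) -> np.ndarray:
        n_tot = sum(n for _, n in samples)
        S_bar = sum((n / n_tot) * S for S, n in samples)
        theta = np.zeros(self.t)
        k = len(self.b_idx)
        for i, j in self.psi_idx:
            theta[k] = S_bar[i, i] if i == j else 0.0
            k += 1
        return theta

    def copy_with(
        self,
        extra_beta: list[tuple[int, int]] = (),
        extra_psi: list[tuple[int, int]] = (),
        drop_beta: list[tuple[int, int]] = (),
    ) -> "SemModel":
        b = self.b_free.copy()
        psi = self.psi_free.copy()
        for i, j in extra_beta:
            if b[i, j]:
                raise ValueError(f"path {self.variables[j]} -> {self.variables[i]} already free")
            b[i, j] = True
        for i, j in drop_beta:
            b[i, j] = False
        for i, j in extra_psi:
            if psi[i, j]:
                raise ValueError(
                    f"covariance {self.variables[i]} ~~ {self.variables[j]} already free"
                )
            psi[i, j] = psi[j, i] = True
        return SemModel(
            list(self.variables), b, psi, self.psi_fixed.copy(), self.fixed_variance_idx
        )


def build_sem_model(graph: PathwayGraph) -> SemModel:
    """Directed edge j→i frees β_ij; bidirected pair frees ψ_ij; diagonal ψ free."""
    if not graph.nodes:
        raise ValueError("empty graph")
    p = len(graph.nodes)
    idx = {n: i for i, n in enumerate(graph.nodes)}
    b_free = np.zeros((p, p), bool)
    for (u, v) in graph.directed_edges:
        b_free[idx[v], idx[u]] = True
    psi_free = np.eye(p, dtype=bool)
    for pair in graph.bidirected_edges:
        a, b = tuple(pair)
        psi_free[idx[a], idx[b]] = psi_free[idx[b], idx[a]] = True
    return SemModel(list(graph.nodes), b_free, psi_free, np.zeros((p, p)))


@dataclass
class SemFit:
    model: SemModel
    samples: list[tuple[np.ndarray, int]]  # (S_g, n_g) pairs
    theta: np.ndarray
    B: np.ndarray
    Psi: np.ndarray
    sigma: np.ndarray          # implied covariance (shared across groups)
    f_ml: float
    chisq: float
    df: int
    loglik: float
    se: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float

    @property
    def n(self) -> int:
        return sum(n for _, n in self.samples)

    @property
    def npar(self) -> int:
        return self.model.t

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / self.se

    @property
    def ci_lower(self) -> np.ndarray:
        return self.theta - Z95 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.theta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.chisq, self.df))


@dataclass
class FitIndices:
    chisq: float
    df: int
    pvalue: float
    rmsea: float
    srmr: float
    cfi: float
    aic: float
    bic: float
    npar: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "npar": self.npar, "chisq": self.chisq, "df": self.df,
            "pvalue": self.pvalue, "cfi": self.cfi, "aic": self.aic,
            "bic": self.bic, "rmsea": self.rmsea, "srmr": self.srmr,
        }


@dataclass
class ModificationIndex:
    lhs: str
    op: str      # "~" (path) or "~~" (covariance)
    rhs: str
    mi: float
    epc: float


# ---------------------------------------------------------------------------
# objective machinery


class _MLObjective:
    """Weighted multi-group ML discrepancy with analytic gradient and
    expected (Fisher) information."""

    def __init__(self, model: SemModel, samples: list[tuple[np.ndarray, int]]):
        self.model = model
        self.samples = [(np.asarray(S, float), int(n)) for S, n in samples]
        self.n_total = sum(n for _, n in self.samples)
        self.weights = [n / self.n_total for _, n in self.samples]
        self.logdet_s = []
        for S, _n in self.samples:
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                raise ValueError("sample covariance matrix is not positive definite")
            self.logdet_s.append(logdet)

    def _implied(self, theta: np.ndarray):
        B, Psi = self.model.unpack(theta)
        p = self.model.p
        I = np.eye(p)
        try:
            A = np.linalg.solve(I - B, I)
        except np.linalg.LinAlgError:
            return None
        sigma = A @ Psi @ A.T
        sigma = 0.5 * (sigma + sigma.T)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return None
        return A, sigma, chol

    def value(self, theta: np.ndarray) -> float:
        state = self._implied(theta)
        if state is None:
            return math.inf
        _A, sigma, chol = state
        logdet = 2 * np.log(np.diag(chol)).sum()
        sigma_inv = linalg.cho_solve((chol, True), np.eye(self.model.p))
        f = 0.0
        for w, (S, _n), lds in zip(self.weights, self.samples, self.logdet_s):
            f += w * (logdet - lds + float(np.sum(sigma_inv * S)) - self.model.p)
        return f

    def value_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray | None]:
        state = self._implied(theta)
        if state is None:
            return math.inf, None
        A, sigma, chol = state
        p = self.model.p
        logdet = 2 * np.log(np.diag(chol)).sum()
        sigma_inv = linalg.cho_solve((chol, True), np.eye(p))
        f = 0.0
        W_total = np.zeros((p, p))
        for w, (S, _n), lds in zip(self.weights, self.samples, self.logdet_s):
            f += w * (logdet - lds + float(np.sum(sigma_inv * S)) - p)
            W_total += w * (sigma_inv - sigma_inv @ S @ sigma_inv)
        GB = 2.0 * A.T @ W_total @ sigma
        P = A.T @ W_total @ A
        grad = np.empty(self.model.t)
        k = 0
        for i, j in self.model.b_idx:
            grad[k] = GB[i, j]
            k += 1
        for i, j in self.model.psi_idx:
            grad[k] = P[i, i] if i == j else 2.0 * P[i, j]
            k += 1
        return f, grad

    def _deltas(self, A: np.ndarray, sigma: np.ndarray,
                b_idx, psi_idx) -> np.ndarray:
        p = self.model.p
        out = np.empty((len(b_idx) + len(psi_idx), p, p))
        k = 0
        for i, j in b_idx:
            C = np.outer(A[:, i], sigma[j, :])
            out[k] = C + C.T
            k += 1
        for i, j in psi_idx:
            if i == j:
                out[k] = np.outer(A[:, i], A[:, i])
            else:
                C = np.outer(A[:, i], A[:, j])
                out[k] = C + C.T
            k += 1
        return out

    def fisher_information(
        self, theta: np.ndarray,
        extra_b: list[tuple[int, int]] = (),
        extra_psi: list[tuple[int, int]] = (),
    ) -> np.ndarray:
        """H_st = sum_g w_g tr(Sigma^-1 D_s Sigma^-1 D_t), free params first,
        then any extra candidate locations."""
        state = self._implied(theta)
        if state is None:
            raise np.linalg.LinAlgError("implied covariance not PD")
        A, sigma, chol = state
        sigma_inv = linalg.cho_solve((chol, True), np.eye(self.model.p))
        b_idx = list(self.model.b_idx) + list(extra_b)
        psi_idx = list(self.model.psi_idx) + list(extra_psi)
        # keep free-parameter packing order: free betas, free psis, extras
        n_fb = len(self.model.b_idx)
        n_fp = len(self.model.psi_idx)
        D_all = self._deltas(A, sigma, b_idx, psi_idx)
        order = (
            list(range(n_fb))
            + list(range(n_fb + len(extra_b), n_fb + len(extra_b) + n_fp))
            + list(range(n_fb, n_fb + len(extra_b)))
            + list(range(n_fb + len(extra_b) + n_fp, len(D_all)))
        )
        D = D_all[order]
        K = np.einsum("ab,sbc,cd->sad", sigma_inv, D, sigma_inv)
        # weights sum to 1 and Sigma is shared, so the group sum collapses
        return np.einsum("spq,tpq->st", K, D)

    def gradient_at(self, theta: np.ndarray,
                    b_idx: list[tuple[int, int]],
                    psi_idx: list[tuple[int, int]]) -> np.ndarray:
        """Gradient of F w.r.t. arbitrary (possibly fixed) parameter locations."""
        state = self._implied(theta)
        if state is None:
            raise np.linalg.LinAlgError("implied covariance not PD")
        A, sigma, chol = state
        p = self.model.p
        sigma_inv = linalg.cho_solve((chol, True), np.eye(p))
        W_total = np.zeros((p, p))
        for w, (S, _n) in zip(self.weights, self.samples):
            W_total += w * (sigma_inv - sigma_inv @ S @ sigma_inv)
        GB = 2.0 * A.T @ W_total @ sigma
        P = A.T @ W_total @ A
        g = [GB[i, j] for i, j in b_idx]
        g += [P[i, i] if i == j else 2.0 * P[i, j] for i, j in psi_idx]
        return np.array(g)


def _fisher_scoring(
    obj: _MLObjective, theta0: np.ndarray, gtol: float, max_iter: int
) -> tuple[np.ndarray, float, float, int, bool]:
    theta = theta0.copy()
    f, g = obj.value_grad(theta)
    if g is None:
        raise ConvergenceError("infeasible starting values")
    for it in range(max_iter):
        gnorm = float(np.max(np.abs(g))) if g is not None else math.inf
        if gnorm < gtol:
            return theta, f, gnorm, it, True
        try:
            H = obj.fisher_information(theta)
        except np.linalg.LinAlgError:
            break
        ridge = 0.0
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(H + ridge * np.eye(len(theta)), g)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-8)
        if step is None:
            break
        alpha = 1.0
        improved = False
        for _ in range(40):
            cand = theta - alpha * step
            f_new, g_new = obj.value_grad(cand)
            if g_new is not None and f_new < f + 1e-14:
                theta, f, g = cand, f_new, g_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    gnorm = float(np.max(np.abs(g))) if g is not None else math.inf
    return theta, f, gnorm, max_iter, gnorm < gtol


def fit_ml_cov(
    model: SemModel,
    samples: list[tuple[np.ndarray, int]],
    theta0: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 10_000,
) -> SemFit:
    """Fit the model to one or more sample covariance matrices sharing θ.

    ``samples`` is a list of (S, n) pairs; the objective is the n-weighted
    mean of the per-group ML discrepancies, so ``chisq = sum_g n_g F_g``.
    """
    obj = _MLObjective(model, samples)
    theta0 = model.start_values(obj.samples) if theta0 is None else np.asarray(theta0, float)
    theta, f, gnorm, n_iter, ok = _fisher_scoring(obj, theta0, gtol, max_iter)
    if not ok:
        # fall back to a quasi-Newton pass, then polish with scoring again
        def fun(th):
            v, g = obj.value_grad(th)
            if g is None:
                return 1e12, np.zeros_like(th)
            return v, g

        res = optimize.minimize(
            fun, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-10},
        )
        theta, f, gnorm, n2, ok = _fisher_scoring(obj, res.x, gtol, 200)
        n_iter += n2
    if not ok:
        raise ConvergenceError(
            f"no convergence: gradient inf-norm {gnorm:.3g} > {gtol:g} "
            f"after {n_iter} iterations (F={f:.6g})"
        )
    B, Psi = model.unpack(theta)
    state = obj._implied(theta)
    _A, sigma, chol = state
    n_total = obj.n_total
    # SEs from the inverse expected information, scaled by 1/N
    H = obj.fisher_information(theta)
    cov = 2.0 / n_total * np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    logdet = 2 * np.log(np.diag(chol)).sum()
    sigma_inv = linalg.cho_solve((chol, True), np.eye(model.p))
    loglik = 0.0
    for (S, n) in obj.samples:
        loglik -= 0.5 * n * (logdet + float(np.sum(sigma_inv * S)) + model.p * math.log(2 * math.pi))
    f = max(f, 0.0)
    chisq = n_total * f
    df = model.n_moments * len(obj.samples) - model.t
    return SemFit(
        model=model, samples=obj.samples, theta=theta, B=B, Psi=Psi, sigma=sigma,
        f_ml=f, chisq=chisq, df=df, loglik=loglik, se=se,
        converged=True, n_iter=n_iter, grad_norm=gnorm,
    )


def zscore_rows(values: np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0, variance 1 (divisor N)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance row; cannot standardize")
    return (values - mu) / sd


def fit_ml(
    model: SemModel,
    matrix: ExpressionMatrix,
    sample_ids: list[str] | None = None,
    gtol: float = 1e-6,
    max_iter: int = 10_000,
) -> SemFit:
    """Single-group fit: rows z-scored, S with divisor N."""
    sub = matrix.subset_genes(model.variables)
    if sample_ids is not None:
        sub = sub.subset_samples(sample_ids)
    n = sub.n_samples
    if n <= model.p:
        logger.warning("n=%d <= p=%d variables; fit may be unstable", n, model.p)
    z = zscore_rows(sub.values)
    S = z @ z.T / n
    return fit_ml_cov(model, [(S, n)], gtol=gtol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# fit assessment


def _cov2cor(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _independence_chisq(samples: list[tuple[np.ndarray, int]], p: int,
                        fixed_variance_idx: tuple[int, ...]) -> tuple[float, int]:
    """Baseline model: variances only (MLE ψ_ii = weighted mean S_ii, closed form)."""
    n_total = sum(n for _, n in samples)
    S_bar_diag = sum((n / n_total) * np.diag(S) for S, n in samples)
    sigma = np.diag(S_bar_diag)
    logdet = float(np.log(S_bar_diag).sum())
    chisq = 0.0
    for S, n in samples:
        _sign, lds = np.linalg.slogdet(S)
        f = logdet - lds + float(np.sum(np.diag(S) / S_bar_diag)) - p
        chisq += n * f
    n_moments = p * (p + 1) // 2 - len(fixed_variance_idx)
    t_base = p - len(fixed_variance_idx)
    df = n_moments * len(samples) - t_base
    return chisq, df


def fit_indices(fit: SemFit) -> FitIndices:
    """χ² p-value, RMSEA (N in the denominator), SRMR over all unique cells
    of the correlation residuals (diagonal included), CFI against the
    independence baseline, AIC and BIC."""
    n = fit.n
    chisq, df = fit.chisq, fit.df
    if df == 0:
        pvalue, rmsea = 1.0, 0.0
        logger.info("df=0: rmsea=0 and pvalue=1 by convention")
    else:
        pvalue = float(stats.chi2.sf(chisq, df))
        rmsea = math.sqrt(max(chisq - df, 0.0) / (df * n))
    # SRMR: n-weighted mean squared correlation residual across groups
    p = fit.model.p
    resid_sq = 0.0
    iu = np.triu_indices(p)
    for S, n_g in fit.samples:
        r = _cov2cor(S)[iu] - _cov2cor(fit.sigma)[iu]
        resid_sq += (n_g / n) * float(np.mean(r ** 2))
    srmr = math.sqrt(resid_sq)
    chisq_b, df_b = _independence_chisq(fit.samples, p, fit.model.fixed_variance_idx)
    denom = max(chisq_b - df_b, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chisq - df, 0.0) / denom
    cfi = min(max(cfi, 0.0), 1.0)
    aic = -2.0 * fit.loglik + 2.0 * fit.npar
    bic = -2.0 * fit.loglik + fit.npar * math.log(n)
    return FitIndices(chisq, df, pvalue, rmsea, srmr, cfi, aic, bic, npar=fit.npar)


def rmsea_from_chisq(chisq: float, df: int, n: int) -> float:
    """RMSEA from summary statistics alone (sample-size N in the denominator)."""
    if df == 0:
        return 0.0
    return math.sqrt(max(chisq - df, 0.0) / (df * n))


def parameter_table(fit: SemFit) -> pd.DataFrame:
    rows = []
    for (lhs, op, rhs), est, se in zip(fit.model.param_labels(), fit.theta, fit.se):
        z = est / se if se > 0 else math.nan
        rows.append({
            "lhs": lhs, "op": op, "rhs": rhs, "est": est, "se": se, "z": z,
            "ci_lower": est - Z95 * se, "ci_upper": est + Z95 * se,
        })
    return pd.DataFrame(rows)


def modification_indices(
    fit: SemFit,
    candidates: list[tuple[str, str, str]] | None = None,
) -> list[ModificationIndex]:
    """Univariate score statistics for currently fixed parameters.

    ``mi = (N/2) g² / h`` with g the gradient of the discrepancy at θ̂ and h
    the efficient information (curvature adjusted for the free parameters);
    ``epc = -g / h``.  Default candidates: every fixed off-diagonal β and
    every fixed off-diagonal ψ not touching a fixed-variance variable.
    Sorted by mi descending.
    """
    model = fit.model
    vidx = {v: i for i, v in enumerate(model.variables)}
    fixed_set = set(model.fixed_variance_idx)
    cand_b: list[tuple[int, int]] = []
    cand_p: list[tuple[int, int]] = []
    if candidates is None:
        for i in range(model.p):
            for j in range(model.p):
                if i == j or model.b_free[i, j] or i in fixed_set:
                    continue
                cand_b.append((i, j))
        for i in range(model.p):
            for j in range(i):
                if model.psi_free[i, j] or i in fixed_set or j in fixed_set:
                    continue
                cand_p.append((i, j))
    else:
        for lhs, op, rhs in candidates:
            i, j = vidx[lhs], vidx[rhs]
            if op == "~":
                if not model.b_free[i, j]:
                    cand_b.append((i, j))
            elif op == "~~":
                i, j = max(i, j), min(i, j)
                if not model.psi_free[i, j]:
                    cand_p.append((i, j))
            else:
                raise ValueError(f"unknown op {op!r}")
    obj = _MLObjective(model, fit.samples)
    t = model.t
    out: list[ModificationIndex] = []
    all_cands = [("~", ij) for ij in cand_b] + [("~~", ij) for ij in cand_p]
    g_all = obj.gradient_at(fit.theta, cand_b, cand_p)
    H_full = obj.fisher_information(fit.theta, extra_b=cand_b, extra_psi=cand_p)
    H_ff = H_full[:t, :t]
    H_ff_inv = np.linalg.pinv(H_ff)
    n = fit.n
    for k, (op, (i, j)) in enumerate(all_cands):
        c = t + k
        h_eff = H_full[c, c] - H_full[c, :t] @ H_ff_inv @ H_full[:t, c]
        if h_eff <= 1e-12:
            logger.warning("singular information for candidate %s %s %s; skipped",
                           model.variables[i], op, model.variables[j])
            continue
        g = g_all[k]
        mi = 0.5 * n * g * g / h_eff
        epc = -g / h_eff
        out.append(ModificationIndex(model.variables[i], op, model.variables[j], mi, epc))
    out.sort(key=lambda m: -m.mi)
    return out


def add_paths_refit(
    fit: SemFit,
    new_edges: list[tuple[str, str, str]],
    gtol: float = 1e-6,
) -> SemFit:
    """Refit with additional free parameters, warm-started from θ̂.

    Each addition is ``(lhs, "~", rhs)`` for a directed path rhs → lhs or
    ``(lhs, "~~", rhs)`` for a covariance.  Duplicates and identification
    violations raise.
    """
    model = fit.model
    vidx = {v: i for i, v in enumerate(model.variables)}
    extra_b: list[tuple[int, int]] = []
    extra_p: list[tuple[int, int]] = []
    for lhs, op, rhs in new_edges:
        i, j = vidx[lhs], vidx[rhs]
        if op == "~":
            if (i, j) in extra_b:
                raise ValueError(f"duplicate addition {lhs} ~ {rhs}")
            extra_b.append((i, j))
        elif op == "~~":
            pair = (max(i, j), min(i, j))
            if pair in extra_p:
                raise ValueError(f"duplicate addition {lhs} ~~ {rhs}")
            extra_p.append(pair)
        else:
            raise ValueError(f"unknown op {op!r}")
    new_model = model.copy_with(extra_beta=extra_b, extra_psi=extra_p)
    # warm start: old estimates, new parameters at 0
    theta0 = np.zeros(new_model.t)
    old = dict(zip(model.param_labels(), fit.theta))
    for k, lab in enumerate(new_model.param_labels()):
        if lab in old:
            theta0[k] = old[lab]
        elif lab[1] == "~~":
            i, j = vidx[lab[0]], vidx[lab[2]]
            if i == j:
                theta0[k] = 0.5
    return fit_ml_cov(new_model, fit.samples, theta0=theta0, gtol=gtol)
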