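"""Two-group perturbation analysis: base / node-effects / edge-effects models.

* base  — pooled single-group fit ignoring group membership.
* node  — pooled model augmented with an exogenous 0/1 group variable sent
  into every node (detects baseline expression shifts).
* edge  — two-group fit with all parameters free per group (detects
  rewired path coefficients).

Likelihood-ratio tests compare each effect model against its nested base
counterpart fit to the same moments; Brown's method combines dependent
p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathsem.expression_io import ExpressionMatrix, GroupLabels
from pathsem.sem import (
    FitIndices,
    SemFit,
    SemModel,
    Z95,
    fit_indices,
    fit_ml_cov,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupModelSet",
    "NodeEffect",
    "EdgeEffect",
    "BrownResult",
    "LrtResult",
    "fit_group_models",
    "lrt_compare",
    "node_effects",
    "edge_effects",
    "brown_combined",
]

GROUP_VAR = "group"


@dataclass
class LrtResult:
    delta_chisq: float
    delta_df: int
    pvalue: float


@dataclass
class NodeEffect:
    lhs: str
    op: str
    rhs: str
    est: float
    se: float
    z: float
    ci_lower: float
    ci_upper: float


@dataclass
class EdgeEffect:
    lhs: str
    op: str
    rhs: str
    est0: float
    est1: float
    d_est: float
    d_se: float
    d_z: float
    d_lower: float
    d_upper: float


@dataclass
class BrownResult:
    X: float
    E: float
    V: float
    c: float
    f: float
    p_combined: float


@dataclass
class EdgeModelFit:
    """Two-group fit with all parameters free per group."""

    fit0: SemFit
    fit1: SemFit

    @property
    def chisq(self) -> float:
        return self.fit0.chisq + self.fit1.chisq

    @property
    def df(self) -> int:
        return self.fit0.df + self.fit1.df

    @property
    def npar(self) -> int:
        return self.fit0.npar + self.fit1.npar

    @property
    def n(self) -> int:
        return self.fit0.n + self.fit1.n

    @property
    def loglik(self) -> float:
        return self.fit0.loglik + self.fit1.loglik

    @property
    def pvalue(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.chisq, self.df))


@dataclass
class GroupModelSet:
    model: SemModel
    fit_base: SemFit
    fit_node: SemFit
    fit_edge: EdgeModelFit
    fit_base_node: SemFit   # node model with all group paths fixed at 0
    fit_base_edge: SemFit   # two-group fit with shared parameters
    lrt_node: LrtResult
    lrt_edge: LrtResult
    alpha: float = 0.05

    def comparison_table(self) -> pd.DataFrame:
        """Model-comparison table: one row per model with the standard indices."""
        rows = []
        for name, fit in (("base", self.fit_base), ("node", self.fit_node)):
            idx = fit_indices(fit)
            rows.append({"model": name, **idx.as_dict()})
        rows.append({"model": "edge", **_edge_indices(self.fit_edge).as_dict()})
        return pd.DataFrame(rows)

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"comparison": "node_vs_base", "delta_chisq": self.lrt_node.delta_chisq,
             "delta_df": self.lrt_node.delta_df, "pvalue": self.lrt_node.pvalue},
            {"comparison": "edge_vs_base", "delta_chisq": self.lrt_edge.delta_chisq,
             "delta_df": self.lrt_edge.delta_df, "pvalue": self.lrt_edge.pvalue},
        ])


def _edge_indices(edge: EdgeModelFit) -> FitIndices:
    n = edge.n
    chisq, df = edge.chisq, edge.df
    pvalue = 1.0 if df == 0 else float(stats.chi2.sf(chisq, df))
    rmsea = 0.0 if df == 0 else math.sqrt(max(chisq - df, 0.0) / (df * n))
    i0 = fit_indices(edge.fit0)
    i1 = fit_indices(edge.fit1)
    w0, w1 = edge.fit0.n / n, edge.fit1.n / n
    srmr = math.sqrt(w0 * i0.srmr ** 2 + w1 * i1.srmr ** 2)
    from pathsem.sem import _independence_chisq  # per-group baselines, summed

    cb0, db0 = _independence_chisq(edge.fit0.samples, edge.fit0.model.p,
                                   edge.fit0.model.fixed_variance_idx)
    cb1, db1 = _independence_chisq(edge.fit1.samples, edge.fit1.model.p,
                                   edge.fit1.model.fixed_variance_idx)
    chisq_b, df_b = cb0 + cb1, db0 + db1
    denom = max(chisq_b - df_b, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else min(max(1.0 - max(chisq - df, 0.0) / denom, 0.0), 1.0)
    aic = -2.0 * edge.loglik + 2 * edge.npar
    bic = -2.0 * edge.loglik + edge.npar * math.log(n)
    return FitIndices(chisq, df, pvalue, rmsea, srmr, cfi, aic, bic, npar=edge.npar)


def _augment_with_group(model: SemModel, free_gamma: bool) -> SemModel:
    """Append an exogenous group variable with variance fixed at 1 and
    (optionally free) paths into every original node."""
    p = model.p
    b = np.zeros((p + 1, p + 1), bool)
    b[:p, :p] = model.b_free
    if free_gamma:
        b[:p, p] = True
    psi = np.zeros((p + 1, p + 1), bool)
    psi[:p, :p] = model.psi_free
    fixed = np.zeros((p + 1, p + 1))
    fixed[:p, :p] = model.psi_fixed
    fixed[p, p] = 1.0
    return SemModel(
        list(model.variables) + [GROUP_VAR], b, psi, fixed,
        tuple(model.fixed_variance_idx) + (p,),
    )


def fit_group_models(
    model: SemModel,
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    alpha: float = 0.05,
    gtol: float = 1e-6,
) -> GroupModelSet:
    """Fit the base / node / edge model triple on pooled-standardized data.

    All variables are z-scored with pooled statistics (divisor N) so group
    mean differences survive standardization and are visible to the node
    model.  The edge model uses per-group covariances about group means;
    its base counterpart shares one parameter vector across both groups.
    """
    labels.validate_against(matrix)
    sub = matrix.subset_genes(model.variables)
    vec = labels.vector_for(sub.sample_ids)
    n0, n1 = int((vec == 0).sum()), int((vec == 1).sum())
    n = n0 + n1
    p = model.p
    if min(n0, n1) < p + 2:
        logger.warning("group sizes (%d, %d) below p + 2 = %d; fits may be unstable",
                       n0, n1, p + 2)
    x = sub.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance node")
    z = (x - mu) / sd

    # base: pooled covariance about the pooled mean
    s_pool = z @ z.T / n
    fit_base = fit_ml_cov(model, [(s_pool, n)], gtol=gtol)

    # node: augmented data with the standardized group indicator
    g = vec.astype(float)
    gz = (g - g.mean()) / g.std()
    za = np.vstack([z, gz])
    s_aug = za @ za.T / n
    model_node = _augment_with_group(model, free_gamma=True)
    model_base_node = _augment_with_group(model, free_gamma=False)
    fit_node = fit_ml_cov(model_node, [(s_aug, n)], gtol=gtol)
    fit_base_node = fit_ml_cov(model_base_node, [(s_aug, n)], gtol=gtol)

    # edge: per-group covariances about group means
    samples_by_group = []
    for code in (0, 1):
        zg = z[:, vec == code]
        zg = zg - zg.mean(axis=1, keepdims=True)
        ng = zg.shape[1]
        samples_by_group.append((zg @ zg.T / ng, ng))
    fit0 = fit_ml_cov(model, [samples_by_group[0]], gtol=gtol)
    fit1 = fit_ml_cov(model, [samples_by_group[1]], gtol=gtol)
    fit_edge = EdgeModelFit(fit0, fit1)
    fit_base_edge = fit_ml_cov(model, samples_by_group, gtol=gtol)

    lrt_node = lrt_compare(fit_base_node, fit_node)
    lrt_edge = lrt_compare(fit_base_edge, fit_edge)
    return GroupModelSet(
        model, fit_base, fit_node, fit_edge, fit_base_node, fit_base_edge,
        lrt_node, lrt_edge, alpha,
    )


def lrt_compare(fit_restricted, fit_full) -> LrtResult:
    """Likelihood-ratio test between nested fits on the same data.

    Negative statistics beyond optimizer noise (1e-6) trigger a warning and
    are clamped at 0.
    """
    d_df = fit_restricted.df - fit_full.df
    if d_df < 0:
        raise ValueError("restricted model must have more df than the full model")
    d_chisq = fit_restricted.chisq - fit_full.chisq
    if d_chisq < 0:
        if d_chisq < -1e-6:
            logger.warning("negative LRT statistic %.3g clamped to 0", d_chisq)
        d_chisq = 0.0
    if d_df == 0:
        return LrtResult(d_chisq, 0, 1.0)
    return LrtResult(d_chisq, d_df, float(stats.chi2.sf(d_chisq, d_df)))


def node_effects(model_set: GroupModelSet) -> tuple[list[NodeEffect], str]:
    """Group→node path estimates plus the node-invariance verdict.

    Verdict: invariance *supported* iff the node model's own χ²
    goodness-of-fit p-value exceeds alpha (the node-vs-base LRT is reported
    separately in the ANOVA table for transparency).
    """
    fit = model_set.fit_node
    rows = []
    for (lhs, op, rhs), est, se in zip(fit.model.param_labels(), fit.theta, fit.se):
        if op == "~" and rhs == GROUP_VAR:
            z = est / se if se > 0 else math.nan
            rows.append(NodeEffect(lhs, op, rhs, est, se, z,
                                   est - Z95 * se, est + Z95 * se))
    verdict = (
        "node invariance supported"
        if fit.pvalue > model_set.alpha
        else "node invariance rejected"
    )
    return rows, verdict


def edge_effects(model_set: GroupModelSet) -> tuple[list[EdgeEffect], str]:
    """Per-edge group differences in path coefficients plus the verdict.

    ``d_est = β̂¹ − β̂⁰``; ``d_se = sqrt(se₀² + se₁²)``.  Verdict: edge
    invariance *rejected* iff the edge-vs-base LRT p-value is below alpha.
    """
    f0, f1 = model_set.fit_edge.fit0, model_set.fit_edge.fit1
    labels = f0.model.param_labels()
    rows = []
    for k, (lhs, op, rhs) in enumerate(labels):
        if op != "~":
            continue
        d_est = float(f1.theta[k] - f0.theta[k])
        d_se = math.sqrt(f0.se[k] ** 2 + f1.se[k] ** 2)
        d_z = d_est / d_se if d_se > 0 else math.nan
        rows.append(EdgeEffect(
            lhs, op, rhs, float(f0.theta[k]), float(f1.theta[k]),
            d_est, d_se, d_z, d_est - Z95 * d_se, d_est + Z95 * d_se,
        ))
    verdict = (
        "edge invariance rejected"
        if model_set.lrt_edge.pvalue < model_set.alpha
        else "edge invariance supported"
    )
    return rows, verdict


def _brown_cov(rho: float) -> float:
    """Moment approximation of cov(-2 ln p_i, -2 ln p_j) for correlated
    test statistics (cubic polynomial, odd-extended to negative rho)."""
    a = abs(rho)
    val = a * (3.263 + a * (0.710 + 0.027 * a))
    return math.copysign(val, rho)


def brown_combined(p_values, stat_corr=None) -> BrownResult:
    """Brown's method for combining dependent p-values.

    With a zero off-diagonal correlation matrix this reduces exactly to
    Fisher's combination (χ² with 2k df).
    """
    p = np.asarray(p_values, float)
    k = len(p)
    if k < 1:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if stat_corr is None:
        corr = np.eye(k)
    else:
        corr = np.asarray(stat_corr, float)
        if corr.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
    X = float(-2.0 * np.log(p).sum())
    E = 2.0 * k
    cov_sum = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            cov_sum += _brown_cov(corr[i, j])
    V = 4.0 * k + 2.0 * cov_sum
    c = V / (2.0 * E)
    f = 2.0 * E * E / V
    p_combined = float(stats.chi2.sf(X / c, f))
    return BrownResult(X, E, V, c, f, p_combined)
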