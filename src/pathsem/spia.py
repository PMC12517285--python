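"""Signaling-pathway impact analysis: over-representation plus perturbation accumulation.

Each pathway gets a hypergeometric over-representation p-value (pNDE), a
bootstrap p-value for the total net perturbation accumulation tA (pPERT),
and the combined ``pG = c - c ln c`` with ``c = pNDE * pPERT``, BH-adjusted
across pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathsem.graphs import PathwayGraph
from pathsem.sam import SamResult

logger = logging.getLogger(__name__)

__all__ = [
    "SpiaParams",
    "ora_pnde",
    "perturbation_factors",
    "ppert_bootstrap",
    "combine_global_p",
    "rank_pathways",
]


@dataclass
class SpiaParams:
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


def ora_pnde(m: int, k: int, D: int, G: int) -> float:
    """Upper-tail hypergeometric P(X >= m), X ~ Hypergeom(G, D, k)."""
    if not (0 <= m <= min(k, D)):
        raise ValueError(f"m={m} outside [0, min(k={k}, D={D})]")
    if k > G or D > G:
        raise ValueError("k and D must not exceed the universe size G")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, G, D, k))


def _propagation_matrix(graph: PathwayGraph) -> tuple[np.ndarray, list[str]]:
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    out_deg = {n: 0 for n in nodes}
    for (u, _v) in graph.directed_edges:
        out_deg[u] += 1
    M = np.zeros((len(nodes), len(nodes)))
    for (u, v), sign in graph.directed_edges.items():
        M[idx[v], idx[u]] = sign / out_deg[u]
    return M, nodes


def perturbation_factors(
    graph: PathwayGraph, delta_e: dict[str, float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve ``PF = dE + M PF`` exactly; returns (PF, Acc, tA).

    ``M[i, j] = sign(j->i) / outdegree(j)``; Acc = PF - dE; tA = sum(Acc).
    """
    if len(graph.nodes) == 0:
        raise ValueError("graph has no nodes")
    M, nodes = _propagation_matrix(graph)
    if isinstance(delta_e, dict):
        de = np.array([delta_e.get(n, 0.0) for n in nodes])
    else:
        de = np.asarray(delta_e, float)
        if de.shape != (len(nodes),):
            raise ValueError("delta_e length does not match node count")
    A = np.eye(len(nodes)) - M
    if abs(np.linalg.det(A)) < 1e-12:
        raise np.linalg.LinAlgError(
            f"(I - M) singular for pathway {graph.name!r}"
        )
    pf = np.linalg.solve(A, de)
    acc = pf - de
    return pf, acc, float(acc.sum())


def ppert_bootstrap(
    graph: PathwayGraph,
    ta_observed: float,
    de_value_pool: np.ndarray,
    n_de_on_pathway: int,
    params: SpiaParams,
) -> float:
    """Two-sided, median-centred bootstrap p-value for tA.

    Each iteration assigns *n_de_on_pathway* values drawn from the pool to
    uniformly chosen pathway genes and recomputes tA; the add-one estimator
    ``(#{|tA_b - med| >= |tA_obs - med|} + 1) / (n_boot + 1)`` is returned.
    """
    pool = np.asarray(de_value_pool, float)
    if pool.size == 0:
        raise ValueError("de_value_pool is empty")
    if n_de_on_pathway < 1:
        raise ValueError("n_de_on_pathway must be >= 1")
    M, nodes = _propagation_matrix(graph)
    p = len(nodes)
    n_on = min(n_de_on_pathway, p)
    A_inv = np.linalg.inv(np.eye(p) - M)
    ones = np.ones(p)
    rng = np.random.default_rng(params.seed)
    ta_b = np.empty(params.n_boot)
    for b in range(params.n_boot):
        de = np.zeros(p)
        pos = rng.choice(p, size=n_on, replace=False)
        de[pos] = rng.choice(pool, size=n_on, replace=True)
        # tA = 1'(PF - dE) = 1'(A_inv - I) dE
        ta_b[b] = ones @ (A_inv @ de - de)
    med = float(np.median(ta_b))
    exceed = int(np.sum(np.abs(ta_b - med) >= abs(ta_observed - med)))
    return (exceed + 1) / (params.n_boot + 1)


def combine_global_p(p_nde: float, p_pert: float) -> float:
    """Fisher-style product combination ``pG = c - c ln c``, ``c = pNDE * pPERT``."""
    if not (0 < p_nde <= 1) or not (0 < p_pert <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = p_nde * p_pert
    if c == 1.0:
        return 1.0
    return c - c * math.log(c)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def rank_pathways(
    pathways: list[PathwayGraph],
    deg: SamResult,
    universe_genes: list[str],
    params: SpiaParams | None = None,
) -> pd.DataFrame:
    """SPIA ranking table over user-supplied pathway graphs.

    The DE universe is the full gene list of the expression matrix; per-gene
    evidence dE is the SAM relative difference r for called DEGs (0
    elsewhere).  Pathways on which (I - M) is singular are reported with
    status ``singular`` and excluded from ranking.
    """
    if not pathways:
        raise ValueError("empty pathway list")
    params = params or SpiaParams()
    universe = set(universe_genes)
    G = len(universe)
    deg_set = deg.deg_set & universe
    D = len(deg_set)
    fc = deg.fold_changes()
    pool = np.array([fc[g] for g in sorted(deg_set)]) if deg_set else np.array([])

    rows = []
    for pw in pathways:
        pw_genes = [g for g in pw.nodes if g in universe]
        k = len(pw_genes)
        on = sorted(set(pw_genes) & deg_set)
        m = len(on)
        p_nde = ora_pnde(m, k, D, G) if k else 1.0
        status = "ok"
        ta = 0.0
        p_pert = 1.0
        if m > 0:
            delta_e = {g: fc[g] for g in on}
            try:
                _, _, ta = perturbation_factors(pw, delta_e)
                p_pert = ppert_bootstrap(pw, ta, pool, m, params)
            except np.linalg.LinAlgError:
                status = "singular"
                logger.warning("pathway %s dropped: (I - M) singular", pw.name)
        p_g = combine_global_p(p_nde, p_pert) if status == "ok" else math.nan
        rows.append(
            {"pathway": pw.name, "k": k, "m": m, "pNDE": p_nde, "tA": ta,
             "pPERT": p_pert, "pG": p_g, "status": status}
        )
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["pG_fdr"] = math.nan
    if ok.any():
        table.loc[ok, "pG_fdr"] = bh_adjust(table.loc[ok, "pG"].to_numpy())
    table = table.sort_values(
        ["status", "pG", "pathway"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return table
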