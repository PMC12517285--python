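"""Significance Analysis of Microarrays (SAM), two-class unpaired.

Per gene, a modified t-statistic ``d = r / (s + s0)`` is compared against
expected order statistics from label permutations; a delta band around the
identity line on the (expected, observed) quantile plot calls DEGs, and the
FDR is the median number of permuted statistics beyond the cutoffs divided
by the number of calls.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from pathsem.expression_io import ExpressionMatrix, GroupLabels

logger = logging.getLogger(__name__)

__all__ = [
    "SamParams",
    "SamResult",
    "PermutationNull",
    "sam_statistics",
    "estimate_s0",
    "permutation_null",
    "call_degs",
    "run_sam",
]


@dataclass
class SamParams:
    delta: float = 1.0
    n_perm: int = 100
    seed: int = 0
    s0_mode: str = "auto"  # auto | fixed
    s0_value: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.s0_mode not in ("auto", "fixed"):
            raise ValueError("s0_mode must be 'auto' or 'fixed'")
        if self.s0_mode == "fixed":
            if self.s0_value is None or self.s0_value < 0:
                raise ValueError("fixed s0 requires a non-negative s0_value")


@dataclass
class PermutationNull:
    """Expected order statistics plus the per-permutation sorted statistics."""

    dbar_e: np.ndarray          # mean k-th order statistic, ascending
    d_perm: np.ndarray          # (n_perm, n_genes), each row sorted ascending
    exhaustive: bool = False


@dataclass
class SamResult:
    gene_ids: list[str]
    r: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s0: float
    expected: np.ndarray
    cut_up: float
    cut_low: float
    deg_ids: list[str]
    fdr: float
    delta: float
    direction: dict[str, str] = field(default_factory=dict)  # gene -> up/down

    @property
    def deg_set(self) -> set[str]:
        return set(self.deg_ids)

    def fold_changes(self) -> dict[str, float]:
        """Per-called-gene relative difference (log2 units, group1 - group0)."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return {g: float(self.r[idx[g]]) for g in self.deg_ids}


def _group_indices(matrix: ExpressionMatrix, labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    labels.validate_against(matrix)
    vec = labels.vector_for(matrix.sample_ids)
    g0 = np.flatnonzero(vec == 0)
    g1 = np.flatnonzero(vec == 1)
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError(f"each group needs >= 2 samples (got {len(g0)}, {len(g1)})")
    return g0, g1


def _rs_from_values(values: np.ndarray, g0: np.ndarray, g1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x0 = values[:, g0]
    x1 = values[:, g1]
    n0, n1 = len(g0), len(g1)
    r = x1.mean(axis=1) - x0.mean(axis=1)
    ss = ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    a = (1.0 / n0 + 1.0 / n1) / (n0 + n1 - 2)
    s = np.sqrt(a * ss)
    return r, s


def sam_statistics(
    matrix: ExpressionMatrix, labels: GroupLabels, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative difference ``r``, pooled scatter ``s`` and statistic ``d = r/(s+s0)``."""
    g0, g1 = _group_indices(matrix, labels)
    r, s = _rs_from_values(matrix.values, g0, g1)
    denom = s + s0
    if np.any(denom == 0):
        gene = matrix.gene_ids[int(np.flatnonzero(denom == 0)[0])]
        raise ValueError(f"s + s0 is zero for gene {gene!r}; use a positive s0")
    return r, s, r / denom


def estimate_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Pick the fudge factor minimizing the coefficient of variation of
    window-wise MADs of ``d`` across s-quantile windows.

    Candidates are 0 and the 5,10,...,100 percentiles of ``s``; ties go to the
    smallest candidate.
    """
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    n = len(s)
    if n < 20:
        raise ValueError("estimate_s0 requires at least 20 genes")
    if np.all(s == 0):
        raise ValueError("all scatter values are zero; s0 cannot be estimated")
    candidates = [0.0] + [float(np.percentile(s, q)) for q in range(5, 105, 5)]
    n_win = max(1, min(100, n // 20))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_win)
    best_cv = math.inf
    best_s0 = 0.0
    for cand in candidates:
        denom = s + cand
        if np.any(denom == 0):
            continue
        d = r / denom
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv * (1 - 1e-12):
            best_cv = cv
            best_s0 = cand
        elif abs(cv - best_cv) <= 1e-12 * max(1.0, best_cv):
            best_s0 = min(best_s0, cand)
    logger.info("estimated s0 = %.5g (window CV %.4g)", best_s0, best_cv)
    return best_s0


def _all_assignments(n: int, n1: int) -> list[np.ndarray]:
    out = []
    for comb in itertools.combinations(range(n), n1):
        vec = np.zeros(n, dtype=int)
        vec[list(comb)] = 1
        out.append(vec)
    return out


def permutation_null(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    n_perm: int,
    seed: int,
    s0: float = 0.0,
    permutations: list[np.ndarray] | None = None,
) -> PermutationNull:
    """Expected order statistics of ``d`` under random label reassignment.

    Permutations are sampled uniformly with replacement (the identity is
    permitted); when the number of distinct assignments is at most *n_perm*
    they are enumerated exhaustively instead.  *permutations* overrides
    sampling with explicit 0/1 label vectors (test hook).
    """
    g0, g1 = _group_indices(matrix, labels)
    n = matrix.n_samples
    n1 = len(g1)
    exhaustive = False
    if permutations is None:
        total = math.comb(n, n1)
        if total <= n_perm:
            perms = _all_assignments(n, n1)
            exhaustive = True
        else:
            rng = np.random.default_rng(seed)
            perms = []
            for _ in range(n_perm):
                vec = np.zeros(n, dtype=int)
                vec[rng.choice(n, size=n1, replace=False)] = 1
                perms.append(vec)
    else:
        perms = [np.asarray(p, int) for p in permutations]
    d_perm = np.empty((len(perms), matrix.n_genes))
    for b, vec in enumerate(perms):
        p0 = np.flatnonzero(vec == 0)
        p1 = np.flatnonzero(vec == 1)
        r_b, s_b = _rs_from_values(matrix.values, p0, p1)
        d_perm[b] = np.sort(r_b / (s_b + s0))
    return PermutationNull(d_perm.mean(axis=0), d_perm, exhaustive)


def call_degs(
    gene_ids: list[str],
    d: np.ndarray,
    null: PermutationNull,
    params: SamParams,
    r: np.ndarray | None = None,
    s: np.ndarray | None = None,
    s0: float = 0.0,
) -> SamResult:
    """Apply the delta threshold to the (expected, observed) quantile pairs."""
    d = np.asarray(d, float)
    dbar = null.dbar_e
    if len(d) != len(dbar):
        raise ValueError("observed and expected statistics differ in length")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diff = d_sorted - dbar
    up_idx = np.flatnonzero(diff >= params.delta)
    low_idx = np.flatnonzero(-diff >= params.delta)
    cut_up = float(d_sorted[up_idx[0]]) if len(up_idx) else math.inf
    cut_low = float(d_sorted[low_idx[-1]]) if len(low_idx) else -math.inf
    # a gene cannot be simultaneously up and down; guard against crossed cuts
    if cut_low >= cut_up:
        mid = 0.5 * (cut_low + cut_up)
        cut_up = np.nextafter(mid, math.inf)
        cut_low = np.nextafter(mid, -math.inf)
    up = d >= cut_up
    down = d <= cut_low
    called = up | down
    deg_ids = [g for g, c in zip(gene_ids, called) if c]
    direction = {g: ("up" if u else "down") for g, u, c in zip(gene_ids, up, called) if c}
    if called.sum() == 0:
        fdr = math.nan
    else:
        false_counts = (null.d_perm >= cut_up).sum(axis=1) + (null.d_perm <= cut_low).sum(axis=1)
        fdr = min(1.0, float(np.median(false_counts)) / called.sum())
    return SamResult(
        gene_ids=list(gene_ids),
        r=np.asarray(r, float) if r is not None else np.full(len(d), math.nan),
        s=np.asarray(s, float) if s is not None else np.full(len(d), math.nan),
        d=d,
        s0=s0,
        expected=dbar,
        cut_up=cut_up,
        cut_low=cut_low,
        deg_ids=deg_ids,
        fdr=fdr,
        delta=params.delta,
        direction=direction,
    )


def run_sam(matrix: ExpressionMatrix, labels: GroupLabels, params: SamParams) -> SamResult:
    """Full SAM pass: s0 selection, observed statistics, permutation null, calls."""
    r, s = _rs_from_values(matrix.values, *_group_indices(matrix, labels))
    if params.s0_mode == "fixed":
        s0 = float(params.s0_value)
    elif len(r) < 20:
        s0 = float(np.median(s))
        logger.warning("fewer than 20 genes; using s0 = median(s) = %.4g", s0)
    else:
        s0 = estimate_s0(r, s)
    _, _, d = sam_statistics(matrix, labels, s0)
    null = permutation_null(matrix, labels, params.n_perm, params.seed, s0=s0)
    result = call_degs(matrix.gene_ids, d, null, params, r=r, s=s, s0=s0)
    logger.info(
        "SAM: delta=%.3g s0=%.4g called=%d fdr=%.3g",
        params.delta, s0, len(result.deg_ids), result.fdr,
    )
    return result


def write_sam_table(result: SamResult, path) -> None:
    """TSV with per-gene statistics and a trailing summary block."""
    with open(path, "w") as fh:
        fh.write("gene_id\tr\ts\td\tcalled\n")
        for i, g in enumerate(result.gene_ids):
            fh.write(
                f"{g}\t{result.r[i]:.6g}\t{result.s[i]:.6g}\t{result.d[i]:.6g}\t"
                f"{result.direction.get(g, 'no')}\n"
            )
        fh.write(f"# s0\t{result.s0:.6g}\n")
        fh.write(f"# delta\t{result.delta:.6g}\n")
        fh.write(f"# cut_low\t{result.cut_low:.6g}\n")
        fh.write(f"# cut_up\t{result.cut_up:.6g}\n")
        fh.write(f"# n_called\t{len(result.deg_ids)}\n")
        fh.write(f"# fdr\t{result.fdr:.6g}\n")
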