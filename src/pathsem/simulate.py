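"""Synthetic expression data with known structural-model ground truth.

Pathway nodes follow ``y = (I - B_g)^-1 (gamma * g + zeta)`` per group g with
``zeta ~ N(0, Psi)``; a large block of independent background genes (some
mean-shifted in group 1) is appended so differential-expression and
enrichment stages can be exercised with a known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pathsem.expression_io import ExpressionMatrix, GroupLabels
from pathsem.graphs import FamilyMap, PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "PathwayFixture",
    "Scenario",
    "simulate_from_sem",
    "fixture_pathways",
    "end_to_end_scenario",
    "scenario_registry",
]


@dataclass
class SimulationSpec:
    node_names: list[str]
    B0: np.ndarray            # B[i, j] = effect of node j on node i, group 0
    B1: np.ndarray            # same, group 1
    Psi: np.ndarray           # residual covariance, shared unless psi1 is given
    gamma: np.ndarray         # group -> node intercept effects (group 1 only)
    n0: int
    n1: int
    n_background: int = 0
    n_shifted: int = 0
    shift: float = 1.0        # log2-unit mean shift of affected background genes
    noise_sd: float = 1.0
    seed: int = 0
    psi1: np.ndarray | None = None   # group-1 residual covariance override

    def __post_init__(self) -> None:
        p = len(self.node_names)
        self.B0 = np.asarray(self.B0, float)
        self.B1 = np.asarray(self.B1, float)
        self.Psi = np.asarray(self.Psi, float)
        self.gamma = np.asarray(self.gamma, float)
        for name, m in (("B0", self.B0), ("B1", self.B1), ("Psi", self.Psi)):
            if m.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
        if self.gamma.shape != (p,):
            raise ValueError("gamma must have one entry per node")
        if self.psi1 is not None:
            self.psi1 = np.asarray(self.psi1, float)
            if self.psi1.shape != (p, p):
                raise ValueError(f"psi1 must be {p}x{p}")
        for psi in (self.Psi,) + ((self.psi1,) if self.psi1 is not None else ()):
            if not np.allclose(psi, psi.T):
                raise ValueError("Psi must be symmetric")
            if np.any(np.linalg.eigvalsh(psi) <= 0):
                raise ValueError("Psi must be positive definite")
        for name, B in (("B0", self.B0), ("B1", self.B1)):
            if abs(np.linalg.det(np.eye(p) - B)) < 1e-12:
                raise np.linalg.LinAlgError(f"(I - {name}) is singular")
        if min(self.n0, self.n1) < 1 or self.n_shifted > self.n_background:
            raise ValueError("invalid sample or background counts")

    def psi_for(self, group: int) -> np.ndarray:
        return self.psi1 if (group == 1 and self.psi1 is not None) else self.Psi

    def implied_covariance(self, group: int) -> np.ndarray:
        """Population covariance of the pathway nodes in the given group."""
        B = self.B1 if group == 1 else self.B0
        A = np.linalg.inv(np.eye(len(self.node_names)) - B)
        return A @ self.psi_for(group) @ A.T


def simulate_from_sem(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroupLabels]:
    """Draw samples from the group-specific linear SEM plus background genes."""
    rng = np.random.default_rng(spec.seed)
    p = len(spec.node_names)
    blocks = []
    sample_ids: list[str] = []
    assignment: dict[str, int] = {}
    for g, n_g, B in ((0, spec.n0, spec.B0), (1, spec.n1, spec.B1)):
        A = np.linalg.inv(np.eye(p) - B)
        zeta = rng.multivariate_normal(np.zeros(p), spec.psi_for(g), size=n_g)
        mean_term = spec.gamma * g
        y = (zeta + mean_term) @ A.T            # rows = samples
        bg = rng.normal(0.0, spec.noise_sd, size=(n_g, spec.n_background))
        if g == 1 and spec.n_shifted:
            bg[:, : spec.n_shifted] += spec.shift
        block = np.hstack([y, bg]).T            # genes x samples
        order = rng.permutation(n_g)
        block = block[:, order]
        blocks.append(block)
        for k in range(n_g):
            sid = f"g{g}_s{k}"
            sample_ids.append(sid)
            assignment[sid] = g
    gene_ids = list(spec.node_names)
    gene_ids += [f"shifted{k}" for k in range(spec.n_shifted)]
    gene_ids += [f"bg{k}" for k in range(spec.n_background - spec.n_shifted)]
    values = np.hstack(blocks)
    return ExpressionMatrix(gene_ids, sample_ids, values), GroupLabels(assignment)


@dataclass
class PathwayFixture:
    graph: PathwayGraph
    family_map: FamilyMap
    deg_ids: list[str] = field(default_factory=list)


def _chain5() -> PathwayFixture:
    g = PathwayGraph(name="chain5")
    for a, b in zip("ABCD", "BCDE"):
        g.add_edge(a, b, 1)
    return PathwayFixture(g, FamilyMap({}), deg_ids=["A", "E"])


def _diamond() -> PathwayFixture:
    g = PathwayGraph(name="diamond")
    g.add_edge("A", "B", 1)
    g.add_edge("A", "C", 1)
    g.add_edge("B", "D", 1)
    g.add_edge("C", "D", 1)
    return PathwayFixture(g, FamilyMap({}), deg_ids=["A", "D"])


def _inhibit_loop() -> PathwayFixture:
    g = PathwayGraph(name="inhibit-loop")
    g.add_edge("A", "B", 1)
    g.add_edge("B", "C", 1)
    g.add_edge("C", "A", -1)
    return PathwayFixture(g, FamilyMap({}), deg_ids=["A", "C"])


def _fcgamma_toy() -> PathwayFixture:
    """12-node toy receptor-signaling graph with 4 designated DEGs."""
    g = PathwayGraph(name="fcgamma-toy")
    edges = [
        ("FCGR1", "SYK", 1), ("SYK", "CRKL", 1), ("SYK", "PI3K", 1),
        ("PI3K", "RAC1", 1), ("RAC1", "WASF2", 1), ("WASF2", "ARPC4", 1),
        ("WASF2", "ARPC5", 1), ("CRKL", "DOCK2", 1), ("DOCK2", "RAC1", 1),
        ("SYK", "PLA2G4A", 1), ("PIP5K1A", "ARF6", 1), ("ARF6", "PLA2G4A", 1),
        ("PI3K", "PIP5K1A", 1),
    ]
    for u, v, s in edges:
        g.add_edge(u, v, s)
    fam = FamilyMap({"ARPC4": "ARPC", "ARPC5": "ARPC",
                     "PIP5K1A": "PIP5K", "WASF2": "WASF"})
    return PathwayFixture(g, fam, deg_ids=["CRKL", "ARF6", "PLA2G4A", "ARPC4"])


def fixture_pathways() -> dict[str, PathwayFixture]:
    """Bundled deterministic pathway fixtures keyed by name."""
    return {
        "chain5": _chain5(),
        "diamond": _diamond(),
        "inhibit-loop": _inhibit_loop(),
        "fcgamma-toy": _fcgamma_toy(),
    }


def chain_spec(
    betas0: np.ndarray,
    betas1: np.ndarray,
    gamma: np.ndarray | None = None,
    n0: int = 150,
    n1: int = 150,
    n_background: int = 0,
    n_shifted: int = 0,
    shift: float = 1.0,
    seed: int = 0,
) -> SimulationSpec:
    """5-node chain with unit-variance nodes in each group.

    Residual variances are solved so every node has population variance 1,
    making the path coefficients standardized in both groups.
    """
    names = list("ABCDE")
    p = 5
    B0 = np.zeros((p, p))
    B1 = np.zeros((p, p))
    for k in range(4):
        B0[k + 1, k] = betas0[k]
        B1[k + 1, k] = betas1[k]
    psi0 = np.ones(p)
    psi1 = np.ones(p)
    for k in range(4):
        psi0[k + 1] = 1.0 - betas0[k] ** 2
        psi1[k + 1] = 1.0 - betas1[k] ** 2
        if psi0[k + 1] <= 0 or psi1[k + 1] <= 0:
            raise ValueError("|beta| must be < 1 for unit-variance chain")
    return SimulationSpec(
        names, B0, B1, np.diag(psi0),
        np.zeros(p) if gamma is None else gamma,
        n0, n1, n_background, n_shifted, shift, 1.0, seed,
        psi1=np.diag(psi1),
    )


@dataclass
class Scenario:
    name: str
    matrix: ExpressionMatrix
    labels: GroupLabels
    pathways: dict[str, PathwayGraph]
    family_maps: dict[str, FamilyMap]
    truth: dict


def _scenario_null(seed: int) -> Scenario:
    betas = np.full(4, 0.6)
    spec = chain_spec(betas, betas, n0=150, n1=150,
                      n_background=2000, n_shifted=0, seed=seed)
    matrix, labels = simulate_from_sem(spec)
    fix = fixture_pathways()
    return Scenario(
        "null", matrix, labels,
        {"chain5": fix["chain5"].graph},
        {"chain5": fix["chain5"].family_map},
        {"group_effects": False, "perturbed_edge": None, "true_degs": [],
         "spec": spec},
    )


def _decoy_pathways(n_decoys: int, n_shifted_decoys: int) -> dict[str, PathwayGraph]:
    """Null 5-gene chain pathways over background genes; the first few get
    one mean-shifted member each so enrichment alone cannot win."""
    decoys: dict[str, PathwayGraph] = {}
    bg_cursor = 0
    for d in range(n_decoys):
        g = PathwayGraph(name=f"decoy{d:02d}")
        genes = []
        if d < n_shifted_decoys:
            genes.append(f"shifted{d}")
        while len(genes) < 5:
            genes.append(f"bg{bg_cursor}")
            bg_cursor += 1
        for a, b in zip(genes[:-1], genes[1:]):
            g.add_edge(a, b, 1)
        decoys[g.name] = g
    return decoys


def _scenario_perturbed_chain(seed: int) -> Scenario:
    betas0 = np.array([0.6, 0.2, 0.6, 0.6])
    betas1 = np.array([0.6, 0.7, 0.6, 0.6])   # edge B->C differs by 0.5
    spec = chain_spec(betas0, betas1, n0=150, n1=150,
                      n_background=2000, n_shifted=40, shift=1.5, seed=seed)
    # group-1 mean shift of ~1 log2 unit on every pathway node, injected
    # upstream of the (group-0) structural matrix so all nodes become DEGs
    spec.gamma = (np.eye(5) - spec.B0) @ np.ones(5)
    matrix, labels = simulate_from_sem(spec)
    fix = fixture_pathways()
    pathways = {"chain5": fix["chain5"].graph}
    pathways.update(_decoy_pathways(20, 5))
    return Scenario(
        "perturbed-chain", matrix, labels,
        pathways,
        {"chain5": fix["chain5"].family_map},
        {
            "group_effects": True,
            "perturbed_edge": ("C", "~", "B"),
            "d_true": 0.5,
            "perturbed_pathway": "chain5",
            "true_degs": [f"shifted{k}" for k in range(40)] + list("ABCDE"),
            "spec": spec,
        },
    )


_REGISTRY = {
    "null": _scenario_null,
    "perturbed-chain": _scenario_perturbed_chain,
}


def scenario_registry() -> list[str]:
    return sorted(_REGISTRY)


def end_to_end_scenario(name: str, seed: int = 0) -> Scenario:
    """Build a ready-to-run scenario with machine-readable ground truth."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown scenario {name!r}; known: {scenario_registry()}")
    return _REGISTRY[name](seed)
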