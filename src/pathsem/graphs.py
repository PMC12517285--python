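"""Signed directed/bidirected pathway graphs.

A :class:`PathwayGraph` has directed edges (sign +1 activation, -1 inhibition)
and unordered bidirected pairs standing for free covariances.  Operations:
DEG annotation, shortest-path perturbation-module extraction, superfamily
merging, and partial-correlation edge pruning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

from pathsem.expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "FamilyMap",
    "read_pathway_graph",
    "write_pathway_graph",
    "annotate_degs",
    "extract_perturbation_module",
    "merge_pir_superfamilies",
    "prune_by_partial_correlation",
]

_RELATIONS = {"activation": 1, "inhibition": -1}


@dataclass
class PathwayGraph:
    """Signed gene graph: directed edges plus bidirected covariance pairs."""

    name: str = "pathway"
    nodes: list[str] = field(default_factory=list)
    directed_edges: dict[tuple[str, str], int] = field(default_factory=dict)
    bidirected_edges: set[frozenset] = field(default_factory=set)
    deg_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for n in self.nodes:
            if n in seen:
                raise ValueError(f"duplicate node {n!r}")
            seen.add(n)
        for (u, v), sign in self.directed_edges.items():
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +-1, got {sign}")
            for x in (u, v):
                if x not in seen:
                    raise ValueError(f"edge endpoint {x!r} not a declared node")
        for pair in self.bidirected_edges:
            if len(pair) != 2:
                raise ValueError(f"bidirected pair must have 2 distinct nodes: {set(pair)}")
            for x in pair:
                if x not in seen:
                    raise ValueError(f"bidirected endpoint {x!r} not a declared node")
        for n in self.nodes:
            self.deg_flags.setdefault(n, False)

    def add_node(self, node: str) -> None:
        if node not in self.deg_flags:
            self.nodes.append(node)
            self.deg_flags[node] = False

    def add_edge(self, source: str, target: str, sign: int = 1) -> None:
        self.add_node(source)
        self.add_node(target)
        if source == target:
            raise ValueError(f"self-loop {source!r} not allowed")
        self.directed_edges[(source, target)] = sign

    def add_bidirected(self, a: str, b: str) -> None:
        self.add_node(a)
        self.add_node(b)
        self.bidirected_edges.add(frozenset((a, b)))

    def copy(self, name: str | None = None) -> "PathwayGraph":
        return PathwayGraph(
            name or self.name,
            list(self.nodes),
            dict(self.directed_edges),
            set(self.bidirected_edges),
            dict(self.deg_flags),
        )

    @property
    def deg_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.deg_flags[n]]

    def parents(self, node: str) -> list[str]:
        return [u for (u, v) in self.directed_edges if v == node]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        for (u, v), sign in self.directed_edges.items():
            g.add_edge(u, v, sign=sign)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed_edges == other.directed_edges
            and self.bidirected_edges == other.bidirected_edges
        )


@dataclass
class FamilyMap:
    """Partial mapping gene → protein-superfamily label; unmapped genes stand alone."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, f in self.mapping.items():
            if not f:
                raise ValueError(f"empty family id for gene {g!r}")

    def family_of(self, gene: str) -> str | None:
        return self.mapping.get(gene)


def read_family_map(path: str | Path) -> FamilyMap:
    """Two-column TSV/CSV: gene_id, family_id."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) < 2:
                raise ValueError(f"family map line needs 2 columns: {line!r}")
            mapping[parts[0].strip()] = parts[1].strip()
    return FamilyMap(mapping)


def read_pathway_graph(path: str | Path, format: str | None = None) -> PathwayGraph:
    """Read a graph from SIF-like TSV (source, relation, target) or GraphML.

    Relations: ``activation`` (+1), ``inhibition`` (-1), ``covariance``
    (bidirected).  A line with a single token declares an isolated node.
    """
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "sif"
    if fmt == "graphml":
        return _read_graphml(path)
    if fmt != "sif":
        raise ValueError(f"unknown format {fmt!r}")
    graph = PathwayGraph(name=path.stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 1:
                graph.add_node(parts[0])
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            src, rel, dst = parts
            if rel == "covariance":
                graph.add_bidirected(src, dst)
            elif rel in _RELATIONS:
                graph.add_edge(src, dst, _RELATIONS[rel])
            else:
                raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}")
    return graph


def _read_graphml(path: Path) -> PathwayGraph:
    g = nx.read_graphml(path)
    graph = PathwayGraph(name=str(g.graph.get("name", path.stem)))
    for n in g.nodes:
        graph.add_node(str(n))
    for u, v, data in g.edges(data=True):
        rel = str(data.get("relation", data.get("sign", "activation")))
        if rel in ("1", "+1"):
            rel = "activation"
        elif rel == "-1":
            rel = "inhibition"
        if rel == "covariance":
            graph.add_bidirected(str(u), str(v))
        elif rel in _RELATIONS:
            graph.add_edge(str(u), str(v), _RELATIONS[rel])
        else:
            raise ValueError(f"{path}: unknown relation {rel!r} on edge {u}->{v}")
    return graph


def write_pathway_graph(graph: PathwayGraph, path: str | Path) -> None:
    """Write the SIF dialect; isolated nodes get single-token lines."""
    inv = {1: "activation", -1: "inhibition"}
    touched: set[str] = set()
    with open(path, "w") as fh:
        for (u, v), sign in graph.directed_edges.items():
            fh.write(f"{u}\t{inv[sign]}\t{v}\n")
            touched.update((u, v))
        for pair in sorted(graph.bidirected_edges, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\tcovariance\t{b}\n")
            touched.update((a, b))
        for n in graph.nodes:
            if n not in touched:
                fh.write(f"{n}\n")


def annotate_degs(graph: PathwayGraph, deg_ids) -> PathwayGraph:
    """Flag nodes that appear in *deg_ids* (idempotent)."""
    deg_set = set(deg_ids)
    out = graph.copy()
    out.deg_flags = {n: n in deg_set for n in out.nodes}
    n_deg = sum(out.deg_flags.values())
    logger.info("%s: %d/%d nodes flagged as DEGs", graph.name, n_deg, len(out.nodes))
    return out


def extract_perturbation_module(graph: PathwayGraph, deg_ids) -> PathwayGraph:
    """Union of all shortest paths between every ordered DEG pair.

    Directed shortest paths are used; for a DEG pair unreachable in either
    direction the shortest undirected paths are taken as a fallback.  All
    tied shortest paths are retained.  The result is the induced subgraph,
    annotated with the DEG flags.
    """
    deg_set = set(deg_ids) & set(graph.nodes)
    if not deg_set:
        raise ValueError(f"no DEG present in graph {graph.name!r}")
    dg = graph.to_networkx()
    ug = dg.to_undirected()
    keep: set[str] = set(deg_set)
    degs = [n for n in graph.nodes if n in deg_set]
    for i, a in enumerate(degs):
        for b in degs[i + 1:]:
            found = False
            for src, dst in ((a, b), (b, a)):
                try:
                    for p in nx.all_shortest_paths(dg, src, dst):
                        keep.update(p)
                    found = True
                except nx.NetworkXNoPath:
                    pass
            if not found:
                try:
                    for p in nx.all_shortest_paths(ug, a, b):
                        keep.update(p)
                except nx.NetworkXNoPath:
                    pass
    nodes = [n for n in graph.nodes if n in keep]
    module = PathwayGraph(
        name=f"{graph.name}_module",
        nodes=nodes,
        directed_edges={e: s for e, s in graph.directed_edges.items()
                        if e[0] in keep and e[1] in keep},
        bidirected_edges={p for p in graph.bidirected_edges if p <= keep},
    )
    return annotate_degs(module, deg_set)


def merge_pir_superfamilies(
    graph: PathwayGraph, matrix: ExpressionMatrix, fam: FamilyMap
) -> tuple[PathwayGraph, ExpressionMatrix]:
    """Collapse non-DEG nodes sharing a superfamily into one node.

    The merged node's expression profile is the per-sample mean of the
    z-scored member profiles; edges re-attach with their sign (a sign
    conflict on the same ordered pair is an error).  DEG nodes are never
    merged.  Returns the merged graph and a matrix restricted to its nodes.
    """
    missing = [n for n in graph.nodes if n not in matrix.gene_ids]
    if missing:
        raise ValueError(f"module genes missing from expression matrix: {missing}")
    groups: dict[str, list[str]] = {}
    for n in graph.nodes:
        if graph.deg_flags[n]:
            continue
        f = fam.family_of(n)
        if f is not None:
            groups.setdefault(f, []).append(n)
    merge_groups = {f: members for f, members in groups.items() if len(members) >= 2}
    rename: dict[str, str] = {}
    for f, members in merge_groups.items():
        for m in members:
            rename[m] = f
    if not rename:
        return graph.copy(), matrix.subset_genes(list(graph.nodes))

    new_nodes: list[str] = []
    for n in graph.nodes:
        label = rename.get(n, n)
        if label not in new_nodes:
            new_nodes.append(label)
    new_edges: dict[tuple[str, str], int] = {}
    for (u, v), sign in graph.directed_edges.items():
        nu, nv = rename.get(u, u), rename.get(v, v)
        if nu == nv:
            continue  # intra-family edge collapses away
        if (nu, nv) in new_edges and new_edges[(nu, nv)] != sign:
            raise ValueError(f"sign conflict after merge on edge {nu!r}->{nv!r}")
        new_edges[(nu, nv)] = sign
    new_bidir: set[frozenset] = set()
    for pair in graph.bidirected_edges:
        a, b = tuple(pair)
        na, nb = rename.get(a, a), rename.get(b, b)
        if na != nb:
            new_bidir.add(frozenset((na, nb)))
    merged = PathwayGraph(f"{graph.name}_merged", new_nodes, new_edges, new_bidir)
    merged = annotate_degs(merged, graph.deg_nodes)

    frame = matrix.to_frame()
    rows = []
    for label in new_nodes:
        if label in merge_groups:
            z = []
            for m in merge_groups[label]:
                x = frame.loc[m].to_numpy(float)
                sd = x.std()
                if sd == 0:
                    raise ValueError(f"zero variance for family member {m!r}")
                z.append((x - x.mean()) / sd)
            rows.append(np.mean(z, axis=0))
        else:
            rows.append(frame.loc[label].to_numpy(float))
    out_matrix = ExpressionMatrix(new_nodes, list(matrix.sample_ids), np.array(rows))
    logger.info("merged %d genes into %d family nodes", len(rename), len(merge_groups))
    return merged, out_matrix


def _partial_correlation(values: np.ndarray, i: int, j: int, cond: list[int]) -> float:
    """Sample partial correlation of rows i, j given the rows in *cond*."""
    idx = [i, j] + list(cond)
    sub = np.corrcoef(values[idx])
    if len(cond) == 0:
        return float(sub[0, 1])
    prec = np.linalg.pinv(sub)
    denom = math.sqrt(prec[0, 0] * prec[1, 1])
    return float(-prec[0, 1] / denom)


def prune_by_partial_correlation(
    graph: PathwayGraph,
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    conditioning: str = "parents",
) -> PathwayGraph:
    """Drop edges whose (partial) correlation is not significant at *alpha*.

    For a directed edge j→i the conditioning set is the other parents of i
    (``conditioning='parents'``) or all other module nodes
    (``conditioning='full'``).  Bidirected pairs are tested marginally.
    All tests use the Fisher z transform with df ``n - |cond| - 3`` and are
    evaluated on the original graph, so pruning is order-independent.
    """
    if conditioning not in ("parents", "full"):
        raise ValueError("conditioning must be 'parents' or 'full'")
    node_idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [n for n in graph.nodes if n not in node_idx]
    if missing:
        raise ValueError(f"nodes missing from matrix: {missing}")
    values = matrix.values
    sds = values[[node_idx[n] for n in graph.nodes]].std(axis=1)
    if np.any(sds == 0):
        bad = graph.nodes[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"zero-variance node {bad!r}")
    n = matrix.n_samples

    def test(i: str, j: str, cond: list[str]) -> float:
        if n <= len(cond) + 3:
            raise ValueError(
                f"insufficient samples (n={n}) for conditioning set of size {len(cond)}"
            )
        rho = _partial_correlation(values, node_idx[i], node_idx[j], [node_idx[c] for c in cond])
        rho = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        z = math.atanh(rho) * math.sqrt(n - len(cond) - 3)
        return 2 * stats.norm.sf(abs(z))

    kept_edges: dict[tuple[str, str], int] = {}
    for (j, i), sign in graph.directed_edges.items():
        if conditioning == "parents":
            cond = [p for p in graph.parents(i) if p != j]
        else:
            cond = [x for x in graph.nodes if x not in (i, j)]
        p = test(i, j, cond)
        if p < alpha:
            kept_edges[(j, i)] = sign
        else:
            logger.info("pruned %s->%s (p=%.3g)", j, i, p)
    kept_bidir: set[frozenset] = set()
    for pair in graph.bidirected_edges:
        a, b = tuple(pair)
        if test(a, b, []) < alpha:
            kept_bidir.add(pair)
    out = PathwayGraph(
        f"{graph.name}_pruned", list(graph.nodes), kept_edges, kept_bidir,
        dict(graph.deg_flags),
    )
    return out
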