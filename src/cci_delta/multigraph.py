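"""Weighted multipartite interactome graphs and their centralities.

A condition's significant interactions are encoded as a graph
``G = (C, M, E)`` with cell-type nodes ``C``, molecule nodes ``M``
(ligands/receptors), and directed weighted edges ``E``.  Every
significant record contributes a length-3 path

    source cell -> ligand -> receptor -> target cell

(e.g. ``Proximal Tubule -> FLT1 -> VEGFB -> Endothelial``).  A directed
record adds that single path; an undirected record registers two paths,
the second reversed, and each touched edge's weight ``W`` is incremented
once for the record -- the two mirror paths are never double counted.
``W`` therefore accumulates the number of interaction-record occurrences
traversing each edge, and summed over all edges equals three times the
number of registered paths: 3 per directed record, 6 per undirected one
(two disjoint mirror paths).

Centralities: degree / in-degree / out-degree (normalized by n-1),
betweenness over shortest paths with distance 1/W, and Katz solving
``x = alpha * A^T x + 1`` with ``alpha = (1 - epsilon) / |lambda_max|``
of the weighted adjacency matrix, returned with unit Euclidean norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import LRDatabase, SignificantMeans

__all__ = [
    "PathRecord",
    "Multigraph",
    "CentralityReport",
    "build_multigraph",
    "centralities",
]


@dataclass(frozen=True)
class PathRecord:
    """Provenance of one significant record inside the graph."""

    interaction_id: str
    source: str
    target: str
    directed: bool
    paths: tuple[tuple[str, str, str, str], ...]


@dataclass
class Multigraph:
    """The 3-tuple G = (C, M, E) realized as a weighted simple digraph.

    ``graph`` nodes carry ``kind`` in {"cell_type", "molecule"}; edges
    carry the occurrence weight ``W`` (attribute ``weight``).  The path
    registry keeps each record's full path provenance, which the simple
    digraph itself cannot represent.
    """

    graph: nx.DiGraph
    records: list[PathRecord] = field(default_factory=list)

    @property
    def cell_types(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == "cell_type"}

    @property
    def molecules(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == "molecule"}

    @property
    def total_weight(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges(data="weight")))

    @property
    def n_paths(self) -> int:
        return sum(len(r.paths) for r in self.records)


def build_multigraph(sig: SignificantMeans, db: LRDatabase) -> Multigraph:
    """Assemble the interactome graph from significant records.

    Records are processed in (interaction_id, source, target) order, so
    the construction is deterministic.  An interaction id absent from
    the database raises ``KeyError`` naming it; a molecule name clashing
    with a cell-type name raises ``ValueError`` (C and M must stay
    disjoint).
    """
    df = sig.table[sig.table["significant"]].sort_values(
        ["interaction_id", "source", "target"], kind="mergesort"
    )
    unknown = sorted(set(df["interaction_id"]) - set(db.ids))
    if unknown:
        raise KeyError(f"unknown interaction ids in table: {unknown[:5]}")

    cell_types = set(df["source"]) | set(df["target"])
    graph = nx.DiGraph()
    for ct in sorted(cell_types):
        graph.add_node(ct, kind="cell_type")

    records: list[PathRecord] = []
    for row in df.itertuples(index=False):
        pair = db[row.interaction_id]
        g_source, g_target = pair.oriented()
        clash = {g_source, g_target} & cell_types
        if clash:
            raise ValueError(
                f"molecule names collide with cell-type names: {sorted(clash)}"
            )
        for mol in (g_source, g_target):
            if mol not in graph:
                graph.add_node(mol, kind="molecule")
        forward = (row.source, g_source, g_target, row.target)
        paths = [forward]
        if not pair.directed:
            paths.append((row.target, g_target, g_source, row.source))
        touched: set[tuple[str, str]] = set()
        for path in paths:
            for u, v in zip(path[:-1], path[1:]):
                touched.add((u, v))
        # each edge incremented once per record, even with mirror paths
        for u, v in touched:
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += 1
            else:
                graph.add_edge(u, v, weight=1)
        records.append(
            PathRecord(
                interaction_id=row.interaction_id,
                source=row.source,
                target=row.target,
                directed=pair.directed,
                paths=tuple(paths),
            )
        )
    return Multigraph(graph=graph, records=records)


@dataclass
class CentralityReport:
    """Per-node centralities plus the parameters that produced them.

    ``table`` columns: degree, in_degree, out_degree, betweenness, katz.
    ``katz_scale`` is the Euclidean norm of the raw Katz solution, so
    ``katz * katz_scale`` satisfies the pre-normalization fixed point
    ``x = alpha * A^T x + 1``.
    """

    table: pd.DataFrame
    alpha: float
    epsilon: float
    lambda_max: float
    katz_scale: float
    normalized_degree: bool
    normalized_betweenness: bool


def _katz(A: np.ndarray, epsilon: float) -> tuple[np.ndarray, float, float, float]:
    """Solve x = alpha A^T x + 1 with alpha = (1 - epsilon)/|lambda_max|."""
    n = A.shape[0]
    eigvals = np.linalg.eigvals(A)
    lam = float(np.max(np.abs(eigvals))) if n else 0.0
    alpha = 0.0 if lam == 0 else (1.0 - epsilon) / lam
    system = np.eye(n) - alpha * A.T
    try:
        x = np.linalg.solve(system, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"Katz system singular at alpha={alpha!r} (epsilon={epsilon!r})"
        ) from exc
    scale = float(np.linalg.norm(x))
    if scale == 0:
        raise np.linalg.LinAlgError("Katz solution degenerate (zero norm)")
    return x / scale, alpha, lam, scale


def centralities(
    g: Multigraph | nx.DiGraph,
    epsilon: float = 1e-6,
    normalized_degree: bool = True,
    normalized_betweenness: bool = True,
    weighted_degree: bool = False,
) -> CentralityReport:
    """Degree family, betweenness (distance = 1/W) and Katz centralities.

    The attenuation factor targets the reciprocal spectral radius of the
    weighted adjacency matrix; it is shrunk by ``epsilon`` (default 1e-6)
    because the system is exactly singular at 1/|lambda_max|.  Both the
    attenuation and the shrink factor are recorded in the report.
    """
    graph = g.graph if isinstance(g, Multigraph) else g
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("centralities of an empty graph are undefined")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")

    if n == 1:
        deg = indeg = outdeg = {nodes[0]: 0.0}
    elif weighted_degree:
        denom = float(n - 1) if normalized_degree else 1.0
        indeg = {v: graph.in_degree(v, weight="weight") / denom for v in nodes}
        outdeg = {v: graph.out_degree(v, weight="weight") / denom for v in nodes}
        deg = {v: graph.degree(v, weight="weight") / denom for v in nodes}
    elif normalized_degree:
        deg = nx.degree_centrality(graph)
        indeg = nx.in_degree_centrality(graph)
        outdeg = nx.out_degree_centrality(graph)
    else:
        deg = {v: float(graph.degree(v)) for v in nodes}
        indeg = {v: float(graph.in_degree(v)) for v in nodes}
        outdeg = {v: float(graph.out_degree(v)) for v in nodes}

    distance_graph = graph.copy()
    for u, v, w in distance_graph.edges(data="weight", default=1):
        distance_graph[u][v]["distance"] = 1.0 / float(w)
    betw = nx.betweenness_centrality(
        distance_graph, normalized=normalized_betweenness, weight="distance"
    )

    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    katz, alpha, lam, scale = _katz(A, epsilon)

    table = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "in_degree": [indeg[v] for v in nodes],
            "out_degree": [outdeg[v] for v in nodes],
            "betweenness": [betw[v] for v in nodes],
            "katz": katz,
        },
        index=pd.Index(nodes, name="node"),
    )
    return CentralityReport(
        table=table,
        alpha=alpha,
        epsilon=epsilon,
        lambda_max=lam,
        katz_scale=scale,
        normalized_degree=normalized_degree,
        normalized_betweenness=normalized_betweenness,
    )
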