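"""Graph edit distance between ErGs: exact solver and bipartite approximation.

The edit distance between two attributed graphs G_a and G_b is the minimum,
over all edit paths transforming G_a into G_b, of the summed operation
costs, normalized by L = |V_a| + |V_b| so the measure is independent of
graph size:

    GED(G_a, G_b; C) = min_path  ( Σ_t C_t · N_t ) / L

where N_t counts applications of edit-operation kind t along the path.

Two solvers are provided:

``exact_ged``
    Depth-first branch-and-bound over all node mappings (substitution,
    deletion, insertion) with induced edge operations.  Exponential; gated
    by a size bound and used as the oracle for small graphs.

``bipartite_ged``
    The fast polynomial approximation: a square assignment problem over
    nodes (with local incident-edge terms) is solved optimally by the
    Hungarian method, the induced edit path is derived from the node
    assignment, and that path's true cost is returned.  Because the induced
    path is a valid transformation, the result is an upper bound on the
    exact distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cost_model import CostTable, edge_indel, edge_sub, node_indel, node_sub
from .graph_model import ErgGraph

__all__ = [
    "EditPath",
    "DistanceResult",
    "GedSizeError",
    "edit_path_cost",
    "exact_ged",
    "bipartite_ged",
    "compute_ged",
    "apply_edit_path",
    "path_is_valid",
    "pairwise_distances",
]

_BIG = 1.0e8  # infeasible-cell sentinel for assignment matrices

# Op records are (op, source, target) triples; op in {"sub","del","ins"}.
# For node ops source/target are node ids (or None); for edge ops they are
# unordered id pairs (or None).  Identity substitutions are recorded but
# contribute no count (they are not edit operations).


class GedSizeError(ValueError):
    """Exact solver refused: combined order exceeds the configured bound."""


@dataclass
class EditPath:
    """A concrete transformation sequence with per-kind operation counts.

    ``counts`` tallies only true edit operations (identity substitutions,
    which appear in ``node_ops``/``edge_ops`` as mapping records, are
    excluded).  ``L`` is the node-count normalizer |V_a| + |V_b|.
    """

    node_ops: list[tuple] = field(default_factory=list)
    edge_ops: list[tuple] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)
    L: int = 0

    @classmethod
    def from_node_mapping(
        cls, ga: ErgGraph, gb: ErgGraph, mapping: dict[str, str | None]
    ) -> "EditPath":
        """Induce the full edit path from a node mapping.

        ``mapping`` sends every node of ``ga`` to a node of ``gb`` or to
        ``None`` (deletion); nodes of ``gb`` not in the image are inserted.
        Edge operations follow from comparing mapped node pairs, each edge
        counted once.
        """
        node_ops: list[tuple] = []
        edge_ops: list[tuple] = []
        counts: Counter = Counter()
        image = {v for v in mapping.values() if v is not None}
        if len(image) != sum(1 for v in mapping.values() if v is not None):
            raise ValueError("node mapping is not injective")

        for u in ga.nodes:
            v = mapping[u]
            if v is None:
                node_ops.append(("del", u, None))
                counts[node_indel(ga.label_of(u))] += 1
            else:
                node_ops.append(("sub", u, v))
                la, lb = ga.label_of(u), gb.label_of(v)
                if la != lb:
                    counts[node_sub(la, lb)] += 1
        for v in gb.nodes:
            if v not in image:
                node_ops.append(("ins", None, v))
                counts[node_indel(gb.label_of(v))] += 1

        # edges of ga: substituted, kept, or deleted
        for (u1, u2), la in ga.edge_labels.items():
            v1, v2 = mapping[u1], mapping[u2]
            lb = gb.edge_label(v1, v2) if (v1 is not None and v2 is not None) else None
            if lb is None:
                edge_ops.append(("del", (u1, u2), None))
                counts[edge_indel(la)] += 1
            else:
                edge_ops.append(("sub", (u1, u2), (v1, v2)))
                if la != lb:
                    counts[edge_sub(la, lb)] += 1
        # edges of gb not induced by a mapped ga edge: inserted
        inverse = {v: u for u, v in mapping.items() if v is not None}
        for (v1, v2), lb in gb.edge_labels.items():
            u1, u2 = inverse.get(v1), inverse.get(v2)
            if u1 is None or u2 is None or not ga.has_edge(u1, u2):
                edge_ops.append(("ins", None, (v1, v2)))
                counts[edge_indel(lb)] += 1

        return cls(node_ops=node_ops, edge_ops=edge_ops, counts=counts, L=ga.order + gb.order)

    @property
    def n_operations(self) -> int:
        return sum(self.counts.values())


def edit_path_cost(path: EditPath, costs: CostTable, normalize: bool = True) -> float:
    """Total cost Σ_t C_t·N_t of a path, optionally divided by L."""
    total = 0.0
    for kind, n in path.counts.items():
        if kind not in costs.costs:
            raise KeyError(f"path references unknown edit-operation kind {kind!r}")
        total += costs.costs[kind] * n
    if normalize:
        return total / path.L if path.L > 0 else 0.0
    return total


@dataclass
class DistanceResult:
    """A normalized GED value together with the edit path that attains it."""

    distance: float
    raw_cost: float
    path: EditPath
    method: str

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.distance


def _result_from_mapping(
    ga: ErgGraph, gb: ErgGraph, mapping: dict[str, str | None], costs: CostTable, method: str
) -> DistanceResult:
    path = EditPath.from_node_mapping(ga, gb, mapping)
    raw = edit_path_cost(path, costs, normalize=False)
    dist = raw / path.L if path.L > 0 else 0.0
    return DistanceResult(distance=dist, raw_cost=raw, path=path, method=method)


# ---------------------------------------------------------------------------
# Exact solver: branch-and-bound over node mappings
# ---------------------------------------------------------------------------

def exact_ged(
    ga: ErgGraph, gb: ErgGraph, costs: CostTable, size_limit: int = 14
) -> DistanceResult:
    """True minimum of the edit-distance objective, by exhaustive search.

    Nodes of ``ga`` are assigned in declaration order to an unused node of
    ``gb`` or to deletion; edge costs accrue incrementally against already
    assigned nodes; leftover ``gb`` structure is inserted at the leaves.
    The current best total prunes the search.  Ties between equal-cost
    mappings resolve to the first one in candidate order (deterministic).
    """
    if ga.order + gb.order > size_limit:
        raise GedSizeError(
            f"combined order {ga.order + gb.order} exceeds exact-solver bound "
            f"{size_limit}; use bipartite_ged"
        )
    a_nodes = ga.nodes
    b_nodes = gb.nodes

    # initial upper bound: delete everything, insert everything
    best_mapping: dict[str, str | None] = {u: None for u in a_nodes}
    best_cost = edit_path_cost(
        EditPath.from_node_mapping(ga, gb, best_mapping), costs, normalize=False
    )

    phi: dict[str, str | None] = {}
    used: set[str] = set()

    def completion_cost() -> float:
        total = 0.0
        image = used
        for v in b_nodes:
            if v not in image:
                total += costs.node_indel_cost(gb.label_of(v))
        inverse = {v: u for u, v in phi.items() if v is not None}
        for (v1, v2), lb in gb.edge_labels.items():
            u1, u2 = inverse.get(v1), inverse.get(v2)
            if u1 is None or u2 is None:
                total += costs.edge_indel_cost(lb)
        return total

    def step_cost(i: int, u: str, v: str | None) -> float:
        if v is None:
            total = costs.node_indel_cost(ga.label_of(u))
            for j in range(i):
                la = ga.edge_label(a_nodes[j], u)
                if la is not None:
                    total += costs.edge_indel_cost(la)
            return total
        total = costs.node_sub_cost(ga.label_of(u), gb.label_of(v))
        for j in range(i):
            w = phi[a_nodes[j]]
            la = ga.edge_label(a_nodes[j], u)
            lb = gb.edge_label(w, v) if w is not None else None
            if la is not None and lb is not None:
                total += costs.edge_sub_cost(la, lb)
            elif la is not None:
                total += costs.edge_indel_cost(la)
            elif lb is not None:
                total += costs.edge_indel_cost(lb)
        return total

    def dfs(i: int, acc: float) -> None:
        nonlocal best_cost, best_mapping
        if acc >= best_cost:
            return
        if i == len(a_nodes):
            total = acc + completion_cost()
            if total < best_cost:
                best_cost = total
                best_mapping = dict(phi)
            return
        u = a_nodes[i]
        for v in b_nodes:
            if v in used:
                continue
            c = step_cost(i, u, v)
            if acc + c < best_cost:
                phi[u] = v
                used.add(v)
                dfs(i + 1, acc + c)
                used.discard(v)
                del phi[u]
        c = step_cost(i, u, None)
        if acc + c < best_cost:
            phi[u] = None
            dfs(i + 1, acc + c)
            del phi[u]

    dfs(0, 0.0)
    return _result_from_mapping(ga, gb, best_mapping, costs, "exact")


# ---------------------------------------------------------------------------
# Bipartite approximation
# ---------------------------------------------------------------------------

def _incident_edge_term(
    labels_a: Sequence, labels_b: Sequence, costs: CostTable
) -> float:
    """Optimal assignment cost between two incident-edge label multisets.

    Unmatched edges on either side pay their indel cost; matched edges pay
    substitution (0 for identical labels).
    """
    d1, d2 = len(labels_a), len(labels_b)
    if d1 == 0 and d2 == 0:
        return 0.0
    size = d1 + d2
    m = np.full((size, size), _BIG)
    for p, la in enumerate(labels_a):
        for q, lb in enumerate(labels_b):
            m[p, q] = costs.edge_sub_cost(la, lb)
        m[p, d2 + p] = costs.edge_indel_cost(la)
    for q, lb in enumerate(labels_b):
        m[d1 + q, q] = costs.edge_indel_cost(lb)
    m[d1:, d2:] = 0.0
    rows, cols = linear_sum_assignment(m)
    return float(m[rows, cols].sum())


def bipartite_ged(ga: ErgGraph, gb: ErgGraph, costs: CostTable) -> DistanceResult:
    """Upper-bound GED via optimal node assignment with local edge terms.

    Builds the (n1+n2)×(n1+n2) cost matrix — substitution block with
    incident-edge assignment terms, deletion/insertion diagonals charging
    the node indel plus all incident edge indels — solves it with the
    Hungarian method, and scores the edit path induced by the assignment.
    Both orientations of the assignment problem are solved and the cheaper
    induced path kept: optimal assignments are not unique, so this keeps
    the result symmetric in its arguments (and never looser).
    """
    fwd = _bipartite_oriented(ga, gb, costs)
    rev = _bipartite_oriented(gb, ga, costs)
    if rev.distance < fwd.distance:
        inverted = {v: u for u, v in rev._mapping.items() if v is not None}
        mapping = {u: inverted.get(u) for u in ga.nodes}
        return _result_from_mapping(ga, gb, mapping, costs, "bipartite")
    return _result_from_mapping(ga, gb, fwd._mapping, costs, "bipartite")


@dataclass
class _OrientedResult:
    distance: float
    _mapping: dict


def _bipartite_oriented(ga: ErgGraph, gb: ErgGraph, costs: CostTable) -> _OrientedResult:
    n1, n2 = ga.order, gb.order
    if n1 == 0 or n2 == 0:
        # degenerate convention: pure deletion/insertion path
        mapping = {u: None for u in ga.nodes}
        return _OrientedResult(
            _result_from_mapping(ga, gb, mapping, costs, "bipartite").distance, mapping
        )
    a_nodes, b_nodes = ga.nodes, gb.nodes
    inc_a = [ga.incident_edge_labels(u) for u in a_nodes]
    inc_b = [gb.incident_edge_labels(v) for v in b_nodes]

    size = n1 + n2
    m = np.full((size, size), _BIG)
    for i, u in enumerate(a_nodes):
        for j, v in enumerate(b_nodes):
            m[i, j] = costs.node_sub_cost(ga.label_of(u), gb.label_of(v)) + _incident_edge_term(
                inc_a[i], inc_b[j], costs
            )
        m[i, n2 + i] = costs.node_indel_cost(ga.label_of(u)) + sum(
            costs.edge_indel_cost(lab) for lab in inc_a[i]
        )
    for j, v in enumerate(b_nodes):
        m[n1 + j, j] = costs.node_indel_cost(gb.label_of(v)) + sum(
            costs.edge_indel_cost(lab) for lab in inc_b[j]
        )
    m[n1:, n2:] = 0.0

    rows, cols = linear_sum_assignment(m)
    mapping: dict[str, str | None] = {}
    for r, c in zip(rows, cols):
        if r < n1:
            mapping[a_nodes[r]] = b_nodes[c] if c < n2 else None
    return _OrientedResult(
        _result_from_mapping(ga, gb, mapping, costs, "bipartite").distance, mapping
    )


def compute_ged(
    ga: ErgGraph, gb: ErgGraph, costs: CostTable, method: str = "bipartite", **kwargs
) -> DistanceResult:
    """Dispatch to ``exact_ged`` or ``bipartite_ged`` by name."""
    if method == "exact":
        return exact_ged(ga, gb, costs, **kwargs)
    if method == "bipartite":
        return bipartite_ged(ga, gb, costs)
    raise ValueError(f"unknown GED method {method!r}")


# ---------------------------------------------------------------------------
# Path application and validity
# ---------------------------------------------------------------------------

def apply_edit_path(ga: ErgGraph, gb: ErgGraph, path: EditPath) -> ErgGraph:
    """Apply a mapping-derived edit path to ``ga``.

    Target labels are taken from ``gb`` (the path records which target
    element each operation produces).  The result should be label-isomorphic
    to ``gb`` for any valid path.
    """
    out = ErgGraph(id=f"{ga.id}->{gb.id}")
    for op, src, tgt in path.node_ops:
        if op in ("sub", "ins"):
            out.add_node(tgt, gb.label_of(tgt))
    node_map = {src: tgt for op, src, tgt in path.node_ops if op == "sub"}
    # surviving ga edges, renamed through the mapping
    kept: dict[tuple[str, str], object] = {}
    for (u1, u2), la in ga.edge_labels.items():
        if u1 in node_map and u2 in node_map:
            kept[tuple(sorted((node_map[u1], node_map[u2])))] = la
    for op, src, tgt in path.edge_ops:
        if op == "del":
            u1, u2 = src
            kept.pop(tuple(sorted((node_map[u1], node_map[u2]))) if u1 in node_map and u2 in node_map else None, None)
        elif op == "sub":
            v1, v2 = tgt
            kept[tuple(sorted((v1, v2)))] = gb.edge_label(v1, v2)
        elif op == "ins":
            v1, v2 = tgt
            kept[tuple(sorted((v1, v2)))] = gb.edge_label(v1, v2)
    for (v1, v2), lab in kept.items():
        out.add_edge(v1, v2, lab)
    return out


def path_is_valid(ga: ErgGraph, gb: ErgGraph, path: EditPath) -> bool:
    """True iff applying ``path`` to ``ga`` yields a labeled-isomorphic
    copy of ``gb`` and the normalizer is |V_a|+|V_b|."""
    import networkx as nx
    from networkx.algorithms.isomorphism import categorical_edge_match, categorical_node_match

    if path.L != ga.order + gb.order:
        return False
    try:
        result = apply_edit_path(ga, gb, path)
    except Exception:
        return False
    return nx.is_isomorphic(
        result.to_networkx(),
        gb.to_networkx(),
        node_match=categorical_node_match("label", None),
        edge_match=categorical_edge_match("label", None),
    )


# ---------------------------------------------------------------------------
# Pairwise distance export
# ---------------------------------------------------------------------------

def pairwise_distances(
    graphs_a: Sequence[ErgGraph],
    graphs_b: Sequence[ErgGraph],
    costs: CostTable,
    method: str = "bipartite",
):
    """Full-precision pairwise distance matrix as a pandas DataFrame."""
    import pandas as pd

    values = np.zeros((len(graphs_a), len(graphs_b)))
    for i, ga in enumerate(graphs_a):
        for j, gb in enumerate(graphs_b):
            values[i, j] = compute_ged(ga, gb, costs, method=method).distance
    return pd.DataFrame(
        values, index=[g.id for g in graphs_a], columns=[g.id for g in graphs_b]
    )
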