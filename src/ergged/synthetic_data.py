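"""Seeded synthetic ErG populations with controlled class structure.

Real LBVS benchmarks give each target a set of active and inactive
molecules whose actives share pharmacophoric composition.  The generator
emulates that premise without chemistry: each class has a prototype graph
with a class-specific pharmacophore-label profile (one class rich in
aromatic/hydrophobic features, the other in donor/acceptor features), and
class members are sampled by applying a few random edit operations to the
prototype.  Within-class distances therefore concentrate below
between-class distances under any cost table that separates the two label
profiles, and each perturbation returns its generating edit path, which by
construction upper-bounds the exact edit distance — the oracle used by the
engine tests.

Everything here is a pure function of its seed/spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ged_engine import EditPath
from .graph_model import (
    ACTIVE,
    EDGE_LABELS,
    INACTIVE,
    NODE_LABELS,
    EdgeLabel,
    ErgGraph,
    LabeledDataset,
    NodeLabel,
    write_graphs,
)

__all__ = [
    "GeneratorSpec",
    "random_erg",
    "perturb_graph",
    "make_two_class_dataset",
    "write_dataset",
    "worked_example_graphs",
    "worked_example_path",
]

#: Default bond-order sampling weights: mostly single bonds, as in reduced
#: molecular graphs.
DEFAULT_EDGE_WEIGHTS = (0.7, 0.2, 0.1)

#: Class label profiles: actives lean aromatic/hydrophobic, inactives lean
#: donor/acceptor; both share the carbon-link backbone label.
_ACTIVE_PROFILE = {
    NodeLabel.AROMATIC: 4.0,
    NodeLabel.HYDROPHOBIC: 3.0,
    NodeLabel.CARBON_LINK: 2.0,
}
_INACTIVE_PROFILE = {
    NodeLabel.DONOR: 4.0,
    NodeLabel.ACCEPTOR: 3.0,
    NodeLabel.CARBON_LINK: 2.0,
}
_BASE_WEIGHT = 0.1


def _profile_weights(profile: dict[NodeLabel, float]) -> np.ndarray:
    w = np.array([profile.get(lab, _BASE_WEIGHT) for lab in NODE_LABELS])
    return w / w.sum()


@dataclass
class GeneratorSpec:
    """Specification of a two-class synthetic dataset.

    ``perturb_ops`` well below ``prototype_order`` keeps the classes
    separable with high probability (guidance, not enforced).
    """

    seed: int
    n_per_class: int = 20
    prototype_order: int = 8
    perturb_ops: int = 2
    edge_density: float = 0.3
    label_weights: tuple[dict[NodeLabel, float], dict[NodeLabel, float]] = field(
        default_factory=lambda: (_ACTIVE_PROFILE, _INACTIVE_PROFILE)
    )
    #: Fraction of each class planted as boundary molecules: before the
    #: usual perturbation, these have ``crossover_ops`` node labels switched
    #: to the opposite prototype's label at the same position, placing them
    #: roughly equidistant between the classes.  Cost tables that do not
    #: weight the class-distinguishing substitutions misclassify them — the
    #: regime cost learning is meant to repair.
    crossover_fraction: float = 0.0
    crossover_ops: int = 4

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.prototype_order < 1 or self.perturb_ops < 0:
            raise ValueError("invalid generator spec")
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must lie in [0, 1]")


def _sample_node_label(rng: np.random.Generator, weights: np.ndarray | None) -> NodeLabel:
    if weights is None:
        return NODE_LABELS[rng.integers(len(NODE_LABELS))]
    return NODE_LABELS[rng.choice(len(NODE_LABELS), p=weights)]


def _sample_edge_label(rng: np.random.Generator) -> EdgeLabel:
    return EDGE_LABELS[rng.choice(len(EDGE_LABELS), p=np.array(DEFAULT_EDGE_WEIGHTS))]


def random_erg(
    seed: int | np.random.Generator,
    order: int,
    edge_density: float = 0.3,
    label_weights: dict[NodeLabel, float] | None = None,
    graph_id: str = "g",
) -> ErgGraph:
    """Connected simple ErG with sampled labels, deterministic per seed.

    A random spanning tree guarantees connectivity; remaining node pairs
    receive an edge with probability ``edge_density``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = _profile_weights(label_weights) if label_weights else None
    g = ErgGraph(id=graph_id)
    ids = [f"v{i}" for i in range(order)]
    for nid in ids:
        g.add_node(nid, _sample_node_label(rng, weights))
    for i in range(1, order):
        j = int(rng.integers(i))  # attach to a random earlier node
        g.add_edge(ids[j], ids[i], _sample_edge_label(rng))
    for i in range(order):
        for j in range(i + 1, order):
            if not g.has_edge(ids[i], ids[j]) and rng.random() < edge_density:
                g.add_edge(ids[i], ids[j], _sample_edge_label(rng))
    return g


def perturb_graph(
    g: ErgGraph,
    n_ops: int,
    seed: int | np.random.Generator,
    label_weights: dict[NodeLabel, float] | None = None,
    new_id: str | None = None,
) -> tuple[ErgGraph, EditPath]:
    """Apply ``n_ops`` random valid edit operations; return the perturbed
    graph and the edit path linking the two.

    The path is induced from the tracked original→perturbed node mapping,
    so it is always a valid transformation and its cost upper-bounds the
    exact edit distance between the pair.  Infeasible sampled operations
    (e.g. deleting an edge of an edgeless graph) are resampled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = _profile_weights(label_weights) if label_weights else None
    h = g.copy(new_id=new_id if new_id is not None else f"{g.id}~")
    mapping: dict[str, str | None] = {u: u for u in g.nodes}
    fresh = 0

    ops = ("node_del", "node_ins", "node_sub", "edge_del", "edge_ins", "edge_sub")
    applied = 0
    attempts = 0
    while applied < n_ops and attempts < 50 * (n_ops + 1):
        attempts += 1
        op = ops[rng.integers(len(ops))]
        if op == "node_del":
            if h.order <= 1:
                continue
            victim = h.nodes[rng.integers(h.order)]
            for (u, v), _ in list(h.edge_labels.items()):
                if victim in (u, v):
                    del h.edge_labels[(u, v)]
            del h.node_labels[victim]
            h._node_order.remove(victim)
            for orig, cur in mapping.items():
                if cur == victim:
                    mapping[orig] = None
        elif op == "node_ins":
            nid = f"w{fresh}"
            fresh += 1
            h.add_node(nid, _sample_node_label(rng, weights))
            anchor = h.nodes[rng.integers(h.order - 1)]
            h.add_edge(anchor, nid, _sample_edge_label(rng))
        elif op == "node_sub":
            victim = h.nodes[rng.integers(h.order)]
            old = h.node_labels[victim]
            candidates = [lab for lab in NODE_LABELS if lab != old]
            h.node_labels[victim] = candidates[rng.integers(len(candidates))]
        elif op == "edge_del":
            if h.size == 0:
                continue
            keys = sorted(h.edge_labels)
            del h.edge_labels[keys[rng.integers(len(keys))]]
        elif op == "edge_ins":
            ids = h.nodes
            absent = [
                (ids[i], ids[j])
                for i in range(len(ids))
                for j in range(i + 1, len(ids))
                if not h.has_edge(ids[i], ids[j])
            ]
            if not absent:
                continue
            u, v = absent[rng.integers(len(absent))]
            h.add_edge(u, v, _sample_edge_label(rng))
        else:  # edge_sub
            if h.size == 0:
                continue
            keys = sorted(h.edge_labels)
            key = keys[rng.integers(len(keys))]
            old = h.edge_labels[key]
            candidates = [lab for lab in EDGE_LABELS if lab != old]
            h.edge_labels[key] = candidates[rng.integers(len(candidates))]
        applied += 1

    path = EditPath.from_node_mapping(g, h, mapping)
    return h, path


def make_two_class_dataset(spec: GeneratorSpec, name: str = "synthetic") -> LabeledDataset:
    """Two-class dataset sampled around two label-profile prototypes.

    Train/test halves are assigned by alternation within each class, so
    both classes appear in both halves for any ``n_per_class`` >= 2.
    """
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    # one shared backbone topology, two class-specific labelings: the class
    # signal is carried by pharmacophore label composition, as in real ErGs
    proto_active = random_erg(
        root, spec.prototype_order, spec.edge_density, spec.label_weights[0], "protoA"
    )
    proto_inactive = proto_active.copy(new_id="protoB")
    weights_b = _profile_weights(spec.label_weights[1])
    for nid in proto_inactive.nodes:
        proto_inactive.node_labels[nid] = _sample_node_label(root, weights_b)

    n_planted = round(spec.crossover_fraction * spec.n_per_class)
    train: list[tuple[ErgGraph, str]] = []
    test: list[tuple[ErgGraph, str]] = []
    for cls, proto, other_proto, prefix, profile in (
        (ACTIVE, proto_active, proto_inactive, "A", spec.label_weights[0]),
        (INACTIVE, proto_inactive, proto_active, "B", spec.label_weights[1]),
    ):
        for k in range(spec.n_per_class):
            base = proto
            if k < n_planted:
                base = proto.copy(new_id=f"{proto.id}x")
                differing = [
                    n for n in base.nodes
                    if base.node_labels[n] != other_proto.node_labels[n]
                ]
                n_cross = min(spec.crossover_ops, len(differing))
                picks = root.choice(len(differing), size=n_cross, replace=False)
                for idx in picks:
                    n = differing[idx]
                    base.node_labels[n] = other_proto.node_labels[n]
            mol, _ = perturb_graph(
                base, spec.perturb_ops, root, label_weights=profile,
                new_id=f"{name}-{prefix}{k:03d}",
            )
            (train if k % 2 == 0 else test).append((mol, cls))
    return LabeledDataset(name=name, train=train, test=test)


def write_dataset(ds: LabeledDataset, graphs_path: str | Path, split_path: str | Path) -> None:
    """Write a dataset as a native-format graphs file plus a split file."""
    graphs = [g for g, _ in ds.train] + [g for g, _ in ds.test]
    classes = [c for _, c in ds.train] + [c for _, c in ds.test]
    write_graphs(graphs, graphs_path, classes=classes)
    lines = [f"{g.id}\ttrain" for g, _ in ds.train] + [f"{g.id}\ttest" for g, _ in ds.test]
    Path(split_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Hand-transcribed worked-example fixtures
# ---------------------------------------------------------------------------

def worked_example_graphs() -> tuple[ErgGraph, ErgGraph]:
    """The transcribed worked-example pair (G1 and a reconstructed G2).

    G1 is a four-node chain [1]-[6]-[5]-[7]; G2 follows from the
    six-operation transformation described alongside the fixture file.
    """
    from importlib import resources

    from .graph_model import _iter_blocks, _parse_block

    text = resources.files("ergged.data").joinpath("worked_example.graphs").read_text("utf-8")
    graphs = [_parse_block(b, "worked_example.graphs")[0] for b in _iter_blocks(text)]
    return graphs[0], graphs[1]


def worked_example_path() -> EditPath:
    """The printed six-operation transformation of G1 into G2.

    Operations: delete node [1], delete a single edge, insert node [5],
    insert a single edge, substitute [7] by [2], substitute a single edge
    by a double edge.
    """
    g1, g2 = worked_example_graphs()
    mapping = {"n1": None, "n2": "a", "n3": "b", "n4": "c"}
    return EditPath.from_node_mapping(g1, g2, mapping)
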