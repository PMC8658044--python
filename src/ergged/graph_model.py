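"""Attributed-graph data model for extended reduced graphs (ErGs).

An ErG is a compact molecular graph: each node carries one of 15
pharmacophoric feature labels (H-bond donor/acceptor, charges, hydrophobic
groups, ring systems, link nodes, and their observed combinations) and each
edge carries one of 3 bond labels (single, double, triple).  Graphs are
simple and undirected — chemical bonds have no direction at this level of
abstraction, and all edit-cost tables used downstream are symmetric.

This module also defines the line-oriented native text format used to ship
datasets, and the two-column split files that assign graphs to train/test
halves.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NodeLabel",
    "EdgeLabel",
    "ErgGraph",
    "LabeledDataset",
    "GraphParseError",
    "load_graphs",
    "write_graphs",
    "load_split",
    "load_dataset",
    "validate_graph",
]


class NodeLabel(enum.Enum):
    """The 15-symbol pharmacophoric node alphabet.

    Composite labels such as DONOR_ACCEPTOR are atomic symbols: similarity
    between, say, ``[0]`` and ``[0,1]`` is expressed only through the edit
    cost table, never by set-overlap logic on the bracket contents.
    """

    DONOR = "[0]"
    ACCEPTOR = "[1]"
    POSITIVE = "[2]"
    NEGATIVE = "[3]"
    HYDROPHOBIC = "[4]"
    AROMATIC = "[5]"
    CARBON_LINK = "[6]"
    HETERO_LINK = "[7]"
    DONOR_ACCEPTOR = "[0,1]"
    DONOR_POSITIVE = "[0,2]"
    DONOR_NEGATIVE = "[0,3]"
    ACCEPTOR_POSITIVE = "[1,2]"
    ACCEPTOR_NEGATIVE = "[1,3]"
    POSITIVE_NEGATIVE = "[2,3]"
    DONOR_ACCEPTOR_POSITIVE = "[0,1,2]"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NodeLabel({self.value!r})"


class EdgeLabel(enum.Enum):
    """Bond-order edge alphabet: single, double, triple."""

    SINGLE = "-"
    DOUBLE = "="
    TRIPLE = "≡"  # "≡"; the ASCII alias "#T" is accepted on input

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EdgeLabel({self.value!r})"


#: Canonical ordering of the alphabets (used for canonical cost-table keys).
NODE_LABELS: tuple[NodeLabel, ...] = tuple(NodeLabel)
EDGE_LABELS: tuple[EdgeLabel, ...] = tuple(EdgeLabel)

_NODE_BY_SYMBOL = {m.value: m for m in NodeLabel}
_EDGE_BY_SYMBOL = {m.value: m for m in EdgeLabel}
_EDGE_BY_SYMBOL["#T"] = EdgeLabel.TRIPLE  # portability alias

#: Molecule activity classes used throughout screening.
ACTIVE = "active"
INACTIVE = "inactive"
CLASSES = (ACTIVE, INACTIVE)


class GraphParseError(ValueError):
    """Raised for malformed graph, split, or cost files (names line/symbol)."""


def parse_node_label(symbol: str) -> NodeLabel:
    try:
        return _NODE_BY_SYMBOL[symbol]
    except KeyError:
        raise GraphParseError(f"unknown node label symbol: {symbol!r}") from None


def parse_edge_label(symbol: str) -> EdgeLabel:
    try:
        return _EDGE_BY_SYMBOL[symbol]
    except KeyError:
        raise GraphParseError(f"unknown edge label symbol: {symbol!r}") from None


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class ErgGraph:
    """A simple undirected attributed graph over the ErG alphabets.

    Node ids are opaque strings local to the graph; cross-graph identity is
    never assumed (edit distance works on labels and topology only).
    """

    id: str
    node_labels: dict[str, NodeLabel] = field(default_factory=dict)
    edge_labels: dict[tuple[str, str], EdgeLabel] = field(default_factory=dict)
    _node_order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._node_order:
            self._node_order = list(self.node_labels)
        canonical = {}
        for (u, v), lab in self.edge_labels.items():
            canonical[_edge_key(u, v)] = lab
        self.edge_labels = canonical

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, label: NodeLabel) -> None:
        if node_id in self.node_labels:
            raise GraphParseError(f"duplicate node id {node_id!r} in graph {self.id!r}")
        self.node_labels[node_id] = label
        self._node_order.append(node_id)

    def add_edge(self, u: str, v: str, label: EdgeLabel) -> None:
        key = _edge_key(u, v)
        if key in self.edge_labels:
            raise GraphParseError(f"duplicate edge {u!r}-{v!r} in graph {self.id!r}")
        self.edge_labels[key] = label

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        """Node ids in declaration order."""
        return list(self._node_order)

    @property
    def order(self) -> int:
        return len(self.node_labels)

    @property
    def size(self) -> int:
        return len(self.edge_labels)

    def label_of(self, node_id: str) -> NodeLabel:
        return self.node_labels[node_id]

    def has_edge(self, u: str, v: str) -> bool:
        return _edge_key(u, v) in self.edge_labels

    def edge_label(self, u: str, v: str) -> EdgeLabel | None:
        return self.edge_labels.get(_edge_key(u, v))

    def edges_of(self, node_id: str) -> list[tuple[str, str, EdgeLabel]]:
        out = []
        for (u, v), lab in self.edge_labels.items():
            if node_id in (u, v):
                out.append((u, v, lab))
        return out

    def incident_edge_labels(self, node_id: str) -> list[EdgeLabel]:
        return [lab for _, _, lab in self.edges_of(node_id)]

    def degree(self, node_id: str) -> int:
        return len(self.edges_of(node_id))

    def copy(self, new_id: str | None = None) -> "ErgGraph":
        return ErgGraph(
            id=new_id if new_id is not None else self.id,
            node_labels=dict(self.node_labels),
            edge_labels=dict(self.edge_labels),
            _node_order=list(self._node_order),
        )

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` with ``label`` attributes."""
        import networkx as nx

        g = nx.Graph()
        for n in self._node_order:
            g.add_node(n, label=self.node_labels[n])
        for (u, v), lab in self.edge_labels.items():
            g.add_edge(u, v, label=lab)
        return g


def validate_graph(g: ErgGraph) -> list[str]:
    """Check the ErgGraph invariants; return human-readable violations.

    An empty list means the graph is valid.  Violations name the offending
    element so a caller can report them against the source file.
    """
    violations: list[str] = []
    if set(g._node_order) != set(g.node_labels):
        violations.append(f"graph {g.id!r}: node order list disagrees with node set")
    for n, lab in g.node_labels.items():
        if not isinstance(lab, NodeLabel):
            violations.append(f"graph {g.id!r}: node {n!r} has non-alphabet label {lab!r}")
    for (u, v), lab in g.edge_labels.items():
        if u == v:
            violations.append(f"graph {g.id!r}: self-loop on node {u!r}")
        if not isinstance(lab, EdgeLabel):
            violations.append(f"graph {g.id!r}: edge {u!r}-{v!r} has non-alphabet label {lab!r}")
        for endpoint in (u, v):
            if endpoint not in g.node_labels:
                violations.append(
                    f"graph {g.id!r}: edge {u!r}-{v!r} references undeclared node {endpoint!r}"
                )
    return violations


@dataclass
class LabeledDataset:
    """One classification task: train/test halves of (graph, class) pairs."""

    name: str
    train: list[tuple[ErgGraph, str]]
    test: list[tuple[ErgGraph, str]]

    def validate(self) -> list[str]:
        violations = []
        train_ids = {g.id for g, _ in self.train}
        test_ids = {g.id for g, _ in self.test}
        overlap = train_ids & test_ids
        if overlap:
            violations.append(f"dataset {self.name!r}: train/test share ids {sorted(overlap)}")
        train_classes = {c for _, c in self.train}
        if not {ACTIVE, INACTIVE} <= train_classes:
            violations.append(f"dataset {self.name!r}: train half lacks one of the two classes")
        for g, c in self.train + self.test:
            if c not in CLASSES:
                violations.append(f"dataset {self.name!r}: graph {g.id!r} has unknown class {c!r}")
            violations.extend(validate_graph(g))
        return violations


# ---------------------------------------------------------------------------
# Native file format
#
#   graph <id> [<class>]
#   n <node-id> <label>
#   e <id1> <id2> <label>
#
# Records are blank-line separated; UTF-8; "#T" is accepted for "≡".
# ---------------------------------------------------------------------------

def _parse_block(lines: list[tuple[int, str]], path: str) -> tuple[ErgGraph, str | None]:
    lineno, header = lines[0]
    parts = header.split()
    if parts[0] != "graph" or len(parts) not in (2, 3):
        raise GraphParseError(f"{path}:{lineno}: expected 'graph <id> [<class>]', got {header!r}")
    cls = parts[2] if len(parts) == 3 else None
    if cls is not None and cls not in CLASSES:
        raise GraphParseError(f"{path}:{lineno}: unknown class {cls!r}")
    g = ErgGraph(id=parts[1])
    for lineno, line in lines[1:]:
        parts = line.split()
        try:
            if parts[0] == "n" and len(parts) == 3:
                g.add_node(parts[1], parse_node_label(parts[2]))
            elif parts[0] == "e" and len(parts) == 4:
                u, v = parts[1], parts[2]
                if u == v:
                    raise GraphParseError(f"self-loop on {u!r}")
                for endpoint in (u, v):
                    if endpoint not in g.node_labels:
                        raise GraphParseError(f"edge references undeclared node {endpoint!r}")
                g.add_edge(u, v, parse_edge_label(parts[3]))
            else:
                raise GraphParseError(f"unrecognised record {line!r}")
        except GraphParseError as exc:
            raise GraphParseError(f"{path}:{lineno}: {exc}") from None
    if g.order < 1:
        raise GraphParseError(f"{path}: graph {g.id!r} declares no nodes")
    return g, cls


def _iter_blocks(text: str) -> Iterable[list[tuple[int, str]]]:
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#") and not line.startswith("#T"):
            continue  # comment line
        if not line:
            if block:
                yield block
                block = []
            continue
        block.append((lineno, line))
    if block:
        yield block


def load_labeled_graphs(path: str | Path) -> list[tuple[ErgGraph, str | None]]:
    """Parse a native-format file, keeping any per-graph class annotations."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    out = []
    seen_ids: set[str] = set()
    for block in _iter_blocks(text):
        g, cls = _parse_block(block, str(path))
        if g.id in seen_ids:
            raise GraphParseError(f"{path}: duplicate graph id {g.id!r}")
        seen_ids.add(g.id)
        out.append((g, cls))
    return out


def load_graphs(path: str | Path) -> list[ErgGraph]:
    """Parse a native-format file into validated graphs (classes dropped)."""
    return [g for g, _ in load_labeled_graphs(path)]


def write_graphs(
    graphs: Sequence[ErgGraph],
    path: str | Path,
    classes: Sequence[str] | None = None,
) -> None:
    """Write graphs in canonical native format (round-trips byte-exactly)."""
    if classes is not None and len(classes) != len(graphs):
        raise ValueError("classes must align with graphs")
    blocks = []
    for i, g in enumerate(graphs):
        header = f"graph {g.id}" if classes is None else f"graph {g.id} {classes[i]}"
        lines = [header]
        lines += [f"n {n} {g.node_labels[n].value}" for n in g.nodes]
        for (u, v) in sorted(g.edge_labels):
            lines.append(f"e {u} {v} {g.edge_labels[(u, v)].value}")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


def load_split(path: str | Path) -> dict[str, str]:
    """Parse a two-column ``graph-id<TAB>{train|test}`` split file."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2 or parts[1] not in ("train", "test"):
            raise GraphParseError(f"{path}:{lineno}: expected '<id>\\t{{train|test}}', got {raw!r}")
        if parts[0] in out:
            raise GraphParseError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def load_dataset(graphs_path: str | Path, split_path: str | Path, name: str) -> LabeledDataset:
    """Assemble a LabeledDataset from a graphs file and a split file."""
    pairs = load_labeled_graphs(graphs_path)
    split = load_split(split_path)
    train, test = [], []
    for g, cls in pairs:
        if cls is None:
            raise GraphParseError(f"graph {g.id!r} in {graphs_path} has no class annotation")
        half = split.get(g.id)
        if half is None:
            raise GraphParseError(f"graph {g.id!r} missing from split file {split_path}")
        (train if half == "train" else test).append((g, cls))
    ds = LabeledDataset(name=name, train=train, test=test)
    violations = ds.validate()
    if violations:
        raise GraphParseError("; ".join(violations))
    return ds
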