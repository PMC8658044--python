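"""The 126-parameter edit-cost model for ErG comparison.

The edit operations on attributed graphs are substitution, insertion and
deletion of nodes and of edges.  With the 15-symbol node alphabet and the
3-symbol edge alphabet, and with substitution costs symmetric, insertion
tied to deletion, and identity substitutions fixed at 0, the learnable
parameter set has exactly

    C(15,2) + 15 + C(3,2) + 3  =  105 + 15 + 3 + 3  =  126

members.  This module defines the canonical parameterization, the expert
default values of Harper et al., uniform tables, table arithmetic, and a
lossless CSV serialization.  It also ships two reference tables obtained on
the six public LBVS benchmark datasets (learned full table, and single-cost
presets from an earlier one-parameter-at-a-time optimisation); those are
provided for convenience and are not reproduced by this package's tests,
which would require the external benchmark data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .graph_model import (
    EDGE_LABELS,
    NODE_LABELS,
    EdgeLabel,
    NodeLabel,
    parse_edge_label,
    parse_node_label,
)

__all__ = [
    "EditOpKind",
    "CostTable",
    "node_sub",
    "node_indel",
    "edge_sub",
    "edge_indel",
    "all_kinds",
    "N_PARAMETERS",
    "harper_defaults",
    "uniform_costs",
    "mean_costs",
    "learned_reference",
    "single_cost_preset",
    "read_cost_table",
    "write_cost_table",
    "CostTableError",
]

# An edit-operation kind is a canonical hashable key:
#   ("node_sub", NodeLabel, NodeLabel)   unordered pair, stored in alphabet order
#   ("node_indel", NodeLabel)            insertion and deletion share the kind
#   ("edge_sub", EdgeLabel, EdgeLabel)
#   ("edge_indel", EdgeLabel)
EditOpKind = tuple

_NODE_INDEX = {lab: i for i, lab in enumerate(NODE_LABELS)}
_EDGE_INDEX = {lab: i for i, lab in enumerate(EDGE_LABELS)}


class CostTableError(ValueError):
    """Raised for incomplete, negative, or malformed cost tables."""


def node_sub(a: NodeLabel, b: NodeLabel) -> EditOpKind:
    """Canonical key for substituting node label ``a`` with ``b`` (a ≠ b)."""
    if a == b:
        raise ValueError("identity substitution is not an edit-operation kind")
    if _NODE_INDEX[a] > _NODE_INDEX[b]:
        a, b = b, a
    return ("node_sub", a, b)


def node_indel(a: NodeLabel) -> EditOpKind:
    return ("node_indel", a)


def edge_sub(x: EdgeLabel, y: EdgeLabel) -> EditOpKind:
    if x == y:
        raise ValueError("identity substitution is not an edit-operation kind")
    if _EDGE_INDEX[x] > _EDGE_INDEX[y]:
        x, y = y, x
    return ("edge_sub", x, y)


def edge_indel(x: EdgeLabel) -> EditOpKind:
    return ("edge_indel", x)


def all_kinds() -> list[EditOpKind]:
    """The 126 learnable kinds, in canonical deterministic order."""
    kinds: list[EditOpKind] = []
    n = len(NODE_LABELS)
    for i in range(n):
        for j in range(i + 1, n):
            kinds.append(("node_sub", NODE_LABELS[i], NODE_LABELS[j]))
    kinds += [("node_indel", lab) for lab in NODE_LABELS]
    m = len(EDGE_LABELS)
    for i in range(m):
        for j in range(i + 1, m):
            kinds.append(("edge_sub", EDGE_LABELS[i], EDGE_LABELS[j]))
    kinds += [("edge_indel", lab) for lab in EDGE_LABELS]
    return kinds


N_PARAMETERS = len(all_kinds())  # 126 for the standard alphabets


@dataclass
class CostTable:
    """A complete assignment of non-negative costs to the 126 kinds.

    Symmetry of substitution and the insert=delete tie hold by construction:
    both directions of a substitution, and both insertion and deletion of a
    label, read the same stored parameter.  Identity substitutions cost 0
    and are not stored (they are not edit operations).
    """

    costs: dict[EditOpKind, float]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        expected = set(all_kinds())
        missing = expected - set(self.costs)
        if missing:
            raise CostTableError(f"cost table missing {len(missing)} kinds, e.g. {sorted_kind_str(next(iter(missing)))}")
        extra = set(self.costs) - expected
        if extra:
            raise CostTableError(f"cost table has unknown kinds, e.g. {next(iter(extra))!r}")
        for k, v in self.costs.items():
            if not (v >= 0) or math.isnan(v):
                raise CostTableError(f"negative or invalid cost {v!r} for {sorted_kind_str(k)}")

    # -- lookups -------------------------------------------------------
    def cost(self, kind: EditOpKind) -> float:
        return self.costs[kind]

    def node_sub_cost(self, a: NodeLabel, b: NodeLabel) -> float:
        return 0.0 if a == b else self.costs[node_sub(a, b)]

    def node_indel_cost(self, a: NodeLabel) -> float:
        return self.costs[node_indel(a)]

    def edge_sub_cost(self, x: EdgeLabel, y: EdgeLabel) -> float:
        return 0.0 if x == y else self.costs[edge_sub(x, y)]

    def edge_indel_cost(self, x: EdgeLabel) -> float:
        return self.costs[edge_indel(x)]

    def replace(self, updates: Mapping[EditOpKind, float], provenance: str) -> "CostTable":
        new = dict(self.costs)
        new.update(updates)
        return CostTable(new, provenance=provenance)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CostTable) and self.costs == other.costs


def sorted_kind_str(kind: EditOpKind) -> str:
    tag = kind[0]
    labels = ",".join(lab.value for lab in kind[1:])
    return f"{tag}({labels})"


# ---------------------------------------------------------------------------
# Harper et al. expert defaults
# ---------------------------------------------------------------------------

# Node substitution matrix in the canonical label order [0] ... [0,1,2].
_HARPER_NODE_SUB = [
    # [0] [1] [2] [3] [4] [5] [6] [7] [01][02][03][12][13][23][012]
    [0, 2, 2, 2, 2, 2, 2, 3, 1, 1, 1, 2, 2, 2, 1],  # [0]
    [2, 0, 2, 2, 2, 2, 2, 3, 1, 2, 2, 1, 1, 2, 1],  # [1]
    [2, 2, 0, 2, 2, 2, 2, 3, 2, 1, 2, 1, 2, 1, 1],  # [2]
    [2, 2, 2, 0, 2, 2, 2, 3, 2, 2, 1, 2, 1, 1, 2],  # [3]
    [2, 2, 2, 2, 0, 2, 2, 3, 2, 2, 2, 2, 2, 2, 2],  # [4]
    [2, 2, 2, 2, 2, 0, 2, 3, 2, 2, 2, 2, 2, 2, 2],  # [5]
    [2, 2, 2, 2, 2, 2, 0, 3, 2, 2, 2, 2, 2, 2, 2],  # [6]
    [3, 3, 3, 3, 3, 3, 3, 0, 3, 3, 3, 3, 3, 3, 3],  # [7]
    [1, 1, 2, 2, 2, 2, 2, 3, 0, 2, 2, 2, 2, 2, 2],  # [0,1]
    [1, 2, 1, 2, 2, 2, 2, 3, 2, 0, 2, 2, 2, 2, 2],  # [0,2]
    [1, 2, 2, 1, 2, 2, 2, 3, 2, 2, 0, 2, 2, 2, 2],  # [0,3]
    [2, 1, 1, 2, 2, 2, 2, 3, 2, 2, 2, 0, 2, 2, 2],  # [1,2]
    [2, 1, 2, 1, 2, 2, 2, 3, 2, 2, 2, 2, 0, 2, 2],  # [1,3]
    [2, 2, 1, 1, 2, 2, 2, 3, 2, 2, 2, 2, 2, 0, 2],  # [2,3]
    [1, 1, 1, 2, 2, 2, 2, 3, 2, 2, 2, 2, 2, 2, 0],  # [0,1,2]
]
_HARPER_NODE_INDEL = [2, 2, 2, 2, 2, 2, 1, 1, 2, 2, 2, 2, 2, 2, 2]
_HARPER_EDGE_SUB = [[0, 3, 3], [3, 0, 3], [3, 3, 0]]
_HARPER_EDGE_INDEL = [0, 1, 1]


def _table_from_matrices(node_sub_m, node_indel_v, edge_sub_m, edge_indel_v, provenance):
    costs: dict[EditOpKind, float] = {}
    n = len(NODE_LABELS)
    for i in range(n):
        for j in range(i + 1, n):
            if node_sub_m[i][j] != node_sub_m[j][i]:
                raise CostTableError("node substitution matrix is not symmetric")
            costs[("node_sub", NODE_LABELS[i], NODE_LABELS[j])] = float(node_sub_m[i][j])
    for i in range(n):
        costs[("node_indel", NODE_LABELS[i])] = float(node_indel_v[i])
    m = len(EDGE_LABELS)
    for i in range(m):
        for j in range(i + 1, m):
            if edge_sub_m[i][j] != edge_sub_m[j][i]:
                raise CostTableError("edge substitution matrix is not symmetric")
            costs[("edge_sub", EDGE_LABELS[i], EDGE_LABELS[j])] = float(edge_sub_m[i][j])
    for i in range(m):
        costs[("edge_indel", EDGE_LABELS[i])] = float(edge_indel_v[i])
    return CostTable(costs, provenance=provenance)


def harper_defaults() -> CostTable:
    """The expert default edit costs of Harper et al. for ErG comparison."""
    return _table_from_matrices(
        _HARPER_NODE_SUB, _HARPER_NODE_INDEL, _HARPER_EDGE_SUB, _HARPER_EDGE_INDEL, "harper"
    )


def uniform_costs(value: float = 1.0) -> CostTable:
    """All 126 parameters set to ``value`` (the 'all-ones' baseline at 1)."""
    if value < 0:
        raise CostTableError(f"uniform cost must be non-negative, got {value}")
    provenance = "ones" if value == 1 else f"uniform({value})"
    return CostTable({k: float(value) for k in all_kinds()}, provenance=provenance)


def mean_costs(tables: Iterable[CostTable]) -> CostTable:
    """Parameter-wise arithmetic mean of complete cost tables."""
    tables = list(tables)
    if not tables:
        raise ValueError("mean_costs requires at least one table")
    kinds = all_kinds()
    costs = {k: sum(t.costs[k] for t in tables) / len(tables) for k in kinds}
    return CostTable(costs, provenance="mean")


# ---------------------------------------------------------------------------
# Serialization: flat CSV `kind,label1,label2,value` (label2 empty for indels)
# ---------------------------------------------------------------------------

def write_cost_table(table: CostTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "label1", "label2", "value"])
        for kind in all_kinds():  # deterministic key order
            tag = kind[0]
            lab1 = kind[1].value
            lab2 = kind[2].value if len(kind) == 3 else ""
            writer.writerow([tag, lab1, lab2, repr(table.costs[kind])])


def _parse_kind(tag: str, lab1: str, lab2: str) -> EditOpKind:
    if tag == "node_sub":
        return node_sub(parse_node_label(lab1), parse_node_label(lab2))
    if tag == "node_indel":
        return node_indel(parse_node_label(lab1))
    if tag == "edge_sub":
        return edge_sub(parse_edge_label(lab1), parse_edge_label(lab2))
    if tag == "edge_indel":
        return edge_indel(parse_edge_label(lab1))
    raise CostTableError(f"unknown edit-operation kind tag {tag!r}")


def _read_cost_rows(rows: Iterable[list[str]], origin: str, provenance: str) -> CostTable:
    costs: dict[EditOpKind, float] = {}
    for row in rows:
        if not row or row[0] == "kind":
            continue
        if len(row) != 4:
            raise CostTableError(f"{origin}: malformed row {row!r}")
        tag, lab1, lab2, value = row
        kind = _parse_kind(tag.strip(), lab1.strip(), lab2.strip())
        v = float(value)
        if v < 0:
            raise CostTableError(f"{origin}: negative cost {v} for {sorted_kind_str(kind)}")
        if kind in costs:
            raise CostTableError(f"{origin}: duplicate entry for {sorted_kind_str(kind)}")
        costs[kind] = v
    missing = set(all_kinds()) - set(costs)
    if missing:
        names = ", ".join(sorted_kind_str(k) for k in list(missing)[:3])
        raise CostTableError(f"{origin}: missing {len(missing)} parameters, e.g. {names}")
    return CostTable(costs, provenance=provenance)


def read_cost_table(path: str | Path, provenance: str | None = None) -> CostTable:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    return _read_cost_rows(rows, str(path), provenance or path.stem)


def learned_reference() -> CostTable:
    """Reference learned cost table (full 126-parameter optimisation).

    Obtained with the iterative learning procedure, Harper initialisation,
    averaged over the six public LBVS benchmark datasets; shipped as data
    for convenience.  This package's tests exercise its structure only, not
    its numeric derivation (that requires the external benchmark data).
    """
    text = resources.files("ergged.data").joinpath("learned_costs_reference.csv").read_text("utf-8")
    rows = list(csv.reader(text.splitlines()))
    return _read_cost_rows(rows, "learned_costs_reference.csv", "learned")


def single_cost_preset(experiment: str, dataset: str) -> CostTable:
    """Harper defaults with one parameter replaced by an earlier published
    single-cost optimisation (experiments C1–C4, per benchmark dataset).

    Shipped as optional data; not exercised by the learning tests.
    """
    text = resources.files("ergged.data").joinpath("single_cost_presets.csv").read_text("utf-8")
    kind_by_exp = {
        "C1": node_indel(NodeLabel.CARBON_LINK),
        "C2": node_sub(NodeLabel.AROMATIC, NodeLabel.CARBON_LINK),
        "C3": edge_indel(EdgeLabel.SINGLE),
        "C4": edge_sub(EdgeLabel.SINGLE, EdgeLabel.DOUBLE),
    }
    if experiment not in kind_by_exp:
        raise ValueError(f"unknown experiment {experiment!r}; expected C1-C4")
    for row in csv.reader(text.splitlines()):
        if row and row[0] == experiment and row[1] == dataset:
            return harper_defaults().replace(
                {kind_by_exp[experiment]: float(row[2])},
                provenance=f"{experiment}:{dataset}",
            )
    raise ValueError(f"no preset for experiment {experiment!r}, dataset {dataset!r}")
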