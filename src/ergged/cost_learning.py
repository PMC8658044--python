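"""Iterative learning of the 126 edit costs from a labeled training set.

One iteration: classify every training molecule leave-one-out with the
current costs; among the misclassified ones (those whose nearest
same-class distance D′ strictly exceeds the nearest different-class
distance D), select the molecule with the smallest gap D′ − D; then nudge
the costs so that, with the operation counts of the two realizing edit
paths held fixed, the two distances swap.  Per-kind corrections are

    α_t  = (D′ − D) · L  / (m  · N_t ),   N_t  > 0   (raises D toward D′)
    α_t′ = (D − D′) · L′ / (m′ · N_t′),   N_t′ > 0   (lowers D′ toward D)

where m and m′ count the operation kinds actually used on each path, and
the update averages the two corrections for kinds on both paths:

    C̄_t = C_t + (α_t + α_t′)/2   if N_t > 0 and N_t′ > 0
          C_t + α_t               if only N_t > 0
          C_t + α_t′              if only N_t′ > 0
          C_t                     otherwise.

Costs are clamped at zero after the update (penalties cannot be negative);
identity substitutions are not learnable kinds and remain exactly 0.
Selecting the smallest-gap molecule keeps each modification minimal, but
convergence is not guaranteed — the trace records every iteration so
oscillation is visible rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .cost_model import CostTable, EditOpKind
from .ged_engine import DistanceResult, EditPath, compute_ged
from .graph_model import ErgGraph

__all__ = [
    "NeighborPair",
    "AlphaUpdate",
    "IterationRecord",
    "LearningTrace",
    "DegeneratePathError",
    "neighbor_distances",
    "select_molecule",
    "compute_alphas",
    "apply_update",
    "learn_costs",
]

logger = logging.getLogger(__name__)


class DegeneratePathError(ValueError):
    """A realizing path has no true edit operations (m = 0 or m′ = 0)."""


@dataclass
class NeighborPair:
    """Nearest different-class (D, via G_q) and same-class (D′, via G_p)
    distances for one training molecule, with the realizing paths."""

    molecule_id: str
    D: float
    D_prime: float
    q_id: str
    p_id: str
    path_q: EditPath
    path_p: EditPath

    @property
    def misclassified(self) -> bool:
        return self.D_prime > self.D

    @property
    def gap(self) -> float:
        return self.D_prime - self.D


@dataclass
class AlphaUpdate:
    """Per-kind corrections derived from one misclassified molecule."""

    alphas: dict[EditOpKind, float]
    alphas_prime: dict[EditOpKind, float]
    m: int
    m_prime: int


@dataclass
class IterationRecord:
    iteration: int
    selected_id: str | None
    D: float | None
    D_prime: float | None
    train_accuracy: float
    costs_after: CostTable


@dataclass
class LearningTrace:
    iterations: list[IterationRecord] = field(default_factory=list)
    final: CostTable | None = None
    converged_early: bool = False


def neighbor_distances(
    g: ErgGraph,
    g_class: str,
    train: Sequence[tuple[ErgGraph, str]],
    costs: CostTable,
    method: str = "bipartite",
) -> NeighborPair:
    """Compute D (Eq. over different-class refs) and D′ (same-class refs).

    Ties resolve to the lowest train index; the molecule itself (by id) is
    excluded from both minima.
    """
    results: list[tuple[int, str, DistanceResult]] = []
    for i, (ref, cls) in enumerate(train):
        if ref.id == g.id:
            continue
        results.append((i, cls, compute_ged(g, ref, costs, method=method)))
    best_q = best_p = None
    for i, cls, res in results:
        if cls != g_class:
            if best_q is None or res.distance < best_q[2].distance:
                best_q = (i, cls, res)
        else:
            if best_p is None or res.distance < best_p[2].distance:
                best_p = (i, cls, res)
    if best_q is None or best_p is None:
        raise ValueError(
            f"train set lacks a reference of each class for molecule {g.id!r}"
        )
    return NeighborPair(
        molecule_id=g.id,
        D=best_q[2].distance,
        D_prime=best_p[2].distance,
        q_id=train[best_q[0]][0].id,
        p_id=train[best_p[0]][0].id,
        path_q=best_q[2].path,
        path_p=best_p[2].path,
    )


def select_molecule(pairs: Sequence[NeighborPair]) -> NeighborPair | None:
    """The misclassified molecule with minimum gap D′ − D (lowest index on
    ties); ``None`` when nothing is misclassified."""
    best = None
    for pair in pairs:
        if not pair.misclassified:
            continue
        if best is None or pair.gap < best.gap:
            best = pair
    return best


def compute_alphas(pair: NeighborPair) -> AlphaUpdate:
    """Per-kind corrections that swap the two fixed-count path costs.

    Satisfies the reconstruction identities
    Σ α_t N_t / L = D′ − D and Σ α_t′ N_t′ / L′ = D − D′.
    """
    if not pair.misclassified:
        raise ValueError(
            f"molecule {pair.molecule_id!r} is not misclassified (D' <= D)"
        )
    counts_q = {k: n for k, n in pair.path_q.counts.items() if n > 0}
    counts_p = {k: n for k, n in pair.path_p.counts.items() if n > 0}
    m, m_prime = len(counts_q), len(counts_p)
    if m == 0 or m_prime == 0:
        raise DegeneratePathError(
            f"molecule {pair.molecule_id!r}: a realizing path has no edit operations"
        )
    gap = pair.D_prime - pair.D
    L, L_prime = pair.path_q.L, pair.path_p.L
    alphas = {k: gap * L / (m * n) for k, n in counts_q.items()}
    alphas_prime = {k: -gap * L_prime / (m_prime * n) for k, n in counts_p.items()}
    return AlphaUpdate(alphas=alphas, alphas_prime=alphas_prime, m=m, m_prime=m_prime)


def apply_update(
    costs: CostTable, upd: AlphaUpdate, clamp: bool = True
) -> CostTable:
    """Averaged cost update; result clamped at 0 when corrections overshoot."""
    updates: dict[EditOpKind, float] = {}
    for kind in set(upd.alphas) | set(upd.alphas_prime):
        if kind in upd.alphas and kind in upd.alphas_prime:
            delta = (upd.alphas[kind] + upd.alphas_prime[kind]) / 2.0
        elif kind in upd.alphas:
            delta = upd.alphas[kind]
        else:
            delta = upd.alphas_prime[kind]
        new = costs.costs[kind] + delta
        if new < 0:
            if clamp:
                logger.warning(
                    "clamping cost of %s at 0 (update would give %g)", kind, new
                )
                new = 0.0
            # without clamping, negative costs propagate for diagnosis
        updates[kind] = new
    return costs.replace(updates, provenance="learned")


def _loo_survey(
    train: Sequence[tuple[ErgGraph, str]], costs: CostTable, method: str
) -> tuple[float, list[NeighborPair]]:
    """Leave-one-out pass: train accuracy and a NeighborPair per molecule."""
    n = len(train)
    results: list[list[DistanceResult | None]] = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            res = compute_ged(train[i][0], train[j][0], costs, method=method)
            results[i][j] = results[j][i] = res  # symmetric costs => symmetric GED

    pairs: list[NeighborPair] = []
    correct = 0
    for j in range(n):
        g, cls = train[j]
        best_q = best_p = None
        for i in range(n):
            if i == j:
                continue
            d = results[j][i].distance
            if train[i][1] != cls:
                if best_q is None or d < results[j][best_q].distance:
                    best_q = i
            else:
                if best_p is None or d < results[j][best_p].distance:
                    best_p = i
        if best_q is None or best_p is None:
            raise ValueError("train set must contain both classes beyond each molecule")
        D = results[j][best_q].distance
        D_prime = results[j][best_p].distance
        if D_prime <= D:
            correct += 1  # nearest same-class at least ties; tie keeps lower index,
            # but a strict D' > D is the only certain misclassification
        pairs.append(
            NeighborPair(
                molecule_id=g.id,
                D=D,
                D_prime=D_prime,
                q_id=train[best_q][0].id,
                p_id=train[best_p][0].id,
                path_q=results[j][best_q].path,
                path_p=results[j][best_p].path,
            )
        )
    return 100.0 * correct / n, pairs


def learn_costs(
    train: Sequence[tuple[ErgGraph, str]],
    init: CostTable,
    max_iter: int = 50,
    method: str = "bipartite",
    clamp: bool = True,
) -> LearningTrace:
    """Run the iterative cost-learning loop on a training set.

    Each iteration classifies all training molecules leave-one-out, selects
    the misclassified molecule with the smallest D′ − D, and applies the
    averaged swap update.  Stops early when nothing is misclassified.
    Deterministic given inputs: every tie rule is fixed.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    classes = {c for _, c in train}
    if len(classes) < 2:
        raise ValueError("learning requires both classes in the train set")

    costs = init
    trace = LearningTrace()
    for it in range(1, max_iter + 1):
        accuracy, pairs = _loo_survey(train, costs, method)
        candidates = sorted(
            (p for p in pairs if p.misclassified), key=lambda p: p.gap
        )
        selected = None
        update = None
        for cand in candidates:
            try:
                update = compute_alphas(cand)
                selected = cand
                break
            except DegeneratePathError as exc:
                logger.warning("iteration %d: skipping %s", it, exc)
        if selected is None:
            trace.iterations.append(
                IterationRecord(it, None, None, None, accuracy, costs)
            )
            trace.converged_early = it < max_iter
            break
        costs = apply_update(costs, update, clamp=clamp)
        trace.iterations.append(
            IterationRecord(it, selected.molecule_id, selected.D, selected.D_prime, accuracy, costs)
        )
        logger.info(
            "iteration %d: selected %s (D=%.4f, D'=%.4f, train acc %.1f%%)",
            it, selected.molecule_id, selected.D, selected.D_prime, accuracy,
        )
    trace.final = costs
    return trace


def write_trace(trace: LearningTrace, path) -> None:
    """Per-iteration tabular log (costs snapshots are not included)."""
    from pathlib import Path

    lines = ["iteration\tselected_id\tD\tD_prime\ttrain_accuracy"]
    for rec in trace.iterations:
        lines.append(
            f"{rec.iteration}\t{rec.selected_id or '-'}\t"
            f"{'' if rec.D is None else repr(rec.D)}\t"
            f"{'' if rec.D_prime is None else repr(rec.D_prime)}\t{rec.train_accuracy!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
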