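"""Per-target screening protocol: subsetting, learning, evaluation.

The experiment protocol mirrors the benchmark layout: each dataset holds
several targets, each target a set of active and inactive molecules split
into train and test halves.  Per target, at most the first ``subset_cap``
actives are kept together with the same number of leading inactives.  Edit
costs are learned per target on the train half; a dataset's table is the
unweighted mean of its targets' tables, and the cross-dataset table is the
unweighted mean of the dataset tables.  Every target's test half is then
classified against its train half under that mean table (or under its own
learned table when ``per_target`` diagnosis is requested).  Accuracy
aggregation is unweighted at both levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cost_model import CostTable, harper_defaults, mean_costs, read_cost_table, uniform_costs
from .cost_learning import learn_costs
from .graph_model import (
    ACTIVE,
    INACTIVE,
    ErgGraph,
    LabeledDataset,
    load_labeled_graphs,
    load_split,
)
from .nn_classifier import evaluate_accuracy

__all__ = [
    "TargetSpec",
    "DatasetSpec",
    "ExperimentConfig",
    "TargetResult",
    "ExperimentReport",
    "DataError",
    "subset_target",
    "load_target",
    "run_experiment",
    "load_config",
]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """A target's data cannot satisfy the protocol (names the target)."""


@dataclass
class TargetSpec:
    name: str
    graphs: str
    split: str


@dataclass
class DatasetSpec:
    name: str
    targets: list[TargetSpec]


@dataclass
class ExperimentConfig:
    datasets: list[DatasetSpec]
    subset_cap: int = 100
    init: str = "harper"  # "harper" | "ones" | path to a cost CSV
    max_iter: int = 50
    method: str = "bipartite"
    per_target: bool = False
    seed: int = 0  # reserved for randomized fixtures; protocol is deterministic

    def __post_init__(self) -> None:
        if self.subset_cap < 1:
            raise ValueError("subset_cap must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def initial_costs(self) -> CostTable:
        if self.init == "harper":
            return harper_defaults()
        if self.init == "ones":
            return uniform_costs(1.0)
        return read_cost_table(self.init)


@dataclass
class TargetResult:
    dataset: str
    target: str
    n_active: int
    n_inactive: int
    accuracy: float | None
    error: str | None = None


@dataclass
class ExperimentReport:
    per_target: list[TargetResult]
    per_dataset_mean: list[tuple[str, float]]
    grand_mean: float
    costs_used: str

    def write_tsv(self, path: str | Path) -> None:
        lines = ["dataset\ttarget\tn_active\tn_inactive\taccuracy"]
        for r in self.per_target:
            acc = "" if r.accuracy is None else f"{r.accuracy:.2f}"
            err = f"\t# {r.error}" if r.error else ""
            lines.append(f"{r.dataset}\t{r.target}\t{r.n_active}\t{r.n_inactive}\t{acc}{err}")
        lines.append("")
        for name, acc in self.per_dataset_mean:
            lines.append(f"# mean {name}\t{acc:.2f}")
        lines.append(f"# grand mean\t{self.grand_mean:.2f}")
        lines.append(f"# costs\t{self.costs_used}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def subset_target(
    actives: list, inactives: list, cap: int = 100
) -> tuple[list, list]:
    """First-``cap`` subsetting: all (or first ``cap``) actives and the same
    number of leading inactives, order preserved."""
    if not actives:
        raise DataError("target has no active molecules")
    n = min(len(actives), cap)
    if len(inactives) < n:
        raise DataError(
            f"target has {len(inactives)} inactive molecules but {n} are required"
        )
    return actives[:n], inactives[:n]


def load_target(spec: TargetSpec, subset_cap: int = 100) -> LabeledDataset:
    """Load one target, apply subsetting in file order, then split."""
    pairs = load_labeled_graphs(spec.graphs)
    for g, cls in pairs:
        if cls is None:
            raise DataError(f"target {spec.name}: graph {g.id!r} has no class annotation")
    actives = [(g, c) for g, c in pairs if c == ACTIVE]
    inactives = [(g, c) for g, c in pairs if c == INACTIVE]
    try:
        actives, inactives = subset_target(actives, inactives, subset_cap)
    except DataError as exc:
        raise DataError(f"target {spec.name}: {exc}") from None
    keep = {g.id for g, _ in actives + inactives}
    split = load_split(spec.split)
    train, test = [], []
    for g, cls in pairs:
        if g.id not in keep:
            continue
        half = split.get(g.id)
        if half is None:
            raise DataError(f"target {spec.name}: graph {g.id!r} missing from split file")
        (train if half == "train" else test).append((g, cls))
    ds = LabeledDataset(name=spec.name, train=train, test=test)
    violations = ds.validate()
    if violations:
        raise DataError("; ".join(violations))
    return ds


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Learn per target, average within then across datasets, evaluate.

    A failing target is reported with its error rather than silently
    dropped; it contributes neither a learned table nor an accuracy.
    """
    init = cfg.initial_costs()

    loaded: list[tuple[str, list[tuple[TargetSpec, LabeledDataset | None, str | None]]]] = []
    dataset_tables: list[CostTable] = []
    learned_by_target: dict[tuple[str, str], CostTable] = {}
    for ds_spec in cfg.datasets:
        rows = []
        target_tables = []
        for t_spec in ds_spec.targets:
            try:
                ds = load_target(t_spec, cfg.subset_cap)
                trace = learn_costs(ds.train, init, max_iter=cfg.max_iter, method=cfg.method)
                target_tables.append(trace.final)
                learned_by_target[(ds_spec.name, t_spec.name)] = trace.final
                rows.append((t_spec, ds, None))
            except (DataError, ValueError, OSError) as exc:
                logger.error("target %s/%s failed: %s", ds_spec.name, t_spec.name, exc)
                rows.append((t_spec, None, str(exc)))
        if target_tables:
            dataset_tables.append(mean_costs(target_tables))
        loaded.append((ds_spec.name, rows))

    if not dataset_tables:
        raise DataError("no target could be learned; nothing to evaluate")
    mean_table = mean_costs(dataset_tables)

    per_target: list[TargetResult] = []
    per_dataset_mean: list[tuple[str, float]] = []
    for ds_name, rows in loaded:
        accs = []
        for t_spec, ds, error in rows:
            if ds is None:
                per_target.append(TargetResult(ds_name, t_spec.name, 0, 0, None, error))
                continue
            table = (
                learned_by_target[(ds_name, t_spec.name)] if cfg.per_target else mean_table
            )
            acc = evaluate_accuracy(ds.test, ds.train, table, method=cfg.method)
            n_act = sum(1 for _, c in ds.train + ds.test if c == ACTIVE)
            n_inact = sum(1 for _, c in ds.train + ds.test if c == INACTIVE)
            per_target.append(TargetResult(ds_name, t_spec.name, n_act, n_inact, acc))
            accs.append(acc)
        if accs:
            per_dataset_mean.append((ds_name, sum(accs) / len(accs)))
    grand_mean = sum(a for _, a in per_dataset_mean) / len(per_dataset_mean)
    return ExperimentReport(
        per_target=per_target,
        per_dataset_mean=per_dataset_mean,
        grand_mean=grand_mean,
        costs_used="per-target learned" if cfg.per_target else mean_table.provenance,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    base = Path(path).parent
    datasets = []
    for ds in raw["datasets"]:
        targets = [
            TargetSpec(
                name=t["name"],
                graphs=str(base / t["graphs"]),
                split=str(base / t["split"]),
            )
            for t in ds["targets"]
        ]
        datasets.append(DatasetSpec(name=ds["name"], targets=targets))
    return ExperimentConfig(
        datasets=datasets,
        subset_cap=int(raw.get("subset_cap", 100)),
        init=str(raw.get("init", "harper")),
        max_iter=int(raw.get("max_iter", 50)),
        method=str(raw.get("method", "bipartite")),
        per_target=bool(raw.get("per_target", False)),
        seed=int(raw.get("seed", 0)),
    )
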