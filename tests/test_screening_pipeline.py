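"""Subsetting protocol and the end-to-end experiment orchestration."""

import pytest

from ergged.cost_model import uniform_costs
from ergged.nn_classifier import evaluate_accuracy
from ergged.screening_pipeline import (
    DataError,
    DatasetSpec,
    ExperimentConfig,
    TargetSpec,
    load_config,
    load_target,
    run_experiment,
    subset_target,
)
from ergged.synthetic_data import GeneratorSpec, make_two_class_dataset, write_dataset


def test_subset_rule_caps_both_classes():
    actives, inactives = list(range(150)), list(range(300))
    a, i = subset_target(actives, inactives, cap=100)
    assert a == actives[:100] and i == inactives[:100]


def test_subset_rule_matches_small_active_sets():
    a, i = subset_target(list(range(40)), list(range(300)), cap=100)
    assert len(a) == len(i) == 40


def test_subset_rule_errors():
    with pytest.raises(DataError):
        subset_target([], list(range(10)), cap=100)
    with pytest.raises(DataError, match="inactive"):
        subset_target(list(range(40)), list(range(10)), cap=100)


def _write_targets(tmp_path, n_targets, n_per_class=12, crossover=0.25):
    targets = []
    for i in range(n_targets):
        spec = GeneratorSpec(
            seed=100 + i, n_per_class=n_per_class, prototype_order=8, perturb_ops=2,
            crossover_fraction=crossover, crossover_ops=4,
        )
        ds = make_two_class_dataset(spec, name=f"t{i}")
        write_dataset(ds, tmp_path / f"t{i}.graphs", tmp_path / f"t{i}.split")
        targets.append(
            TargetSpec(name=f"t{i}", graphs=str(tmp_path / f"t{i}.graphs"),
                       split=str(tmp_path / f"t{i}.split"))
        )
    return targets


def test_load_target_applies_subsetting(tmp_path):
    (target,) = _write_targets(tmp_path, 1, n_per_class=8, crossover=0.0)
    ds = load_target(target, subset_cap=3)
    n_active = sum(1 for _, c in ds.train + ds.test if c == "active")
    n_inactive = sum(1 for _, c in ds.train + ds.test if c == "inactive")
    assert n_active == n_inactive == 3


def test_run_experiment_report_is_internally_consistent(tmp_path):
    targets = _write_targets(tmp_path, 2, n_per_class=6, crossover=0.0)
    cfg = ExperimentConfig(
        datasets=[DatasetSpec(name="synthA", targets=targets)], init="harper", max_iter=3
    )
    report = run_experiment(cfg)
    assert len(report.per_target) == 2
    accs = [r.accuracy for r in report.per_target]
    assert all(a is not None for a in accs)
    (ds_name, ds_mean), = report.per_dataset_mean
    assert ds_name == "synthA"
    assert ds_mean == pytest.approx(sum(accs) / len(accs))
    assert report.grand_mean == pytest.approx(ds_mean)
    assert report.costs_used == "mean"

    out = tmp_path / "report.tsv"
    report.write_tsv(out)
    assert "grand mean" in out.read_text()


def test_identical_datasets_give_identical_dataset_means(tmp_path):
    targets = _write_targets(tmp_path, 1, n_per_class=6, crossover=0.0)
    cfg = ExperimentConfig(
        datasets=[
            DatasetSpec(name="d1", targets=targets),
            DatasetSpec(name="d2", targets=targets),
        ],
        max_iter=2,
    )
    report = run_experiment(cfg)
    means = dict(report.per_dataset_mean)
    assert means["d1"] == means["d2"]


def test_learned_mean_costs_do_not_degrade_grand_mean(tmp_path):
    """Three targets with planted boundary molecules: the learned-mean
    table's grand mean is at least the all-ones baseline's."""
    targets = _write_targets(tmp_path, 3)
    cfg = ExperimentConfig(
        datasets=[DatasetSpec(name="synthA", targets=targets)], init="ones", max_iter=30
    )
    report = run_experiment(cfg)
    ones = uniform_costs(1.0)
    baseline = [
        evaluate_accuracy(load_target(t).test, load_target(t).train, ones)
        for t in targets
    ]
    assert report.grand_mean >= sum(baseline) / len(baseline) - 1e-9


def test_failing_target_is_reported_not_dropped(tmp_path):
    targets = _write_targets(tmp_path, 1, n_per_class=6, crossover=0.0)
    targets.append(TargetSpec(name="ghost", graphs=str(tmp_path / "no.graphs"),
                              split=str(tmp_path / "no.split")))
    cfg = ExperimentConfig(datasets=[DatasetSpec(name="d", targets=targets)], max_iter=2)
    report = run_experiment(cfg)
    by_name = {r.target: r for r in report.per_target}
    assert by_name["ghost"].accuracy is None and by_name["ghost"].error
    assert by_name["t0"].accuracy is not None


def test_config_yaml_roundtrip(tmp_path):
    _write_targets(tmp_path, 1, n_per_class=6, crossover=0.0)
    cfg_file = tmp_path / "exp.yaml"
    cfg_file.write_text(
        "subset_cap: 50\ninit: ones\nmax_iter: 7\nmethod: bipartite\n"
        "datasets:\n  - name: d\n    targets:\n"
        "      - {name: t0, graphs: t0.graphs, split: t0.split}\n",
        encoding="utf-8",
    )
    cfg = load_config(cfg_file)
    assert cfg.subset_cap == 50 and cfg.init == "ones" and cfg.max_iter == 7
    assert cfg.datasets[0].targets[0].name == "t0"
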