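"""Neighbour distances, alpha corrections, averaged update, learning loop."""

from collections import Counter

import pytest

from ergged.cost_learning import (
    AlphaUpdate,
    DegeneratePathError,
    NeighborPair,
    apply_update,
    compute_alphas,
    learn_costs,
    neighbor_distances,
    select_molecule,
)
from ergged.cost_model import edge_indel, node_indel, node_sub, uniform_costs
from ergged.ged_engine import EditPath, edit_path_cost
from ergged.graph_model import EdgeLabel as E, NodeLabel as N
from ergged.synthetic_data import GeneratorSpec, make_two_class_dataset

from .conftest import make_graph


def _pair(mol_id, D, Dp, path_q=None, path_p=None):
    dummy = EditPath(counts=Counter({node_indel(N.DONOR): 1}), L=2)
    return NeighborPair(
        molecule_id=mol_id, D=D, D_prime=Dp, q_id="q", p_id="p",
        path_q=path_q or dummy, path_p=path_p or dummy,
    )


def test_neighbor_distances_single_op_fixture(harper):
    """Different-class neighbour one bond-order substitution away (3/4),
    same-class neighbour one free-edged node indel away (1/5)."""
    g = make_graph("g", {"a": "[6]", "b": "[6]"}, [("a", "b", "-")])
    diff = make_graph("q", {"a": "[6]", "b": "[6]"}, [("a", "b", "=")])
    same = make_graph("p", {"a": "[6]", "b": "[6]", "c": "[6]"},
                      [("a", "b", "-"), ("b", "c", "-")])
    pair = neighbor_distances(g, "active", [(diff, "inactive"), (same, "active")], harper)
    assert pair.D == pytest.approx(3 / 4)
    assert pair.D_prime == pytest.approx(1 / 5)
    assert pair.q_id == "q" and pair.p_id == "p"
    assert not pair.misclassified  # D' < D: correctly classified


def test_neighbor_distances_requires_both_classes(harper):
    g = make_graph("g", {"a": "[6]"})
    with pytest.raises(ValueError, match="class"):
        neighbor_distances(g, "active", [(make_graph("r", {"a": "[5]"}), "active")], harper)


def test_misclassification_is_strict_gap():
    assert _pair("m", 0.4, 0.6).misclassified
    assert not _pair("m", 0.5, 0.5).misclassified


def test_select_molecule_argmin_and_ties():
    assert select_molecule([]) is None
    assert select_molecule([_pair("a", 0.5, 0.4)]) is None  # none misclassified
    pairs = [_pair("a", 0.0, 0.5), _pair("b", 0.0, 0.1), _pair("c", 0.0, 0.3)]
    assert select_molecule(pairs).molecule_id == "b"
    tied = [_pair("first", 0.0, 0.25), _pair("second", 0.25, 0.5)]  # equal gaps
    assert select_molecule(tied).molecule_id == "first"


def test_alpha_direct_substitution_and_reconstruction():
    """Single-kind path with N=2, L=4 and gap 0.5 gives alpha = 1.0, and the
    weighted alpha sums reconstruct ±(D'−D)."""
    k, k2 = node_indel(N.DONOR), node_indel(N.ACCEPTOR)
    pair = _pair(
        "m", 0.2, 0.7,
        path_q=EditPath(counts=Counter({k: 2}), L=4),
        path_p=EditPath(counts=Counter({k2: 1}), L=2),
    )
    upd = compute_alphas(pair)
    assert upd.m == 1 and upd.m_prime == 1
    assert upd.alphas[k] == pytest.approx(1.0)
    recon_q = sum(a * pair.path_q.counts[t] for t, a in upd.alphas.items()) / pair.path_q.L
    recon_p = sum(a * pair.path_p.counts[t] for t, a in upd.alphas_prime.items()) / pair.path_p.L
    assert recon_q == pytest.approx(0.5, abs=1e-12)
    assert recon_p == pytest.approx(-0.5, abs=1e-12)
    assert recon_q + recon_p == pytest.approx(0.0, abs=1e-12)


def test_alpha_preconditions():
    with pytest.raises(ValueError, match="misclassified"):
        compute_alphas(_pair("m", 0.5, 0.5))
    degenerate = _pair("m", 0.0, 0.5, path_q=EditPath(counts=Counter(), L=2))
    with pytest.raises(DegeneratePathError):
        compute_alphas(degenerate)


def test_apply_update_cases(ones):
    k_q = node_sub(N.DONOR, N.ACCEPTOR)
    k_both = node_indel(N.AROMATIC)
    k_neg = edge_indel(E.DOUBLE)
    base = ones.replace({k_q: 2.0, k_both: 2.0}, "base")
    upd = AlphaUpdate(
        alphas={k_q: 1.0, k_both: 0.4},
        alphas_prime={k_both: -0.2, k_neg: -5.0},
        m=2, m_prime=2,
    )
    out = apply_update(base, upd)
    assert out.cost(k_q) == pytest.approx(3.0)  # only N_t > 0
    assert out.cost(k_both) == pytest.approx(2.1)  # averaged (0.4 - 0.2)/2
    assert out.cost(k_neg) == 0.0  # clamped from 1 - 5
    untouched = node_sub(N.POSITIVE, N.NEGATIVE)
    assert out.cost(untouched) == base.cost(untouched)


def test_disjoint_support_swap_identity(ones):
    """With disjoint operation supports, recomputing the two fixed paths
    under the updated costs exchanges D and D' exactly."""
    g = make_graph("g", {"x": "[0]"})
    q = make_graph("q", {"x": "[0,1]"})  # inactive, one node substitution away
    p = make_graph("p", {"x": "[0]", "y": "[6]"}, [("x", "y", "=")])  # active
    pair = neighbor_distances(g, "active", [(q, "inactive"), (p, "active")], ones)
    assert pair.misclassified
    assert set(pair.path_q.counts).isdisjoint(pair.path_p.counts)

    upd = compute_alphas(pair)
    new = apply_update(ones, upd)
    new_D = edit_path_cost(pair.path_q, new, normalize=True)
    new_Dp = edit_path_cost(pair.path_p, new, normalize=True)
    assert new_D == pytest.approx(pair.D_prime, abs=1e-12)
    assert new_Dp == pytest.approx(pair.D, abs=1e-12)


def test_learn_costs_fixed_point_on_separable_train(harper):
    train = [
        (make_graph("a1", {"x": "[5]"}), "active"),
        (make_graph("a2", {"x": "[5]"}), "active"),
        (make_graph("b1", {"x": "[0]"}), "inactive"),
        (make_graph("b2", {"x": "[0]"}), "inactive"),
    ]
    trace = learn_costs(train, harper, max_iter=10)
    assert len(trace.iterations) == 1
    assert trace.converged_early
    assert trace.final == harper
    assert trace.iterations[0].train_accuracy == 100.0


def test_learning_improves_boundary_dataset(ones):
    """On a seeded dataset with planted boundary molecules, the endpoint
    train accuracy does not fall below its starting value."""
    ds = make_two_class_dataset(
        GeneratorSpec(seed=5, n_per_class=16, prototype_order=8, perturb_ops=2,
                      crossover_fraction=0.25, crossover_ops=4)
    )
    trace = learn_costs(ds.train, ones, max_iter=20)
    first = trace.iterations[0].train_accuracy
    last = trace.iterations[-1].train_accuracy
    assert first < 100.0  # uniform costs do misclassify the plants
    assert last >= first
    # determinism of the whole loop
    trace2 = learn_costs(ds.train, ones, max_iter=20)
    assert [r.selected_id for r in trace2.iterations] == [
        r.selected_id for r in trace.iterations
    ]
    assert trace2.final == trace.final
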