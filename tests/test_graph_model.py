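"""Graph data model, native file format, and validation."""

import pytest
from hypothesis import given, settings, strategies as st

from ergged.graph_model import (
    EDGE_LABELS,
    NODE_LABELS,
    GraphParseError,
    NodeLabel,
    load_dataset,
    load_graphs,
    load_labeled_graphs,
    load_split,
    validate_graph,
    write_graphs,
)
from ergged.synthetic_data import worked_example_graphs

from .conftest import make_graph


def test_minimal_single_node_file(tmp_path):
    p = tmp_path / "one.graphs"
    p.write_text("graph g1\nn a [5]\n", encoding="utf-8")
    (g,) = load_graphs(p)
    assert g.order == 1 and g.size == 0
    assert g.label_of("a") is NodeLabel.AROMATIC


def test_worked_example_chain_transcription_roundtrip(tmp_path):
    """The transcribed 4-node chain reloads identically from the native format."""
    g1, _ = worked_example_graphs()
    assert g1.order == 4 and g1.size == 3
    assert [g1.label_of(n).value for n in g1.nodes] == ["[1]", "[6]", "[5]", "[7]"]
    assert all(lab.value == "-" for lab in g1.edge_labels.values())

    out = tmp_path / "copy.graphs"
    write_graphs([g1], out)
    (back,) = load_graphs(out)
    assert back.node_labels == g1.node_labels
    assert back.edge_labels == g1.edge_labels
    # canonical form is a fixed point of write∘load
    out2 = tmp_path / "copy2.graphs"
    write_graphs([back], out2)
    assert out.read_text() == out2.read_text()


@pytest.mark.parametrize(
    "body, fragment",
    [
        ("graph g\nn a [5]\nn b [6]\ne a b #\n", "#"),
        ("graph g\nn a [9]\n", "[9]"),
        ("graph g\nn a [5]\nn b [6]\ne a b -\ne b a -\n", "duplicate edge"),
        ("graph g\nn a [5]\ne a c -\n", "undeclared"),
        ("graph g\nn a [5]\ne a a -\n", "self-loop"),
    ],
)
def test_parse_errors_name_offender(tmp_path, body, fragment):
    p = tmp_path / "bad.graphs"
    p.write_text(body, encoding="utf-8")
    with pytest.raises(GraphParseError, match=r".*" + fragment.replace("[", r"\[")):
        load_graphs(p)


def test_triple_bond_alias_accepted(tmp_path):
    p = tmp_path / "t.graphs"
    p.write_text("graph g\nn a [5]\nn b [6]\ne a b #T\n", encoding="utf-8")
    (g,) = load_graphs(p)
    assert g.edge_label("a", "b").value == "≡"


def test_validate_graph_violations():
    ok = make_graph("ok", {"a": "[0]", "b": "[1]"}, [("a", "b", "-")])
    assert validate_graph(ok) == []
    bad = make_graph("bad", {"u": "[0]"})
    bad.edge_labels[("u", "u")] = list(bad.node_labels.values())[0]  # force self-loop
    assert any("self-loop" in v and "u" in v for v in validate_graph(bad))
    bad2 = make_graph("bad2", {"u": "[0]"})
    from ergged.graph_model import EdgeLabel

    bad2.edge_labels[("u", "z")] = EdgeLabel.SINGLE
    assert any("undeclared" in v for v in validate_graph(bad2))


@st.composite
def erg_graphs(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    labels = draw(st.lists(st.sampled_from(NODE_LABELS), min_size=n, max_size=n))
    g = make_graph("hyp", {})
    for i, lab in enumerate(labels):
        g.add_node(f"n{i}", lab)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = draw(st.lists(st.sampled_from(pairs), unique=True, max_size=len(pairs))) if pairs else []
    for i, j in chosen:
        g.add_edge(f"n{i}", f"n{j}", draw(st.sampled_from(EDGE_LABELS)))
    return g


@settings(derandomize=True, max_examples=50, deadline=None)
@given(erg_graphs())
def test_write_load_roundtrip_property(tmp_path_factory, g):
    """Any valid graph survives serialization, and the canonical form is a
    fixed point of write∘load."""
    d = tmp_path_factory.mktemp("rt")
    p1, p2 = d / "a.graphs", d / "b.graphs"
    write_graphs([g], p1)
    (back,) = load_graphs(p1)
    assert back.node_labels == g.node_labels and back.edge_labels == g.edge_labels
    write_graphs([back], p2)
    assert p1.read_text() == p2.read_text()


def test_dataset_assembly_and_class_annotations(tmp_path):
    gp = tmp_path / "d.graphs"
    gp.write_text(
        "graph a1 active\nn x [5]\n\n"
        "graph a2 active\nn x [4]\n\n"
        "graph i1 inactive\nn x [0]\n\n"
        "graph i2 inactive\nn x [1]\n",
        encoding="utf-8",
    )
    sp = tmp_path / "d.split"
    sp.write_text("a1\ttrain\ni1\ttrain\na2\ttest\ni2\ttest\n", encoding="utf-8")
    ds = load_dataset(gp, sp, "toy")
    assert [g.id for g, _ in ds.train] == ["a1", "i1"]
    assert [c for _, c in ds.test] == ["active", "inactive"]
    assert ds.validate() == []
    assert load_split(sp)["a2"] == "test"
    # unlabeled graphs are rejected for dataset assembly but fine standalone
    gp2 = tmp_path / "plain.graphs"
    gp2.write_text("graph a1\nn x [5]\n", encoding="utf-8")
    assert load_labeled_graphs(gp2)[0][1] is None
    with pytest.raises(GraphParseError, match="class"):
        load_dataset(gp2, sp, "toy")
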