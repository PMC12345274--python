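"""PPI loading, backbone construction, GBA expansion, core extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nsdgrn.grn import (
    annotate_categories,
    build_backbone,
    core_table,
    extract_core,
    gba_expand,
    load_ppi,
)
from nsdgrn.chip import classify_targets
from nsdgrn.models import NsdgrnError

REG = "NsdD"


def edges_df(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


# ---------------------------------------------------------------------------
# load_ppi
# ---------------------------------------------------------------------------


def test_confidence_threshold_is_inclusive(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("a\tb\t150\na\tc\t149\nb\tc\t151\n")
    df = load_ppi(path, 150)
    kept = set(map(tuple, df[["node_a", "node_b"]].to_numpy()))
    assert kept == {("a", "b"), ("b", "c")}


def test_duplicate_unordered_pair_keeps_max_confidence(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("node_a\tnode_b\tconfidence\na\tb\t200\nb\ta\t300\n")
    df = load_ppi(path, 150)
    assert len(df) == 1
    assert df.iloc[0]["confidence"] == 300


def test_malformed_confidence_is_error_with_line_number(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("a\tb\t200\na\tc\tNOPE\n")
    with pytest.raises(NsdgrnError, match=":2"):
        load_ppi(path, 150)


def test_self_loops_dropped():
    df = load_ppi(edges_df([("a", "a", 500), ("a", "b", 500)]), 150)
    assert len(df) == 1


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------


def classification(chip, degs, universe):
    return classify_targets(chip, degs, universe)


def test_backbone_without_qualifying_edges_is_direct_binding_star():
    cls = classification({"a", "b"}, set(), {"a", "b", "x", "y"})
    edges = edges_df([("x", "y", 500)])  # neither endpoint associated
    g = build_backbone(edges, cls, REG)
    assert set(g.nodes) == {"a", "b", REG}
    assert all(d["kind"] == "direct_binding" for *_, d in g.edges(data=True))
    assert g.degree(REG) == 2


def test_backbone_keeps_only_doubly_associated_edges():
    # fixture of 6 edges; exactly 3 have both endpoints associated
    cls = classification({"a", "b"}, {"c", "d"}, set("abcdefg"))
    edges = edges_df(
        [
            ("a", "b", 200),  # both
            ("a", "c", 200),  # both
            ("c", "d", 200),  # both
            ("a", "e", 200),  # e not associated
            ("e", "f", 200),
            ("d", "g", 200),
        ]
    )
    g = build_backbone(edges, cls, REG)
    ppi_edges = {
        frozenset(e) for *e, d in g.edges(data=True) if d["kind"] == "ppi"
    }
    assert ppi_edges == {frozenset("ab"), frozenset("ac"), frozenset("cd")}


def test_backbone_with_everything_associated_keeps_all_edges():
    cls = classification({"a"}, {"b", "c"}, {"a", "b", "c"})
    edges = edges_df([("a", "b", 200), ("b", "c", 300), ("a", "c", 400)])
    g = build_backbone(edges, cls, REG)
    assert g.number_of_edges() == 3 + 1  # 3 ppi + regulator->a


def test_backbone_origin_attributes():
    cls = classification({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d"})
    g = build_backbone(edges_df([]), cls, REG)
    assert g.nodes["a"]["origin"] == "chip"
    assert g.nodes["b"]["origin"] == "both"
    assert g.nodes["c"]["origin"] == "rna"
    assert g.nodes[REG]["origin"] == "regulator"
    assert "d" not in g  # not associated


def test_isolated_associated_genes_retained_by_default_dropped_on_toggle():
    cls = classification(set(), {"lonely"}, {"lonely", "x"})
    g = build_backbone(edges_df([]), cls, REG)
    assert "lonely" in g and g.degree("lonely") == 0
    g2 = build_backbone(edges_df([]), cls, REG, keep_isolated=False)
    assert "lonely" not in g2


@pytest.mark.parametrize("seed", range(10))
def test_backbone_edges_match_brute_force_filter(seed):
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(60)]
    chip = set(rng.choice(universe, size=10, replace=False))
    degs = set(rng.choice(universe, size=20, replace=False))
    cls = classification(chip, degs, universe)
    rows = []
    for _ in range(120):
        a, b = rng.choice(universe, size=2, replace=False)
        rows.append((a, b, float(rng.integers(150, 1000))))
    edges = load_ppi(edges_df(rows), 150)
    g = build_backbone(edges, cls, REG)
    expected = {
        frozenset((a, b))
        for a, b, _ in edges.itertuples(index=False)
        if a in cls.associated and b in cls.associated
    }
    got = {frozenset(e) for *e, d in g.edges(data=True) if d["kind"] == "ppi"}
    # the regulator's direct edges may overlay a ppi edge; exclude regulator pairs
    expected = {e for e in expected if REG not in e}
    assert got == expected


# ---------------------------------------------------------------------------
# GBA expansion
# ---------------------------------------------------------------------------


def test_expand_without_external_neighbors_is_fixed_point():
    cls = classification({"a"}, {"b"}, {"a", "b"})
    edges = edges_df([("a", "b", 200)])
    backbone = build_backbone(edges, cls, REG)
    expanded = gba_expand(backbone, edges)
    assert nx.utils.graphs_equal(backbone, expanded)


def test_star_expansion_adds_all_spokes():
    cls = classification({"hub"}, set(), {"hub"} | {f"s{i}" for i in range(5)})
    spokes = edges_df([("hub", f"s{i}", 200) for i in range(5)])
    backbone = build_backbone(edges_df([]), cls, REG)
    expanded = gba_expand(backbone, spokes)
    assert set(expanded.nodes) == {"hub", REG} | {f"s{i}" for i in range(5)}
    for i in range(5):
        assert expanded.nodes[f"s{i}"]["origin"] == "neighbor"


def bfs_depth1(edge_table, sources):
    """Independent oracle: breadth-first search truncated at depth 1."""
    adjacency = {}
    for a, b, _ in edge_table.itertuples(index=False):
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    reached = set(sources)
    for s in sources:
        reached |= adjacency.get(s, set())
    return reached


@pytest.mark.parametrize("seed", range(10))
def test_expansion_node_set_equals_depth1_bfs(seed):
    rng = np.random.default_rng(100 + seed)
    universe = [f"g{i}" for i in range(80)]
    chip = set(rng.choice(universe, size=6, replace=False))
    degs = set(rng.choice(universe, size=10, replace=False))
    cls = classification(chip, degs, universe)
    rows = []
    for _ in range(150):
        a, b = rng.choice(universe, size=2, replace=False)
        rows.append((a, b, float(rng.integers(150, 1000))))
    edges = load_ppi(edges_df(rows), 150)
    backbone = build_backbone(edges, cls, REG)
    expanded = gba_expand(backbone, edges)
    assert set(expanded.nodes) == bfs_depth1(edges, set(backbone.nodes))


def test_double_expansion_differs_iff_depth2_neighbors_exist():
    # path: a(backbone) - n1 - n2; one pass adds n1 only, a second adds n2
    cls = classification({"a"}, set(), {"a"})
    edges = edges_df([("a", "n1", 200), ("n1", "n2", 200)])
    backbone = build_backbone(edges_df([]), cls, REG)
    once = gba_expand(backbone, edges)
    twice = gba_expand(once, edges)
    assert set(once.nodes) == {"a", REG, "n1"}
    assert set(twice.nodes) == {"a", REG, "n1", "n2"}  # guards against closure


def test_operations_are_row_order_invariant():
    cls = classification({"a", "b"}, {"c"}, set("abcxyz"))
    rows = [("a", "c", 200), ("c", "x", 300), ("b", "y", 400), ("x", "z", 500)]
    edges_fwd = edges_df(rows)
    edges_rev = edges_df(rows[::-1])
    g1 = gba_expand(build_backbone(edges_fwd, cls, REG), edges_fwd)
    g2 = gba_expand(build_backbone(edges_rev, cls, REG), edges_rev)
    assert nx.utils.graphs_equal(g1, g2)


# ---------------------------------------------------------------------------
# core extraction
# ---------------------------------------------------------------------------


def seeded_graph():
    g = nx.Graph()
    g.add_node(REG, origin="regulator")
    for n in ["veA", "flbD", "laeA", "steA"]:
        g.add_node(n, origin="chip")
    g.add_edge(REG, "veA", kind="direct_binding")
    return g


def test_minimal_target_keeps_exactly_regulator_plus_seeds():
    g = seeded_graph()
    core = extract_core(g, ["veA", "flbD"], size_target=3, regulator_id=REG)
    assert set(core.nodes) == {REG, "veA", "flbD"}


def test_clique_core_tie_broken_lexicographically():
    # 50-clique: all neighbors tie on degree, so selection after the two
    # seeds must be the lexicographically smallest ids
    g = nx.complete_graph([f"n{i:02d}" for i in range(50)])
    g.add_node(REG)
    g.add_edge(REG, "n00", kind="direct_binding")
    core = extract_core(g, ["n48", "n49"], size_target=30, regulator_id=REG)
    assert core.number_of_nodes() == 30
    expected = {REG, "n48", "n49"} | {f"n{i:02d}" for i in range(27)}
    assert set(core.nodes) == expected


def test_disconnected_seed_retained_as_isolated_node():
    g = seeded_graph()
    g.add_node("orphan", origin="rna")
    core = extract_core(g, ["veA", "orphan"], size_target=5, regulator_id=REG)
    assert "orphan" in core
    assert core.degree("orphan") == 0
    assert core.nodes["orphan"]["is_seed"]


def test_size_target_below_seed_count_is_hard_error():
    g = seeded_graph()
    with pytest.raises(NsdgrnError, match="size_target"):
        extract_core(g, ["veA", "flbD", "laeA"], size_target=3, regulator_id=REG)


def test_missing_seed_warns_and_is_dropped():
    g = seeded_graph()
    with pytest.warns(UserWarning, match="ghost"):
        core = extract_core(g, ["veA", "ghost"], size_target=5, regulator_id=REG)
    assert "ghost" not in core


def test_core_size_never_exceeds_target_and_fills_when_possible():
    g = nx.complete_graph([f"n{i:02d}" for i in range(40)])
    g.add_node(REG)
    g.add_edge(REG, "n00")
    core = extract_core(g, ["n00"], size_target=30, regulator_id=REG)
    assert core.number_of_nodes() == 30
    small = extract_core(seeded_graph(), ["flbD"], size_target=30, regulator_id=REG)
    assert small.number_of_nodes() <= 30


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------


def test_empty_map_labels_everything_unannotated():
    g = seeded_graph()
    out = annotate_categories(g, {})
    assert all(d["category"] == "unannotated" for _, d in out.nodes(data=True))


def test_unknown_category_label_is_hard_error():
    with pytest.raises(NsdgrnError, match="mystery"):
        annotate_categories(seeded_graph(), {"veA": "mystery"})


def test_category_labels_round_trip_through_graphml(tmp_path):
    from nsdgrn import io as nio

    g = annotate_categories(
        seeded_graph(),
        {"veA": "sexual development", "flbD": "asexual development"},
    )
    for n in g.nodes:
        g.nodes[n].setdefault("is_seed", False)
    path = tmp_path / "cats.graphml"
    nio.write_network(g, path, "graphml")
    back = nio.read_network(path)
    assert back.nodes["veA"]["category"] == "sexual development"
    assert back.nodes["flbD"]["category"] == "asexual development"


def test_core_table_lists_nodes_with_attributes():
    g = annotate_categories(seeded_graph(), {"veA": "sexual development"})
    for n in g.nodes:
        g.nodes[n].setdefault("is_seed", False)
    table = core_table(g)
    assert list(table.columns) == ["node", "origin", "category", "is_seed", "degree"]
    assert len(table) == g.number_of_nodes()
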