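"""Graph construction, induced-edge counting, permutation test, enrichment."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ribiscreen.network import (
    BIOGRID_EVIDENCE_MAP,
    build_graph,
    component_stats,
    count_induced_edges,
    count_induced_edge_lines,
    export_graph,
    hypergeometric_enrichment,
    map_evidence,
    permutation_test,
    prune_hubs,
    read_edge_list,
    write_edge_list,
)
from conftest import brute_force_induced_edges, hypergeom_upper_tail_enumeration


EDGES = [("A", "B", "affinity"), ("B", "C", "other"), ("C", "D", "other"), ("A", "E", "other")]


def test_induced_graph_on_hit_set():
    graph = build_graph(EDGES, "ABCDE", {"A", "B", "C"})
    assert set(graph.nodes) == {"A", "B", "C"}
    assert set(map(frozenset, graph.edges)) == {frozenset("AB"), frozenset("BC")}


def test_self_loops_dropped_and_duplicates_merged_by_precedence():
    edges = [("A", "A", "affinity"), ("A", "B", "interaction_screen"), ("B", "A", "affinity")]
    graph = build_graph(edges, "AB", {"A", "B"})
    assert list(graph.edges) == [("A", "B")]
    assert graph.edges["A", "B"]["evidence_class"] == "affinity"


def test_unknown_hit_kept_isolated_with_warning():
    with pytest.warns(UserWarning, match="not in the universe"):
        graph = build_graph(EDGES, "ABCDE", {"A", "B", "Zz"})
    assert "Zz" in graph.nodes
    assert graph.degree("Zz") == 0


def test_biogrid_evidence_mapping():
    assert map_evidence("Affinity Capture-MS") == "affinity"
    assert map_evidence("Reconstituted Complex") == "affinity"
    assert map_evidence("Two-hybrid") == "interaction_screen"
    assert map_evidence("FRET") == "other"
    assert map_evidence("Never Heard Of It") == "other"
    assert set(BIOGRID_EVIDENCE_MAP.values()) == {"affinity", "interaction_screen", "other"}


def test_count_induced_edges_examples():
    edges = [("A", "B", "other"), ("B", "C", "other"), ("C", "D", "other")]
    assert count_induced_edges(edges, {"A", "B", "C"}) == 2
    assert count_induced_edges(edges, set()) == 0
    duplicated = edges + [("B", "A", "affinity")]
    assert count_induced_edges(duplicated, {"A", "B"}) == 1
    assert count_induced_edge_lines(duplicated, {"A", "B"}) == 2


def test_count_matches_brute_force_on_small_graphs():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(50)]
    for _ in range(20):
        n_edges = int(rng.integers(0, 120))
        edges = [
            (genes[int(a)], genes[int(b)], "other")
            for a, b in rng.integers(0, 50, size=(n_edges, 2))
        ]
        subset = {str(g) for g in rng.choice(genes, size=int(rng.integers(0, 30)), replace=False)}
        assert count_induced_edges(edges, subset) == brute_force_induced_edges(edges, subset)


def test_random_subset_mean_matches_uniform_placement_expectation():
    """Monte-Carlo mean of induced edges over random 100-gene subsets of a
    uniform 1000-node, 2000-edge graph matches M*k(k-1)/(N(N-1))."""
    from ribiscreen.synthetic_data import GraphGeneratorConfig, generate_graph, strain_ids

    genes = strain_ids(1000)
    edges = generate_graph(
        GraphGeneratorConfig(n_genes=1000, background_edges=2000, planted_set_size=0,
                             planted_extra_edges=0, seed=21),
        [],
        genes=genes,
    )
    result = permutation_test(edges, genes, set_size=100, observed_set=[],
                              n_permutations=2000, seed=22)
    expected = 2000 * (100 * 99) / (1000 * 999)
    assert result.null_mean == pytest.approx(expected, rel=0.05)


def test_permutation_degenerate_full_universe():
    genes = ["A", "B", "C", "D"]
    edges = [("A", "B", "other"), ("C", "D", "other")]
    result = permutation_test(edges, genes, set_size=4, observed_set=genes,
                              n_permutations=50, seed=1)
    assert result.observed_edges == 2
    assert result.null_mean == 2.0
    assert result.null_max == 2
    assert result.empirical_p == 1.0


def test_permutation_p_is_never_zero():
    from ribiscreen.synthetic_data import GraphGeneratorConfig, generate_graph, strain_ids

    genes = strain_ids(300)
    planted = genes[:60]
    edges = generate_graph(
        GraphGeneratorConfig(n_genes=300, background_edges=600, planted_set_size=60,
                             planted_extra_edges=300, seed=5),
        planted,
        genes=genes,
    )
    result = permutation_test(edges, genes, 60, planted, n_permutations=500, seed=6)
    assert result.empirical_p == pytest.approx(1 / 501)
    assert 0 < result.empirical_p <= 1


def test_prune_hubs_examples():
    graph = build_graph(
        [("H", "X", "other"), ("H", "Y", "other"), ("X", "Z", "other")],
        "HXYZ",
        {"H", "X", "Y", "Z"},
    )
    pruned = prune_hubs(graph, {"H"})
    assert set(pruned.nodes) == {"X", "Z"}
    assert list(pruned.edges) == [("X", "Z")]
    # pruning an absent gene changes nothing
    same = prune_hubs(graph, {"nope"})
    assert set(same.nodes) == set(graph.nodes) and set(same.edges) == set(graph.edges)


def test_prune_hubs_matches_brute_force_and_keeps_isolates():
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(40)]
    for rep in range(10):
        edges = [
            (genes[int(a)], genes[int(b)], "other")
            for a, b in rng.integers(0, 40, size=(60, 2))
            if a != b
        ]
        graph = build_graph(edges, genes, set(genes))
        hubs = {str(g) for g in rng.choice(genes, size=3, replace=False)}
        pruned = prune_hubs(graph, hubs)
        expected_removed = set(hubs)
        for n in graph.nodes:
            nbrs = set(graph.neighbors(n))
            if n not in hubs and nbrs and nbrs <= hubs:
                expected_removed.add(n)
        assert set(pruned.nodes) == set(graph.nodes) - expected_removed
        for n in pruned.nodes:
            if graph.degree(n) > 0 and not set(graph.neighbors(n)) <= hubs:
                assert n in pruned.nodes  # nodes with a non-hub edge always survive


def test_component_stats_examples():
    edgeless = build_graph([], "ABCDE", set("ABCDE"))
    stats = component_stats(edgeless)
    assert stats.major_component_size == 1
    assert stats.isolated_count == 5

    path_graph = build_graph(
        [("A", "B", "other"), ("B", "C", "other")], "ABCD", set("ABCD")
    )
    stats = component_stats(path_graph)
    assert stats.major_component_size == 3
    assert stats.isolated_count == 1
    assert sum(stats.component_sizes) == 4


def test_component_sizes_conserve_nodes(small_screen):
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(30)]
    edges = [
        (genes[int(a)], genes[int(b)], "other")
        for a, b in rng.integers(0, 30, size=(25, 2))
    ]
    graph = build_graph(edges, genes, set(genes))
    stats = component_stats(graph)
    assert sum(stats.component_sizes) == graph.number_of_nodes()


def test_hypergeometric_examples():
    universe = [f"u{i}" for i in range(10)]
    annot = universe[:5]
    hits = universe[1:5]  # overlap 4 of 4 hits
    p = hypergeometric_enrichment(hits, annot, universe)
    assert p == pytest.approx(5 / 210)
    assert hypergeometric_enrichment(hits, universe, universe) == pytest.approx(1.0)
    assert hypergeometric_enrichment(universe[5:9], annot, universe) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeometric_enrichment(hits, annot, [])


def test_hypergeometric_matches_enumeration():
    rng = np.random.default_rng(44)
    for _ in range(25):
        n = int(rng.integers(5, 21))
        universe = [f"u{i}" for i in range(n)]
        annot = {str(g) for g in rng.choice(universe, size=int(rng.integers(1, n + 1)), replace=False)}
        hits = {str(g) for g in rng.choice(universe, size=int(rng.integers(1, n + 1)), replace=False)}
        expected = hypergeom_upper_tail_enumeration(n, len(annot), len(hits), len(annot & hits))
        assert hypergeometric_enrichment(hits, annot, universe) == pytest.approx(expected)


def test_graphml_round_trip(tmp_path):
    graph = build_graph(
        [("A", "B", "affinity"), ("B", "C", "interaction_screen")],
        "ABC",
        {"A", "B", "C"},
        annotations={
            "A": {"downstream_torc1": True, "localization": "nucleus"},
            "B": {"downstream_torc1": False, "localization": "endomembrane_vacuole"},
            "C": {"downstream_torc1": False, "localization": "other"},
        },
    )
    path = tmp_path / "net.graphml"
    export_graph(graph, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(graph.nodes)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, graph.edges))
    assert back.nodes["A"]["downstream_torc1"] is True
    assert back.nodes["B"]["localization"] == "endomembrane_vacuole"
    assert back.edges["A", "B"]["evidence_class"] == "affinity"


def test_sif_export_lists_edges_and_isolates(tmp_path):
    graph = build_graph([("A", "B", "affinity")], "ABC", {"A", "B", "C"})
    path = tmp_path / "net.sif"
    export_graph(graph, path)
    lines = path.read_text().splitlines()
    assert "A\taffinity\tB" in lines
    assert "C" in lines


def test_empty_graph_exports_valid_files(tmp_path):
    empty = nx.Graph()
    export_graph(empty, tmp_path / "e.graphml")
    export_graph(empty, tmp_path / "e.sif")
    assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
    assert (tmp_path / "e.sif").read_text() == ""


def test_edge_list_tsv_round_trip(tmp_path):
    frame = pd.DataFrame(EDGES, columns=["gene_a", "gene_b", "evidence_class"])
    path = tmp_path / "edges.tsv"
    write_edge_list(frame, path)
    assert read_edge_list(path).equals(frame)
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.tsv"
        bad.write_text("x\ty\n1\t2\n")
        read_edge_list(bad)
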