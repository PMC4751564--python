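"""Evidence-typed interaction networks over the hit set and connectivity tests.

The central statistic is the induced-edge count: the number of unique
interaction pairs whose both endpoints lie in a gene set. Its significance
is assessed by drawing many random same-sized gene sets from the screened
universe and counting their induced edges; the add-one empirical p-value
never reaches zero, so the smallest reportable value with 10,000 draws is
1/10,001.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _stats

EVIDENCE_AFFINITY = "affinity"
EVIDENCE_SCREEN = "interaction_screen"
EVIDENCE_OTHER = "other"
EVIDENCE_CLASSES = (EVIDENCE_AFFINITY, EVIDENCE_SCREEN, EVIDENCE_OTHER)
# merged duplicate pairs keep the strongest evidence class
EVIDENCE_PRECEDENCE = {EVIDENCE_AFFINITY: 0, EVIDENCE_SCREEN: 1, EVIDENCE_OTHER: 2}

#: Mapping from BioGRID experimental-system names to the three edge classes.
BIOGRID_EVIDENCE_MAP = {
    "Affinity Capture-Luminescence": EVIDENCE_AFFINITY,
    "Affinity Capture-MS": EVIDENCE_AFFINITY,
    "Affinity Capture-RNA": EVIDENCE_AFFINITY,
    "Affinity Capture-Western": EVIDENCE_AFFINITY,
    "Reconstituted Complex": EVIDENCE_AFFINITY,
    "Two-hybrid": EVIDENCE_SCREEN,
    "Protein-Fragment Complementation Assay": EVIDENCE_SCREEN,
    "Biochemical Activity": EVIDENCE_OTHER,
    "Cocrystal Structure": EVIDENCE_OTHER,
    "Cofractionation": EVIDENCE_OTHER,
    "Colocalization": EVIDENCE_OTHER,
    "Copurification": EVIDENCE_OTHER,
    "FRET": EVIDENCE_OTHER,
}

EDGE_COLUMNS = ["gene_a", "gene_b", "evidence_class"]


def map_evidence(experimental_system: str) -> str:
    """Collapse a BioGRID experimental-system name to an edge class."""
    return BIOGRID_EVIDENCE_MAP.get(experimental_system, EVIDENCE_OTHER)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Load a 3-column TSV edge list (gene_a, gene_b, evidence_class)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: edge list missing columns {missing}")
    return frame


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def _edge_arrays(edge_list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize an edge list (DataFrame or iterable of tuples) to arrays."""
    if isinstance(edge_list, pd.DataFrame):
        a = edge_list["gene_a"].to_numpy(dtype=object)
        b = edge_list["gene_b"].to_numpy(dtype=object)
        cls = edge_list["evidence_class"].to_numpy(dtype=object)
    else:
        rows = [tuple(e) for e in edge_list]
        a = np.array([r[0] for r in rows], dtype=object)
        b = np.array([r[1] for r in rows], dtype=object)
        cls = np.array(
            [r[2] if len(r) > 2 else EVIDENCE_OTHER for r in rows], dtype=object
        )
    return a, b, cls


def count_induced_edges(edge_list, gene_set: Iterable[str]) -> int:
    """Unique unordered pairs within ``gene_set``, excluding self-loops."""
    genes = set(gene_set)
    if not genes:
        return 0
    a, b, _ = _edge_arrays(edge_list)
    pairs = {
        (x, y) if x < y else (y, x)
        for x, y in zip(a, b)
        if x != y and x in genes and y in genes
    }
    return len(pairs)


def count_induced_edge_lines(edge_list, gene_set: Iterable[str]) -> int:
    """Induced edges counted as evidence lines (duplicate pairs not merged)."""
    genes = set(gene_set)
    a, b, _ = _edge_arrays(edge_list)
    return int(sum(1 for x, y in zip(a, b) if x != y and x in genes and y in genes))


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed-vs-null induced-edge-count test outcome."""

    observed_edges: int
    n_permutations: int
    null_mean: float
    null_max: int
    null_distribution: dict[int, int]
    empirical_p: float
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_edges": self.observed_edges,
            "n_permutations": self.n_permutations,
            "null_mean": self.null_mean,
            "null_max": self.null_max,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "null_distribution": {str(k): v for k, v in sorted(self.null_distribution.items())},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def permutation_test(
    edge_list,
    universe: Sequence[str],
    set_size: int,
    observed_set: Iterable[str],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Connectivity enrichment of a gene set by induced-subgraph permutation.

    Draws ``n_permutations`` uniform ``set_size``-subsets of ``universe``
    (without replacement within a draw, independently across draws), counts
    each subset's induced edges among the unique pairs of ``edge_list``, and
    reports the add-one empirical p-value for the observed set.
    """
    universe = list(universe)
    n_genes = len(universe)
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds universe size {n_genes}")
    index = {g: i for i, g in enumerate(universe)}

    a, b, _ = _edge_arrays(edge_list)
    pairs = set()
    for x, y in zip(a, b):
        if x == y or x not in index or y not in index:
            continue
        i, j = index[x], index[y]
        pairs.add((i, j) if i < j else (j, i))
    if pairs:
        ai = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        bi = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    else:
        ai = bi = np.empty(0, dtype=np.int64)

    member = np.zeros(n_genes, dtype=bool)
    obs_idx = [index[g] for g in observed_set if g in index]
    member[obs_idx] = True
    observed = int(np.count_nonzero(member[ai] & member[bi]))

    rng = np.random.default_rng(seed)
    counts = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        member[:] = False
        member[rng.choice(n_genes, size=set_size, replace=False)] = True
        counts[i] = np.count_nonzero(member[ai] & member[bi])

    exceed = int(np.count_nonzero(counts >= observed))
    return PermutationTestResult(
        observed_edges=observed,
        n_permutations=n_permutations,
        null_mean=float(counts.mean()),
        null_max=int(counts.max()),
        null_distribution=dict(Counter(counts.tolist())),
        empirical_p=(exceed + 1) / (n_permutations + 1),
        seed=seed,
    )


def build_graph(
    edge_list,
    gene_universe: Iterable[str],
    hit_set: Iterable[str],
    annotations: Mapping[str, Mapping] | None = None,
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Induced evidence-typed graph on the hit set (plus reference nodes).

    Self-loops are dropped; duplicate pairs are merged keeping the
    strongest evidence class (affinity > interaction_screen > other). Hits
    absent from the gene universe are kept as isolated nodes with a warning.
    """
    universe = set(gene_universe)
    nodes = set(hit_set) | set(extra_nodes)
    unknown = nodes - universe - set(extra_nodes)
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit genes not in the universe (kept isolated): "
            f"{sorted(unknown)[:5]}",
            stacklevel=2,
        )
    graph = nx.Graph()
    for n in sorted(nodes):
        attrs = dict(annotations.get(n, {})) if annotations else {}
        graph.add_node(n, **attrs)
    a, b, cls = _edge_arrays(edge_list)
    for x, y, c in zip(a, b, cls):
        if x == y or x not in nodes or y not in nodes:
            continue
        c = c if c in EVIDENCE_PRECEDENCE else EVIDENCE_OTHER
        if graph.has_edge(x, y):
            old = graph.edges[x, y]["evidence_class"]
            if EVIDENCE_PRECEDENCE[c] < EVIDENCE_PRECEDENCE[old]:
                graph.edges[x, y]["evidence_class"] = c
        else:
            graph.add_edge(x, y, evidence_class=c)
    return graph


def prune_hubs(graph: nx.Graph, hub_genes: Iterable[str]) -> nx.Graph:
    """Remove promiscuous hub nodes and nodes connected only through them.

    A node is dropped either because it is a listed hub, or because it has
    at least one edge and every one of its neighbors is a hub. Nodes
    retaining any non-hub edge -- and isolated nodes -- are kept.
    """
    hubs = set(hub_genes) & set(graph.nodes)
    doomed = set(hubs)
    for n in graph.nodes:
        if n in hubs:
            continue
        neighbors = set(graph.neighbors(n))
        if neighbors and neighbors <= hubs:
            doomed.add(n)
    pruned = graph.copy()
    pruned.remove_nodes_from(doomed)
    return pruned


@dataclass(frozen=True)
class ComponentStats:
    major_component_size: int
    isolated_count: int
    component_sizes: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "major_component_size": self.major_component_size,
            "isolated_count": self.isolated_count,
            "component_sizes": list(self.component_sizes),
        }


def component_stats(graph: nx.Graph) -> ComponentStats:
    """Largest connected component, count of degree-0 nodes, all sizes."""
    sizes = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return ComponentStats(
        major_component_size=sizes[0] if sizes else 0,
        isolated_count=sum(1 for n in graph.nodes if graph.degree(n) == 0),
        component_sizes=tuple(sizes),
    )


def hypergeometric_enrichment(
    hit_set: Iterable[str], annotation_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric probability of the hit/annotation overlap.

    P(X >= k) for k = |hits ∩ annotation| when |hits| genes are drawn from a
    universe containing |annotation| annotated genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_set) & universe
    annot = set(annotation_set) & universe
    k = len(hits & annot)
    return float(_stats.hypergeom.sf(k - 1, len(universe), len(annot), len(hits)))


def export_graph(graph: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write the annotated graph as GraphML or SIF.

    GraphML carries node attributes (e.g. the downstream-of-TORC1 flag that
    drives node-center coloring, localization tags for border coloring) and
    the per-edge evidence class; SIF encodes edges as
    ``gene_a <tab> evidence_class <tab> gene_b`` with bare lines for
    isolated nodes. Both import directly into standard graph viewers.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        lines = []
        for a, b, data in sorted(graph.edges(data=True)):
            lines.append(f"{a}\t{data.get('evidence_class', EVIDENCE_OTHER)}\t{b}")
        for n in sorted(graph.nodes):
            if graph.degree(n) == 0:
                lines.append(str(n))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
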