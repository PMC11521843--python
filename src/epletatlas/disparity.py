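"""Hamming distances between allele profiles and 1-nearest-neighbour
disparity graphs.

Distances are only meaningful between alleles whose mature-protein position
numbering is comparable; these sets of loci are modelled as coordinate
namespaces.  By default the class I heavy chains (A, B, C) share one
namespace, the DRB chains (DRB1/3/4/5) share one, and DQA1, DQB1, DPA1 and
DPB1 each stand alone.

A group's disparity graph contains the group's alleles as nodes; every
allele is linked to all of its most similar neighbours.  Alleles that are
strictly more similar to another group than to their own ("cross-reactive"
in the computational sense) are instead linked to their foreign nearest
neighbours, which are added to the graph as external nodes.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np

from .atlas import AlleleProfile
from .registry import AlleleName

Policy = Literal["difference", "shared_only"]

DEFAULT_NAMESPACES: dict[str, frozenset[str]] = {
    "classI": frozenset({"A", "B", "C"}),
    "DRB": frozenset({"DRB1", "DRB3", "DRB4", "DRB5"}),
    "DQA1": frozenset({"DQA1"}),
    "DQB1": frozenset({"DQB1"}),
    "DPA1": frozenset({"DPA1"}),
    "DPB1": frozenset({"DPB1"}),
}


def namespace_of(locus: str, namespaces: Mapping[str, frozenset[str]] | None = None) -> str:
    namespaces = namespaces or DEFAULT_NAMESPACES
    for name, loci in namespaces.items():
        if locus in loci:
            return name
    raise ValueError(f"locus {locus!r} not covered by any coordinate namespace")


def hamming_distance(
    p1: AlleleProfile, p2: AlleleProfile, policy: Policy = "difference"
) -> int:
    """Number of positions with differing amino-acid content.

    A position differs when the two residue sets are disjoint (an allele
    carrying S/G overlaps one carrying G).  Under the default ``difference``
    policy a position covered by only one profile counts as a difference;
    ``shared_only`` restricts the count to positions covered by both.
    """
    if policy == "difference":
        d = 0
        for pos in p1.residues.keys() | p2.residues.keys():
            a, b = p1.residues.get(pos), p2.residues.get(pos)
            if a is None or b is None or not (a & b):
                d += 1
        return d
    if policy == "shared_only":
        d = 0
        for pos in p1.residues.keys() & p2.residues.keys():
            if not (p1.residues[pos] & p2.residues[pos]):
                d += 1
        return d
    raise ValueError(f"unknown distance policy {policy!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Hamming distances within one coordinate namespace."""

    alleles: list[AlleleName]
    values: np.ndarray  # (n, n) int array
    policy: Policy = "difference"
    namespace: str = ""

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.alleles)}

    def distance(self, a: AlleleName, b: AlleleName) -> int:
        return int(self.values[self._index[a], self._index[b]])

    def __contains__(self, allele: AlleleName) -> bool:
        return allele in self._index

    def groups(self) -> list[str]:
        return sorted({a.group_label for a in self.alleles})

    def group_members(self, group_label: str) -> list[AlleleName]:
        return [a for a in self.alleles if a.group_label == group_label]

    def to_frame(self):
        import pandas as pd

        names = [a.raw for a in self.alleles]
        return pd.DataFrame(self.values, index=names, columns=names)


def distance_matrix(
    atlas: Mapping[AlleleName, AlleleProfile],
    namespace: str | None = None,
    policy: Policy = "difference",
    namespaces: Mapping[str, frozenset[str]] | None = None,
) -> DistanceMatrix:
    """All pairwise distances between atlas profiles of one namespace.

    With ``namespace=None`` all atlas alleles must already share a single
    namespace; otherwise pass the namespace name to select its loci.
    """
    namespaces = namespaces or DEFAULT_NAMESPACES
    if namespace is None:
        spaces = {namespace_of(a.locus, namespaces) for a in atlas}
        if len(spaces) > 1:
            raise ValueError(
                f"atlas spans namespaces {sorted(spaces)}; pass namespace= to select one"
            )
        namespace = spaces.pop() if spaces else ""
        alleles = sorted(atlas)
    else:
        loci = namespaces[namespace]
        alleles = sorted(a for a in atlas if a.locus in loci)
    if not alleles:
        raise ValueError(f"no atlas alleles in namespace {namespace!r}")
    n = len(alleles)
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming_distance(atlas[alleles[i]], atlas[alleles[j]], policy)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(alleles=alleles, values=values, policy=policy, namespace=namespace)


Scope = Literal["own_group", "other_groups", "all"]


def nearest_neighbours(
    matrix: DistanceMatrix, allele: AlleleName, scope: Scope = "all"
) -> set[tuple[AlleleName, int]]:
    """All alleles attaining the minimal distance to ``allele`` in scope.

    Ties are not broken: every minimal-distance neighbour is returned, which
    keeps downstream graphs deterministic.  An empty scope (e.g. own_group
    for a singleton group) yields the empty set.
    """
    if allele not in matrix:
        raise KeyError(f"allele {allele} not in distance matrix")
    group = allele.group_label
    candidates = [
        b
        for b in matrix.alleles
        if b != allele
        and (
            scope == "all"
            or (scope == "own_group" and b.group_label == group)
            or (scope == "other_groups" and b.group_label != group)
        )
    ]
    if not candidates:
        return set()
    dmin = min(matrix.distance(allele, b) for b in candidates)
    return {(b, dmin) for b in candidates if matrix.distance(allele, b) == dmin}


@dataclass(frozen=True)
class CrossReactivity:
    is_cross_reactive: bool
    d_own: int | None
    d_other: int | None


def classify_cross_reactive(matrix: DistanceMatrix, allele: AlleleName) -> CrossReactivity:
    """Is the allele strictly nearer to a foreign group than to its own?

    Ties resolve to the own group.  For a singleton group d_own is None and
    the allele is trivially cross-reactive whenever any foreign allele
    exists (the degenerate-group pattern of loci such as DPB1).
    """
    own = nearest_neighbours(matrix, allele, "own_group")
    other = nearest_neighbours(matrix, allele, "other_groups")
    d_own = min(d for _, d in own) if own else None
    d_other = min(d for _, d in other) if other else None
    if d_other is None:
        return CrossReactivity(False, d_own, None)
    if d_own is None:
        return CrossReactivity(True, None, d_other)
    return CrossReactivity(d_other < d_own, d_own, d_other)


def monomorphic_clusters(matrix: DistanceMatrix, group_label: str) -> list[set[AlleleName]]:
    """Connected components of the distance-0 relation within a group.

    Distance 0 means identical residue maps, so the relation is transitive
    and the components are true equivalence classes.  Singletons are not
    reported.
    """
    members = matrix.group_members(group_label)
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if matrix.distance(a, b) == 0:
                g.add_edge(a, b)
    return sorted(
        (set(c) for c in nx.connected_components(g) if len(c) > 1),
        key=lambda c: min(c),
    )


def build_disparity_graph(
    atlas: Mapping[AlleleName, AlleleProfile],
    matrix: DistanceMatrix,
    group_label: str,
) -> nx.Graph:
    """Disparity graph of one allele group with cross-reactive augmentation.

    In-group alleles link to all their nearest own-group neighbours; alleles
    classified cross-reactive link instead to their nearest foreign-group
    neighbours, which enter the graph flagged ``is_external``.  Edges carry
    the Hamming distance; distance-0 edges are flagged ``monomorphic`` (their
    labels are suppressed when rendering).
    """
    members = matrix.group_members(group_label)
    if not members:
        raise ValueError(f"group {group_label!r} has no alleles in the matrix")
    g = nx.Graph(focus_group=group_label, policy=matrix.policy, namespace=matrix.namespace)

    clusters = monomorphic_clusters(matrix, group_label)
    cluster_id = {a: i for i, c in enumerate(clusters) for a in sorted(c)}
    for a in members:
        g.add_node(
            a.raw,
            allele=a.raw,
            group=a.group_label,
            is_external=False,
            cluster_id=cluster_id.get(a, -1),
        )
    for a in members:
        cr = classify_cross_reactive(matrix, a)
        scope: Scope = "other_groups" if cr.is_cross_reactive else "own_group"
        for b, d in sorted(nearest_neighbours(matrix, a, scope)):
            if b.raw not in g:
                g.add_node(
                    b.raw,
                    allele=b.raw,
                    group=b.group_label,
                    is_external=True,
                    cluster_id=-1,
                )
            g.add_edge(a.raw, b.raw, distance=int(d), monomorphic=(d == 0))
        g.nodes[a.raw]["is_cross_reactive"] = cr.is_cross_reactive
    return g


def graph_to_json(graph: nx.Graph) -> str:
    """Deterministic JSON adjacency serialization."""
    import json

    data = nx.node_link_data(graph, edges="edges")
    data["nodes"].sort(key=lambda n: n["id"])
    data["edges"].sort(key=lambda e: (e["source"], e["target"]))
    return json.dumps(data, sort_keys=True, indent=1)


def write_graphml(graph: nx.Graph, path) -> None:
    # rebuild with sorted nodes/edges so serialization is byte-deterministic
    h = nx.Graph(**graph.graph)
    for n in sorted(graph.nodes):
        h.add_node(n, **graph.nodes[n])
    for u, v in sorted(graph.edges, key=lambda e: tuple(sorted(e))):
        h.add_edge(*sorted((u, v)), **graph.edges[u, v])
    nx.write_graphml(h, path, named_key_ids=True)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export: distance as edge label (suppressed when 0)."""
    lines = ["graph disparity {"]
    for n in sorted(graph.nodes):
        attrs = graph.nodes[n]
        shape = "box" if attrs.get("is_external") else "ellipse"
        lines.append(f'  "{n}" [shape={shape}, group="{attrs.get("group", "")}"];')
    for u, v in sorted(graph.edges, key=lambda e: tuple(sorted(e))):
        d = graph.edges[u, v]["distance"]
        label = "" if graph.edges[u, v].get("monomorphic") else f' [label="{d}"]'
        a, b = sorted((u, v))
        lines.append(f'  "{a}" -- "{b}"{label};')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
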