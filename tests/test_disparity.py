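"""Hamming distances, nearest-neighbour sets and disparity graphs."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epletatlas import (
    build_disparity_graph,
    classify_cross_reactive,
    distance_matrix,
    graph_to_json,
    hamming_distance,
    monomorphic_clusters,
    namespace_of,
    nearest_neighbours,
    parse_allele_name,
    write_graphml,
)
from epletatlas.atlas import AlleleProfile

from _oracles import oracle_cross_reactive, oracle_distance, oracle_nearest, random_profiles


def _profile(raw, residues):
    return AlleleProfile(
        allele=parse_allele_name(raw),
        residues={p: frozenset(r) for p, r in residues.items()},
    )


@pytest.mark.parametrize(
    "r1, r2, policy, expected",
    [
        ({44: "K"}, {44: "K"}, "difference", 0),
        ({44: "K"}, {44: "R"}, "difference", 1),
        ({44: "K"}, {}, "difference", 1),
        ({44: "K"}, {}, "shared_only", 0),
        ({164: {"S", "G"}}, {164: {"G"}}, "difference", 0),  # overlap is a match
        ({44: "K", 45: "M"}, {44: "K", 46: "D"}, "difference", 2),
    ],
)
def test_hamming_distance_definition(r1, r2, policy, expected):
    p1 = _profile("A*01:01", {p: set(r) for p, r in r1.items()})
    p2 = _profile("A*01:02", {p: set(r) for p, r in r2.items()})
    assert hamming_distance(p1, p2, policy) == expected
    assert hamming_distance(p2, p1, policy) == expected


def test_identical_confirmed_repertoires_have_distance_zero(atlas):
    m = distance_matrix({a: p for a, p in atlas.items() if a.locus == "A"}, "classI")
    assert m.distance(parse_allele_name("A*01:01"), parse_allele_name("A*01:02")) == 0


def test_default_namespace_partition():
    assert namespace_of("A") == namespace_of("C") == "classI"
    assert namespace_of("DRB1") == namespace_of("DRB5") == "DRB"
    assert namespace_of("DQB1") == "DQB1"
    with pytest.raises(ValueError):
        namespace_of("X")


@pytest.mark.parametrize("seed", range(10))
def test_matrix_matches_brute_force_oracle(seed):
    rng = random.Random(seed)
    profiles = random_profiles(rng, n_alleles=15, max_set=2)
    for policy in ("difference", "shared_only"):
        m = distance_matrix(profiles, "classI", policy)
        for a in profiles:
            for b in profiles:
                assert m.distance(a, b) == oracle_distance(profiles[a], profiles[b], policy)


def test_matrix_invariant_under_input_order():
    rng = random.Random(3)
    profiles = random_profiles(rng, n_alleles=10)
    shuffled = dict(reversed(list(profiles.items())))
    m1, m2 = distance_matrix(profiles, "classI"), distance_matrix(shuffled, "classI")
    for a in profiles:
        for b in profiles:
            assert m1.distance(a, b) == m2.distance(a, b)


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("scope", ["all", "own_group", "other_groups"])
def test_nearest_neighbours_match_linear_scan(seed, scope):
    rng = random.Random(seed)
    profiles = random_profiles(rng, n_alleles=20, n_groups=4)
    m = distance_matrix(profiles, "classI")
    for a in profiles:
        assert nearest_neighbours(m, a, scope) == oracle_nearest(profiles, a, scope)


def test_nearest_neighbours_returns_full_argmin_set():
    profiles = {
        p.allele: p
        for p in [
            _profile("A*01:01", {1: "K", 2: "M"}),
            _profile("A*01:02", {1: "K", 2: "R"}),   # d=1 from query
            _profile("A*01:03", {1: "R", 2: "M"}),   # d=1 from query
            _profile("A*01:04", {1: "R", 2: "R", 3: "D"}),  # farther
        ]
    }
    m = distance_matrix(profiles, "classI")
    got = nearest_neighbours(m, parse_allele_name("A*01:01"))
    assert {(a.raw, d) for a, d in got} == {("A*01:02", 1), ("A*01:03", 1)}


def test_singleton_scope_yields_empty_set_not_error():
    profiles = {
        p.allele: p
        for p in [_profile("A*01:01", {1: "K"}), _profile("A*02:01", {1: "R"})]
    }
    m = distance_matrix(profiles, "classI")
    assert nearest_neighbours(m, parse_allele_name("A*01:01"), "own_group") == set()


def test_cross_reactivity_tie_resolves_to_own_group():
    profiles = {
        p.allele: p
        for p in [
            _profile("A*01:01", {1: "K", 2: "M", 3: "A"}),
            _profile("A*01:02", {1: "K", 2: "M", 3: "G"}),  # d_own = 1
            _profile("A*02:01", {1: "K", 2: "R", 3: "A"}),  # d_other = 1
        ]
    }
    m = distance_matrix(profiles, "classI")
    cr = classify_cross_reactive(m, parse_allele_name("A*01:01"))
    assert (cr.is_cross_reactive, cr.d_own, cr.d_other) == (False, 1, 1)


def test_singleton_group_is_trivially_cross_reactive():
    profiles = {
        p.allele: p
        for p in [
            _profile("DPB1*104:01", {1: "K"}),
            _profile("DPB1*105:01", {1: "R", 2: "D"}),
        ]
    }
    m = distance_matrix(profiles, "DPB1")
    cr = classify_cross_reactive(m, parse_allele_name("DPB1*104:01"))
    assert cr.is_cross_reactive and cr.d_own is None


@pytest.mark.parametrize("seed", range(6))
def test_cross_reactive_classification_matches_oracle(seed):
    rng = random.Random(seed)
    profiles = random_profiles(rng, n_alleles=25, n_groups=4)
    m = distance_matrix(profiles, "classI")
    for a in profiles:
        assert classify_cross_reactive(m, a).is_cross_reactive == oracle_cross_reactive(
            profiles, a
        )


@settings(max_examples=150, derandomize=True)
@given(
    st.lists(
        st.dictionaries(
            st.integers(1, 8), st.sampled_from("ACDEFG"), min_size=0, max_size=8
        ),
        min_size=3,
        max_size=3,
    )
)
def test_triangle_inequality_for_singleton_profiles(maps):
    """With one residue per position and the default policy the distance is a
    Hamming distance over an extended gap alphabet, hence a metric."""
    p1, p2, p3 = (
        _profile(f"A*01:{i + 1:02d}", {pos: {r} for pos, r in m.items()})
        for i, m in enumerate(maps)
    )
    d12 = hamming_distance(p1, p2)
    d13 = hamming_distance(p1, p3)
    d23 = hamming_distance(p2, p3)
    assert d12 <= d13 + d23
    assert d13 <= d12 + d23
    assert d23 <= d12 + d13


def test_monomorphic_clusters_and_transitivity():
    profiles = {
        p.allele: p
        for p in [
            _profile("A*01:01", {1: "K"}),
            _profile("A*01:02", {1: "K"}),
            _profile("A*01:03", {1: "K"}),
            _profile("A*01:04", {1: "R"}),
        ]
    }
    m = distance_matrix(profiles, "classI")
    clusters = monomorphic_clusters(m, "A*01")
    assert [sorted(a.raw for a in c) for c in clusters] == [
        ["A*01:01", "A*01:02", "A*01:03"]
    ]
    all_distinct = {
        p.allele: p
        for p in [_profile("A*01:01", {1: "K"}), _profile("A*01:02", {1: "R"})]
    }
    assert monomorphic_clusters(distance_matrix(all_distinct, "classI"), "A*01") == []


def test_disparity_graph_monomorphic_triangle_plus_labelled_edge():
    profiles = {
        p.allele: p
        for p in [
            _profile("A*01:01", {1: "K", 2: "M"}),
            _profile("A*01:02", {1: "K", 2: "M"}),
            _profile("A*01:03", {1: "K", 2: "M"}),
            _profile("A*01:04", {1: "R", 2: "D"}),
        ]
    }
    m = distance_matrix(profiles, "classI")
    g = build_disparity_graph(profiles, m, "A*01")
    zero_edges = [e for e in g.edges(data=True) if e[2]["monomorphic"]]
    assert len(zero_edges) == 3  # triangle over the identical trio
    # the distinct allele is equidistant to all three, so the full argmin
    # set yields three labelled edges
    other = [e for e in g.edges(data=True) if not e[2]["monomorphic"]]
    assert len(other) == 3 and all(e[2]["distance"] == 2 for e in other)
    assert all("A*01:04" in (u, v) for u, v, _ in other)


def test_disparity_graph_adds_external_node_for_planted_cross_reactive():
    profiles = {
        p.allele: p
        for p in [
            _profile("A*01:01", {1: "K", 2: "M", 3: "A", 4: "D"}),
            _profile("A*01:02", {1: "K", 2: "M", 3: "A", 4: "E"}),
            # nearer (d=1) to A*02 core than to own group (d=4)
            _profile("A*01:03", {1: "W", 2: "W", 3: "W", 4: "W", 5: "F"}),
            _profile("A*02:01", {1: "W", 2: "W", 3: "W", 4: "W", 5: "Y"}),
        ]
    }
    m = distance_matrix(profiles, "classI")
    g = build_disparity_graph(profiles, m, "A*01")
    assert g.nodes["A*02:01"]["is_external"]
    assert g.edges["A*01:03", "A*02:01"]["distance"] == 1
    assert g.nodes["A*01:03"]["is_cross_reactive"]
    # group without cross-reactive members gains no external nodes
    g2 = build_disparity_graph(profiles, m, "A*02")
    externals = [n for n, d in g2.nodes(data=True) if d["is_external"]]
    assert externals == ["A*01:03"]  # A*02:01 itself is singleton -> trivially CR


def test_every_in_group_allele_with_neighbours_has_an_edge(atlas):
    m = distance_matrix({a: p for a, p in atlas.items() if a.locus == "A"}, "classI")
    for label in m.groups():
        g = build_disparity_graph(atlas, m, label)
        for n, d in g.nodes(data=True):
            if not d["is_external"]:
                assert g.degree(n) >= 1
        for u, v, d in g.edges(data=True):
            assert d["distance"] == m.distance(parse_allele_name(u), parse_allele_name(v))


def test_graph_serializations_are_deterministic(tmp_path, atlas):
    m = distance_matrix({a: p for a, p in atlas.items() if a.locus == "A"}, "classI")
    g1 = build_disparity_graph(atlas, m, "A*01")
    g2 = build_disparity_graph(atlas, m, "A*01")
    assert graph_to_json(g1) == graph_to_json(g2)
    f1, f2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
    write_graphml(g1, f1)
    write_graphml(g2, f2)
    assert f1.read_bytes() == f2.read_bytes()
    assert nx.utils.graphs_equal(g1, g2)


def test_unknown_group_raises(atlas):
    m = distance_matrix({a: p for a, p in atlas.items() if a.locus == "A"}, "classI")
    with pytest.raises(ValueError):
        build_disparity_graph(atlas, m, "A*99")
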