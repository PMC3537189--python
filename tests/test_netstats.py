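"""Network structural metrics, MCL clustering and domain projection."""

import numpy as np
import pytest

from _oracles import brute_force_metrics
from interolog.domains import DomainAssignment
from interolog.netstats import (
    degree_histogram,
    domain_projection,
    induced_subnetwork,
    mcl_cluster,
    structural_summary,
    top_hubs,
)


def _random_edges(rng, max_nodes=50):
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.02, 0.3))
    edges = set()
    for i in range(n):
        for j in range(i, n):
            if (i == j and rng.random() < 0.05) or (i != j and rng.random() < p):
                edges.add((nodes[i], nodes[j]))
    return edges


def test_triangle_graph():
    s = structural_summary({("a", "b"), ("b", "c"), ("a", "c")})
    assert s.transitivity == pytest.approx(1.0)
    assert s.diameter == 1
    assert s.density == pytest.approx(1.0)
    assert s.n_clusters == 1 and s.n_isolated == 0


def test_path_graph():
    s = structural_summary({("a", "b"), ("b", "c")})
    assert s.transitivity == 0.0
    assert s.diameter == 2
    assert s.mean_degree == pytest.approx(4.0 / 3.0)
    assert s.mean_shortest_path == pytest.approx((1 + 1 + 2) * 2 / 6)


def test_empty_edge_set_gives_zero_summary():
    s = structural_summary(set())
    assert s.n_proteins == 0 and s.diameter == 0 and s.mean_degree == 0.0


def test_self_loops_counted_then_removed():
    s = structural_summary({("a", "a"), ("a", "b"), ("c", "c")})
    assert s.n_self_interactions == 2
    assert s.n_interactions == 3
    assert s.n_isolated == 1  # c has only its self-interaction
    assert s.mean_degree == pytest.approx(2.0 / 3.0)
    # removing self-loops leaves the simple-graph transitivity unchanged
    assert s.transitivity == structural_summary({("a", "b")}).transitivity


def test_summary_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(31)
    for _ in range(25):
        edges = _random_edges(rng)
        s = structural_summary(edges)
        oracle = brute_force_metrics(edges)
        for key, expected in oracle.items():
            assert getattr(s, key) == pytest.approx(expected), key


def test_degree_histogram():
    star = {("hub", f"leaf{i}") for i in range(5)}
    assert degree_histogram(star, bin_width=10) == {0: 6}
    assert degree_histogram(star, bin_width=2) == {0: 5, 4: 1}
    assert degree_histogram(set()) == {}
    with pytest.raises(ValueError):
        degree_histogram(star, bin_width=0)


def test_degree_histogram_matches_brute_counts():
    rng = np.random.default_rng(8)
    edges = _random_edges(rng)
    deg = {}
    for a, b in {tuple(sorted(e)) for e in edges}:
        if a != b:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        else:
            deg.setdefault(a, 0)
    hist = degree_histogram(edges, bin_width=3)
    assert sum(hist.values()) == len(deg)
    for start, count in hist.items():
        assert count == sum(1 for d in deg.values() if start <= d < start + 3)


def test_top_hubs_ranking_and_ties():
    star = {("hub", f"leaf{i}") for i in range(5)}
    assert top_hubs(star, 1) == [("hub", 5)]
    tied = {("a", "x"), ("b", "y")}
    assert top_hubs(tied, 2) == [("a", 1), ("b", 1)]  # lexicographic tie-break
    planted = star | {("big", f"m{i}") for i in range(40)}
    assert top_hubs(planted, 1)[0] == ("big", 40)
    assert len(top_hubs(star, 100)) == 6  # k > N returns all
    with pytest.raises(ValueError):
        top_hubs(star, 0)


def test_induced_subnetwork():
    edges = {("a", "b"), ("b", "c"), ("c", "d"), ("a", "a")}
    sub, notes = induced_subnetwork(edges, ["a", "b", "x"], copy_counts={"a": 3})
    assert sub == {("a", "b"), ("a", "a")}
    assert notes["a"] == 3 and notes["b"] is None
    empty, _ = induced_subnetwork(edges, ["y", "z"])
    assert empty == set()
    with pytest.raises(ValueError):
        induced_subnetwork(edges, [])


def test_induced_subnetwork_hub_degrees_match_brute_counts(world, pipeline_fixed):
    # a curated "meiosis-like" list: images of the first 25 source proteins
    targets = [t for p in world.source_proteins[:25] for t in world.copy_map[p]]
    sub, _ = induced_subnetwork(pipeline_fixed.pall.edges, targets)
    hubs = top_hubs(sub, 5)
    for node, degree in hubs:
        brute = sum(1 for a, b in sub if a != b and node in (a, b))
        assert degree == brute


# ----------------------------------------------------------------------- MCL
def test_mcl_two_disjoint_triangles():
    edges = {("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")}
    clusters = mcl_cluster(edges)
    assert len(clusters) == 2
    assert {frozenset(c) for c in clusters} == {frozenset("abc"), frozenset("xyz")}


def test_mcl_single_edge_and_singletons():
    assert mcl_cluster({("a", "b")}) == [{"a", "b"}]
    clusters = mcl_cluster({("a", "b"), ("c", "c")})
    assert {frozenset(c) for c in clusters} == {frozenset("ab"), frozenset("c")}


def _clique(members):
    return {(a, b) for i, a in enumerate(members) for b in members[i + 1 :]}


def test_mcl_splits_bridged_cliques_at_the_bridge():
    left = [f"l{i}" for i in range(5)]
    right = [f"r{i}" for i in range(5)]
    edges = _clique(left) | _clique(right) | {("l0", "r0")}
    clusters = mcl_cluster(edges, inflation=2.0)
    assert len(clusters) == 2
    assert {frozenset(c) for c in clusters} == {frozenset(left), frozenset(right)}


def test_mcl_output_is_a_partition_and_idempotent_on_cliques():
    rng = np.random.default_rng(12)
    edges = _random_edges(rng, max_nodes=30)
    nodes = {n for e in edges for n in e}
    clusters = mcl_cluster(edges)
    seen = [n for c in clusters for n in c]
    assert sorted(seen) == sorted(nodes)  # every node exactly once
    # re-clustering a clique returns a single cluster
    assert mcl_cluster(_clique([f"c{i}" for i in range(5)])) == [{f"c{i}" for i in range(5)}]
    with pytest.raises(ValueError):
        mcl_cluster(edges, inflation=1.0)


# ----------------------------------------------------------- domain projection
def _asn(protein, domains):
    return DomainAssignment(protein, set(domains), {d: 1e-20 for d in domains})


def test_domain_projection_single_support():
    assignments = {"AHP2": _asn("AHP2", ["PF01627"]), "MND1": _asn("MND1", ["PF03962"])}
    prov = {("PF01627", "PF03962"): {"inferred"}}
    proj = domain_projection({("AHP2", "MND1")}, assignments, prov)
    assert set(proj.edges) == {("PF01627", "PF03962")}
    assert proj.edges[("PF01627", "PF03962")]["evidence"] == {"inferred"}
    assert proj.n_unsupported == 0


def test_domain_projection_empty_ddis_and_self_flags():
    assignments = {"P": _asn("P", ["dS"]), "Q": _asn("Q", ["dS", "dT"])}
    assert domain_projection({("P", "Q")}, assignments, {}).edges == {}
    proj = domain_projection({("P", "Q")}, assignments, {("dS", "dS"): {"known"}})
    assert "dS" in proj.self_interacting


def test_domain_projection_matches_brute_force_join(world, pipeline_fixed):
    prov = {p: {"known"} for p in world.true_ddis}
    edges = set(list(pipeline_fixed.pall.edges)[:200])
    proj = domain_projection(edges, world.target_assignments, prov)
    brute = {}
    unsupported = 0
    for p, q in edges:
        dp = world.target_assignments.get(p)
        dq = world.target_assignments.get(q)
        if dp is None or dq is None:
            unsupported += 1
            continue
        support = {
            tuple(sorted((a, b))) for a in dp.domains for b in dq.domains
        } & world.true_ddis
        if not support:
            unsupported += 1
        for s in support:
            brute.setdefault(s, []).append(tuple(sorted((p, q))))
    assert set(proj.edges) == set(brute)
    assert proj.n_unsupported == unsupported
    for pair, plist in brute.items():
        assert sorted(proj.edges[pair]["protein_edges"]) == sorted(plist)
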