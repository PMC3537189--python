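"""Structural analysis of prediction networks.

Summary metrics follow the usual interactome-topology conventions:
self-interactions are counted, then removed before any structural metric;
distances are computed within connected components; "protein clusters" are
components with at least two nodes (isolated proteins are reported
separately); degree centralization is Freeman's index normalized by the
star-graph maximum.  Also provides degree histograms, hub ranking, induced
sub-networks (e.g. a meiosis gene set), Markov clustering (MCL), and the
projection of a protein sub-network onto its supporting domain pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .util import canonical_pair


@dataclass
class NetworkSummary:
    n_proteins: int = 0
    n_interactions: int = 0
    n_isolated: int = 0
    n_self_interactions: int = 0
    n_clusters: int = 0
    diameter: int = 0
    mean_degree: float = 0.0
    mean_shortest_path: float = 0.0
    transitivity: float = 0.0
    centralization: float = 0.0
    density: float = 0.0
    density_with_self: float = 0.0


def _simple_graph(edges):
    """Canonical edge set -> (nx.Graph without self-loops, n_self, n_edges_input)."""
    pairs = {canonical_pair(a, b) for a, b in edges}
    G = nx.Graph()
    n_self = 0
    for a, b in pairs:
        if a == b:
            n_self += 1
            G.add_node(a)
        else:
            G.add_edge(a, b)
    return G, n_self, len(pairs)


def structural_summary(edges) -> NetworkSummary:
    """Structural profile of an undirected interaction network.

    Self-loops are counted, then removed; every metric below refers to the
    resulting simple graph.  An empty edge set yields an all-zero summary.
    """
    G, n_self, n_input = _simple_graph(edges)
    n = G.number_of_nodes()
    if n == 0:
        return NetworkSummary()
    m = G.number_of_edges()
    degrees = dict(G.degree())
    comps = list(nx.connected_components(G))
    diameter = 0
    path_sum, path_cnt = 0, 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for node, dists in nx.all_pairs_shortest_path_length(sub):
            for other, d in dists.items():
                if other != node:
                    path_sum += d
                    path_cnt += 1
                    diameter = max(diameter, d)
    dmax = max(degrees.values())
    centralization = (
        sum(dmax - d for d in degrees.values()) / ((n - 1) * (n - 2)) if n > 2 else 0.0
    )
    return NetworkSummary(
        n_proteins=n,
        n_interactions=n_input,
        n_isolated=sum(1 for d in degrees.values() if d == 0),
        n_self_interactions=n_self,
        n_clusters=sum(1 for c in comps if len(c) >= 2),
        diameter=diameter,
        mean_degree=2.0 * m / n,
        mean_shortest_path=path_sum / path_cnt if path_cnt else 0.0,
        transitivity=nx.transitivity(G),
        centralization=centralization,
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        density_with_self=2.0 * (m + n_self) / (n * (n - 1)) if n > 1 else 0.0,
    )


def degree_histogram(edges, bin_width: int = 10) -> dict:
    """Per-node simple-graph degrees binned as [0,w), [w,2w), ...

    Returns ``{bin_start: count}`` for nonempty bins.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    G, _, _ = _simple_graph(edges)
    hist: dict = {}
    for _, d in G.degree():
        start = (d // bin_width) * bin_width
        hist[start] = hist.get(start, 0) + 1
    return dict(sorted(hist.items()))


def top_hubs(edges, k: int) -> list:
    """The k highest-degree proteins (self-loops excluded), ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    G, _, _ = _simple_graph(edges)
    ranked = sorted(G.degree(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def induced_subnetwork(pall, protein_list, copy_counts=None):
    """Edges of the sub-network induced by ``protein_list``.

    Returns ``(edge set, annotations)`` where annotations carry, per node
    present in the sub-network, the number of target-species copies of its
    source counterpart (from ``copy_counts``, if given).
    """
    keep = set(protein_list)
    if not keep:
        raise ValueError("protein list must be nonempty")
    edges = pall.edges if hasattr(pall, "edges") else pall
    sub = {canonical_pair(a, b) for a, b in edges if a in keep and b in keep}
    nodes = {n for e in sub for n in e}
    annotations = {n: (copy_counts or {}).get(n) for n in nodes}
    return sub, annotations


def mcl_cluster(
    edges,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune_threshold: float = 1e-5,
) -> list:
    """Markov clustering of an undirected graph.

    Alternates expansion (matrix squaring) and inflation (entrywise power
    + column renormalization) on the column-stochastic adjacency matrix
    (self-loops added with weight 1), pruning entries below
    ``prune_threshold``, until the matrix change falls below 1e-8 or
    ``max_iter``.  Clusters are read from attractor rows; every node is
    assigned to exactly one cluster (ties to the lowest-id attractor).
    Disconnected singletons form singleton clusters.  Returns a list of
    node sets.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    G, _, _ = _simple_graph(edges)
    nodes = sorted(G.nodes())
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.eye(n)
    for a, b in G.edges():
        M[idx[a], idx[b]] = 1.0
        M[idx[b], idx[a]] = 1.0
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < 1e-8:
            break
    attractors = [i for i in range(n) if M[i, i] > 0]
    assignment: dict = {}
    for j in range(n):
        owners = [i for i in attractors if M[i, j] > 0]
        assignment[j] = min(owners) if owners else j
    clusters: dict = {}
    for j, owner in assignment.items():
        clusters.setdefault(owner, set()).add(nodes[j])
    return sorted(clusters.values(), key=lambda c: min(c))


@dataclass
class DomainProjection:
    edges: dict  # canonical domain pair -> {"evidence": set, "protein_edges": list}
    self_interacting: set = field(default_factory=set)
    n_unsupported: int = 0


def domain_projection(subnetwork_edges, assignments, ddi_provenance) -> DomainProjection:
    """Project a protein sub-network onto its supporting domain interactions.

    For each protein edge, its candidate domain pairs are intersected with
    the DDI set; supporting pairs become domain-level edges labelled by
    their evidence origin (e.g. known vs inferred).  Self-interacting
    domains are flagged; protein edges with no supporting domain pair are
    omitted and tallied.
    """
    prov = (
        ddi_provenance.provenance
        if hasattr(ddi_provenance, "provenance")
        else dict(ddi_provenance)
    )
    ddi_pairs = set(prov)
    out: dict = {}
    self_flags: set = set()
    n_unsupported = 0
    for p, q in subnetwork_edges:
        ap, aq = assignments.get(p), assignments.get(q)
        if ap is None or aq is None:
            n_unsupported += 1
            continue
        support = {canonical_pair(a, b) for a in ap.domains for b in aq.domains} & ddi_pairs
        if not support:
            n_unsupported += 1
            continue
        for dpair in support:
            entry = out.setdefault(dpair, {"evidence": set(), "protein_edges": []})
            entry["evidence"] |= set(prov.get(dpair, set()))
            entry["protein_edges"].append(canonical_pair(p, q))
            if dpair[0] == dpair[1]:
                self_flags.add(dpair[0])
    return DomainProjection(out, self_flags, n_unsupported)
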