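"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, double
loops, all-pairs BFS) and shares no code with the implementation paths it
checks.
"""

import itertools
from collections import deque

import numpy as np

from interolog.bp import Factor, FactorGraph, factor_value


# ---------------------------------------------------------------- factor graphs
def enumerate_marginals_and_logz(graph, params):
    """Exact marginals and -ln Z by summing over all 2^n configurations."""
    n = graph.n_vars
    Z = 0.0
    marg = np.zeros(n)
    for xs in itertools.product((0, 1), repeat=n):
        w = 1.0
        for i, x in enumerate(xs):
            w *= params.beta if x else 1.0 - params.beta
        for f in graph.factors:
            w *= factor_value(f.positive, [xs[v] for v in f.vars], params.epsilon)
        Z += w
        for i, x in enumerate(xs):
            if x:
                marg[i] += w
    return marg / Z, -np.log(Z)


def generic_sumproduct_message(factor_positive, epsilon, incoming, target):
    """Factor-to-variable message by explicit configuration sum.

    ``incoming`` is the list of P(x_j = 1) for every incident variable;
    ``target`` indexes the variable the message goes to.  Returns the
    normalized message as (m0, m1).
    """
    k = len(incoming)
    m = [0.0, 0.0]
    for xs in itertools.product((0, 1), repeat=k):
        w = 1.0
        for j, x in enumerate(xs):
            if j == target:
                continue
            w *= incoming[j] if x else 1.0 - incoming[j]
        m[xs[target]] += w * factor_value(factor_positive, xs, epsilon)
    s = m[0] + m[1]
    return m[0] / s, m[1] / s


def random_acyclic_graph(rng, max_vars=12):
    """Random tree-structured factor graph (variables named by index)."""
    n_vars = int(rng.integers(1, max_vars + 1))
    variables = [(f"D{i:03d}", f"E{i:03d}") for i in range(n_vars)]
    factors = []
    used = [0]
    i = 1
    while i < n_vars:
        k = min(int(rng.integers(1, 4)), n_vars - i)
        anchor = int(rng.choice(used))
        factors.append(
            Factor(("p", "q"), bool(rng.integers(2)), (anchor,) + tuple(range(i, i + k)))
        )
        used.extend(range(i, i + k))
        i += k
    if not factors:
        factors.append(Factor(("p", "q"), bool(rng.integers(2)), (0,)))
    return FactorGraph(variables, factors)


def random_loopy_graph(rng, max_vars=12):
    """Random factor graph with cycles (factors over random variable subsets)."""
    n_vars = int(rng.integers(3, max_vars + 1))
    variables = [(f"D{i:03d}", f"E{i:03d}") for i in range(n_vars)]
    n_factors = int(rng.integers(n_vars, 2 * n_vars))
    factors = []
    for _ in range(n_factors):
        k = int(rng.integers(1, min(4, n_vars) + 1))
        vs = tuple(sorted(int(v) for v in rng.choice(n_vars, size=k, replace=False)))
        factors.append(Factor(("p", "q"), bool(rng.integers(2)), vs))
    covered = {v for f in factors for v in f.vars}
    for v in range(n_vars):
        if v not in covered:
            factors.append(Factor(("p", "q"), True, (v,)))
    return FactorGraph(variables, factors)


# ---------------------------------------------------------------- graph metrics
def brute_force_metrics(edges):
    """All network-summary metrics by explicit loops (no networkx)."""
    pairs = {tuple(sorted(e)) for e in edges}
    self_loops = {e for e in pairs if e[0] == e[1]}
    simple = pairs - self_loops
    nodes = sorted({n for e in pairs for n in e})
    adj = {n: set() for n in nodes}
    for a, b in simple:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    m = len(simple)
    deg = {v: len(adj[v]) for v in nodes}

    # components via BFS
    comp_of = {}
    comps = []
    for v in nodes:
        if v in comp_of:
            continue
        comp = {v}
        q = deque([v])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in comp:
                    comp.add(w)
                    q.append(w)
        for u in comp:
            comp_of[u] = len(comps)
        comps.append(comp)

    # all-pairs BFS distances within components
    diameter = 0
    path_sum = 0
    path_cnt = 0
    for v in nodes:
        dist = {v: 0}
        q = deque([v])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        for u, d in dist.items():
            if u != v:
                diameter = max(diameter, d)
                path_sum += d
                path_cnt += 1

    # triangles and connected triples
    triangles = 0
    triples = 0
    for v in nodes:
        k = deg[v]
        triples += k * (k - 1) // 2
        neigh = sorted(adj[v])
        for i, a in enumerate(neigh):
            for b in neigh[i + 1 :]:
                if b in adj[a]:
                    triangles += 1
    triangles //= 3
    transitivity = 3.0 * triangles / triples if triples else 0.0

    dmax = max(deg.values()) if deg else 0
    centralization = (
        sum(dmax - d for d in deg.values()) / ((n - 1) * (n - 2)) if n > 2 else 0.0
    )
    return {
        "n_proteins": n,
        "n_interactions": len(pairs),
        "n_isolated": sum(1 for v in nodes if deg[v] == 0),
        "n_self_interactions": len(self_loops),
        "n_clusters": sum(1 for c in comps if len(c) >= 2),
        "diameter": diameter,
        "mean_degree": 2.0 * m / n if n else 0.0,
        "mean_shortest_path": path_sum / path_cnt if path_cnt else 0.0,
        "transitivity": transitivity,
        "centralization": centralization,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
    }


def brute_force_transfer(pairs, bridge_links):
    """Interolog transfer by explicit double loop over bridged copies."""
    targets = {}
    for s, t in bridge_links:
        targets.setdefault(s, set()).add(t)
    out = set()
    for a1, a2 in pairs:
        t1, t2 = targets.get(a1, set()), targets.get(a2, set())
        if not t1 or not t2:
            continue
        for b1 in t1:
            for b2 in t2:
                if a1 == a2 and b2 < b1:
                    continue  # unordered pairs with replacement among copies
                out.add(tuple(sorted((b1, b2))))
    return out
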