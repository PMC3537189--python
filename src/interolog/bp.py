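"""Factor-graph belief propagation for domain-domain interaction inference.

The model: each candidate domain pair d carries a binary variable x_d
(interacting or not) with prior P(x_d = 1) = beta.  Each training protein
pair is a function node over its candidate domain pairs.  An interacting
pair requires at least one of its candidates to interact; a non-interacting
pair requires none to.  Both constraints are softened by a single
reliability parameter epsilon, as an observation channel on the OR of the
incident variables:

    f+(x) = (1 - (1 - eps) * prod_d (1 - x_d)) / (1 + eps)
    f-(x) = (eps + (1 - eps) * prod_d (1 - x_d)) / (1 + eps)

With OR(x) = 1 the positive factor takes value 1/(1+eps) and the negative
factor eps/(1+eps), and symmetrically for OR(x) = 0: the label is flipped
with probability eps/(1+eps), and eps = 0 recovers the hard constraints.
The 1/(1+eps) normalization (f+ + f- = 1 for every configuration) does not
affect messages or beliefs, but it is what gives the Bethe free energy an
interior minimum in epsilon, making the parameter estimable by grid search.

Sum-product messages for these OR factors have a closed form, so an
iteration costs O(edges) regardless of factor degree; the Bethe free energy
enumerates factor configurations exactly and therefore caps factor degree.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class ModelParams:
    """epsilon: data-reliability/error parameter; beta: prior DDI probability."""

    epsilon: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must lie in [0, 1)")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")


@dataclass
class Factor:
    proteins: tuple  # canonical protein pair
    positive: bool
    vars: tuple  # indices into FactorGraph.variables


@dataclass
class FactorGraph:
    variables: list  # index -> canonical domain pair
    factors: list  # Factor
    var_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.var_index:
            self.var_index = {v: i for i, v in enumerate(self.variables)}

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def var_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vars, dtype=int)
        for f in self.factors:
            for v in f.vars:
                deg[v] += 1
        return deg

    def edge_arrays(self):
        """Flat (var_idx, factor_idx, factor_sign) arrays, one entry per edge."""
        ev, ef, pos = [], [], []
        for fi, f in enumerate(self.factors):
            for v in f.vars:
                ev.append(v)
                ef.append(fi)
                pos.append(f.positive)
        return (
            np.asarray(ev, dtype=np.intp),
            np.asarray(ef, dtype=np.intp),
            np.asarray(pos, dtype=bool),
        )


def factor_value(positive: bool, xs, epsilon: float) -> float:
    """Normalized soft-OR factor value for a 0/1 configuration ``xs``."""
    prod = 1.0
    for x in xs:
        prod *= 1.0 - x
    raw = 1.0 - (1.0 - epsilon) * prod if positive else epsilon + (1.0 - epsilon) * prod
    return raw / (1.0 + epsilon)


def build_factor_graph(positives, negatives, assignments, degree_cap: int = 16):
    """Construct the bipartite factor graph from signed training protein pairs.

    One variable per distinct candidate domain pair across all training
    pairs; one signed factor per training pair, incident to its candidates.
    Training pairs with zero candidates (unannotated partner) are excluded
    and tallied.  Factors whose candidate count exceeds ``degree_cap`` are
    pruned to the ``degree_cap`` candidates with the smallest combined
    assignment e-values (the Bethe free energy enumerates factor
    configurations exactly and needs bounded degree).

    Returns ``(FactorGraph, n_excluded)``.
    """
    variables: list = []
    var_index: dict = {}
    factors: list = []
    n_excluded = 0

    def _candidates(p, q):
        ap, aq = assignments.get(p), assignments.get(q)
        if ap is None or aq is None or not ap.domains or not aq.domains:
            return None
        return sorted({canonical_pair(a, b) for a in ap.domains for b in aq.domains})

    def _prune(cands, p, q):
        if len(cands) <= degree_cap:
            return cands
        ep = assignments[p].best_evalues
        eq = assignments[q].best_evalues
        ev = lambda d: min(ep.get(d, 0.0), eq.get(d, 0.0))  # noqa: E731
        ranked = sorted(cands, key=lambda pr: (ev(pr[0]) + ev(pr[1]), pr))
        warnings.warn(
            f"factor ({p}, {q}) has {len(cands)} candidate domain pairs; "
            f"pruned to {degree_cap}",
            stacklevel=3,
        )
        return sorted(ranked[:degree_cap])

    for sign, pairs in ((True, positives), (False, negatives)):
        for p, q in pairs:
            cands = _candidates(p, q)
            if not cands:
                n_excluded += 1
                continue
            cands = _prune(cands, p, q)
            idxs = []
            for pair in cands:
                if pair not in var_index:
                    var_index[pair] = len(variables)
                    variables.append(pair)
                idxs.append(var_index[pair])
            factors.append(Factor(canonical_pair(p, q), sign, tuple(idxs)))
    if not factors:
        raise ValueError("empty training set: no usable positive or negative pairs")
    return FactorGraph(variables, factors, var_index), n_excluded


@dataclass
class BeliefState:
    beliefs: np.ndarray  # P(x_d = 1) per variable
    converged: bool
    iterations: int
    # per-edge messages (probability of x = 1), aligned with edge_arrays()
    msg_f2v: np.ndarray
    msg_v2f: np.ndarray


def _loo_logsum(vals: np.ndarray, group: np.ndarray, n_groups: int, base: np.ndarray | float):
    """Leave-one-out group sums of log-values that may contain -inf.

    For edge e in group g, returns base[g] + sum of vals over the other
    edges of g, with -inf handled exactly (a single -inf elsewhere forces
    the LOO sum to -inf).
    """
    finite = np.isfinite(vals)
    safe = np.where(finite, vals, 0.0)
    fin_sum = np.zeros(n_groups)
    np.add.at(fin_sum, group, safe)
    ninf = np.zeros(n_groups, dtype=int)
    np.add.at(ninf, group, (~finite).astype(int))
    base = np.broadcast_to(np.asarray(base, dtype=float), (n_groups,))
    out = base[group] + fin_sum[group] - safe
    others_inf = np.where(finite, ninf[group] > 0, ninf[group] > 1)
    out = np.where(others_inf, -np.inf, out)
    return out


def run_bp(
    graph: FactorGraph,
    params: ModelParams,
    max_iter: int = 500,
    tol: float = 1e-6,
    damping: float = 0.5,
) -> BeliefState:
    """Sum-product fixed-point iteration with a synchronous (flooded) schedule.

    Messages are two-valued distributions stored as the probability of
    x = 1; they start uniform and are damped (``new = (1-damping)*update +
    damping*old``).  Iteration stops when the largest absolute message
    change falls below ``tol`` or after ``max_iter`` sweeps; beliefs are
    returned either way with a convergence flag.
    """
    eps, beta = params.epsilon, params.beta
    ev, ef, pos = graph.edge_arrays()
    n_e, n_v, n_f = len(ev), graph.n_vars, len(graph.factors)
    mu = np.full(n_e, 0.5)  # factor -> variable
    nu = np.full(n_e, 0.5)  # variable -> factor
    log_b1, log_b0 = np.log(beta), np.log1p(-beta)

    converged = False
    it = 0
    with np.errstate(divide="ignore"):
        for it in range(1, max_iter + 1):
            # variable -> factor: prior x product of other incoming factor messages
            s1 = _loo_logsum(np.log(mu), ev, n_v, log_b1)
            s0 = _loo_logsum(np.log1p(-mu), ev, n_v, log_b0)
            with np.errstate(invalid="ignore"):
                norm = np.logaddexp(s1, s0)
                nu_new = np.exp(s1 - norm)
            nu_new = np.where(np.isnan(nu_new), 0.5, nu_new)

            # factor -> variable: closed-form OR-factor messages
            lo = _loo_logsum(np.log1p(-nu_new), ef, n_f, 0.0)
            prod = np.exp(lo)  # prod_{j != i} (1 - nu_j)
            mu_new = np.where(
                pos,
                1.0 / (2.0 - (1.0 - eps) * prod),
                np.divide(
                    eps,
                    2.0 * eps + (1.0 - eps) * prod,
                    out=np.zeros_like(prod),
                    where=(2.0 * eps + (1.0 - eps) * prod) > 0,
                ),
            )

            if not (np.all(np.isfinite(mu_new)) and np.all(np.isfinite(nu_new))):
                bad = int(np.flatnonzero(~np.isfinite(mu_new) | ~np.isfinite(nu_new))[0])
                raise FloatingPointError(
                    f"non-finite message on edge {bad} "
                    f"(variable {graph.variables[ev[bad]]}, factor {graph.factors[ef[bad]].proteins})"
                )

            mu_upd = damping * mu + (1.0 - damping) * mu_new
            nu_upd = damping * nu + (1.0 - damping) * nu_new
            delta = max(
                np.max(np.abs(mu_upd - mu), initial=0.0),
                np.max(np.abs(nu_upd - nu), initial=0.0),
            )
            mu, nu = mu_upd, nu_upd
            if delta < tol:
                converged = True
                break

        b1 = np.full(n_v, log_b1)
        b0 = np.full(n_v, log_b0)
        np.add.at(b1, ev, np.log(mu))
        np.add.at(b0, ev, np.log1p(-mu))
        with np.errstate(invalid="ignore"):
            beliefs = np.exp(b1 - np.logaddexp(b1, b0))
        beliefs = np.where(np.isnan(beliefs), 0.5, beliefs)

    return BeliefState(beliefs, converged, it, mu, nu)


def bethe_free_energy(
    graph: FactorGraph, state: BeliefState, params: ModelParams, degree_cap: int = 16
) -> float:
    """Bethe free energy of a belief-propagation state.

    F = sum_a sum_x b_a(x) ln(b_a(x)/f_a(x))
      + sum_i sum_x b_i(x) ln(b_i(x)/phi_i(x))
      - sum_i deg(i) * sum_x b_i(x) ln b_i(x)

    where phi_i is the Bernoulli(beta) prior (treated as a unary factor, so
    variable counting degrees include it) and factor beliefs are computed
    exactly from the incoming variable messages.  On acyclic graphs at a BP
    fixed point this equals -ln Z.  Factors above ``degree_cap`` raise.
    """
    eps, beta = params.epsilon, params.beta
    b = np.clip(state.beliefs, 0.0, 1.0)

    def _xlogx(p):
        return float(np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)))

    # variable terms: prior-factor KL + degree correction
    deg = graph.var_degrees()
    F = 0.0
    for i in range(graph.n_vars):
        bi = np.array([1.0 - b[i], b[i]])
        phi = np.array([1.0 - beta, beta])
        F += _xlogx(bi) - float(np.sum(np.where(bi > 0, bi * np.log(phi), 0.0)))
        F -= deg[i] * _xlogx(bi)

    # factor terms, with incoming messages grouped per factor
    ev, ef, pos = graph.edge_arrays()
    nu_by_factor: dict = {}
    for e in range(len(ev)):
        nu_by_factor.setdefault(ef[e], []).append(state.msg_v2f[e])
    for fi, f in enumerate(graph.factors):
        k = len(f.vars)
        if k > degree_cap:
            raise ValueError(
                f"factor {f.proteins} has degree {k} > cap {degree_cap}; "
                "prune candidates at graph construction"
            )
        nus = nu_by_factor[fi]
        weights = np.empty(2**k)
        fvals = np.empty(2**k)
        for ci, xs in enumerate(itertools.product((0, 1), repeat=k)):
            w = 1.0
            for x, p in zip(xs, nus):
                w *= p if x else (1.0 - p)
            weights[ci] = w
            fvals[ci] = factor_value(f.positive, xs, eps)
        ba = weights * fvals
        z = ba.sum()
        if z <= 0:
            raise FloatingPointError(f"degenerate factor belief at {f.proteins}")
        ba /= z
        mask = ba > 0
        F += float(np.sum(ba[mask] * (np.log(ba[mask]) - np.log(fvals[mask]))))
    return F


@dataclass
class FitResult:
    best: ModelParams
    surface: pd.DataFrame  # columns: beta, epsilon, free_energy, converged, iterations


def fit_parameters(
    graph: FactorGraph,
    beta_grid,
    epsilon_grid,
    max_iter: int = 500,
    tol: float = 1e-6,
    damping: float = 0.5,
    degree_cap: int = 16,
) -> FitResult:
    """Grid search (beta, epsilon) by minimizing the Bethe free energy.

    Runs BP to a fixed point at every grid point and evaluates the free
    energy there; non-converged points are recorded in the surface but
    excluded from the argmin, with a warning.
    """
    beta_grid, epsilon_grid = list(beta_grid), list(epsilon_grid)
    if not beta_grid or not epsilon_grid:
        raise ValueError("parameter grids must be nonempty")
    rows = []
    best: tuple | None = None
    for beta in beta_grid:
        for eps in epsilon_grid:
            params = ModelParams(epsilon=eps, beta=beta)
            state = run_bp(graph, params, max_iter=max_iter, tol=tol, damping=damping)
            F = bethe_free_energy(graph, state, params, degree_cap=degree_cap)
            rows.append(
                {
                    "beta": beta,
                    "epsilon": eps,
                    "free_energy": F,
                    "converged": state.converged,
                    "iterations": state.iterations,
                }
            )
            if not state.converged:
                warnings.warn(
                    f"BP did not converge at beta={beta}, epsilon={eps}; "
                    "point excluded from argmin",
                    stacklevel=2,
                )
                continue
            if best is None or F < best[0]:
                best = (F, params)
    if best is None:
        raise RuntimeError("no grid point converged; cannot select parameters")
    return FitResult(best[1], pd.DataFrame(rows))


def sole_pair_lower_bound(params: ModelParams) -> float:
    """Belief lower bound for the only candidate of a positive pair with no
    negative evidence: beta / (beta + (1 - beta) * epsilon)."""
    return params.beta / (params.beta + (1.0 - params.beta) * params.epsilon)


@dataclass
class SelectionResult:
    selected: set  # canonical domain pairs with belief >= cutoff
    beliefs: dict  # domain pair -> belief
    overlap_d4: int
    sole_pairs: set  # selected pairs that are the only candidate of >= 1 positive pair


def select_ddis(graph: FactorGraph, state: BeliefState, cutoff: float, d4) -> SelectionResult:
    """Select high-confidence DDIs at a belief cutoff.

    Also reports the overlap with the known set D4 and the "sole pair"
    subset: selected pairs that are the only candidate domain pair of at
    least one positive training pair.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    beliefs = {pair: float(state.beliefs[i]) for i, pair in enumerate(graph.variables)}
    selected = {pair for pair, p in beliefs.items() if p >= cutoff}
    d4_pairs = d4.pairs if hasattr(d4, "pairs") else set(d4)
    sole = set()
    for f in graph.factors:
        if f.positive and len(f.vars) == 1:
            pair = graph.variables[f.vars[0]]
            if pair in selected:
                sole.add(pair)
    return SelectionResult(selected, beliefs, len(selected & d4_pairs), sole)
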