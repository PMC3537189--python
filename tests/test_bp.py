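"""Belief propagation: messages, beliefs, Bethe free energy, fitting, selection."""

import numpy as np
import pytest

from _oracles import (
    enumerate_marginals_and_logz,
    generic_sumproduct_message,
    random_acyclic_graph,
    random_loopy_graph,
)
from interolog.bp import (
    Factor,
    FactorGraph,
    ModelParams,
    bethe_free_energy,
    build_factor_graph,
    factor_value,
    fit_parameters,
    run_bp,
    select_ddis,
    sole_pair_lower_bound,
)
from interolog.domains import DomainAssignment, KnownDDISet

TIGHT = dict(max_iter=3000, tol=1e-13)


def _graph(*factors, n_vars):
    variables = [(f"D{i:03d}", f"E{i:03d}") for i in range(n_vars)]
    return FactorGraph(variables, list(factors))


def _asn(protein, domains):
    return DomainAssignment(protein, set(domains), {d: 1e-20 for d in domains})


# ------------------------------------------------------------------- messages
def test_closed_form_messages_agree_with_generic_sum_product():
    """The O(1) OR-factor messages must equal the explicit configuration sum."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        k = int(rng.integers(1, 6))
        eps = float(rng.uniform(0.0, 0.5))
        positive = bool(rng.integers(2))
        incoming = rng.uniform(0.0, 1.0, size=k)
        target = int(rng.integers(k))
        m0, m1 = generic_sumproduct_message(positive, eps, list(incoming), target)
        prod = np.prod([1.0 - p for j, p in enumerate(incoming) if j != target])
        if positive:
            r1, r0 = 1.0, 1.0 - (1.0 - eps) * prod
        else:
            r1, r0 = eps, eps + (1.0 - eps) * prod
        s = r0 + r1
        assert m0 == pytest.approx(r0 / s, abs=1e-12)
        assert m1 == pytest.approx(r1 / s, abs=1e-12)


def test_factor_values_form_a_channel():
    # positive + negative factor values sum to 1 for every configuration
    rng = np.random.default_rng(0)
    for _ in range(50):
        k = int(rng.integers(1, 5))
        xs = rng.integers(0, 2, size=k)
        eps = float(rng.uniform(0, 0.9))
        assert factor_value(True, xs, eps) + factor_value(False, xs, eps) == pytest.approx(1.0)


# ------------------------------------------------------- exactness on trees
def test_bp_beliefs_exact_on_random_acyclic_graphs():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        graph = random_acyclic_graph(rng)
        params = ModelParams(
            epsilon=float(rng.uniform(0.005, 0.3)), beta=float(rng.uniform(0.05, 0.9))
        )
        state = run_bp(graph, params, **TIGHT)
        assert state.converged
        marg, _ = enumerate_marginals_and_logz(graph, params)
        np.testing.assert_allclose(state.beliefs, marg, atol=1e-8)


def test_bethe_equals_minus_log_z_on_acyclic_graphs():
    rng = np.random.default_rng(99)
    for _ in range(50):
        graph = random_acyclic_graph(rng)
        params = ModelParams(
            epsilon=float(rng.uniform(0.005, 0.3)), beta=float(rng.uniform(0.05, 0.9))
        )
        state = run_bp(graph, params, **TIGHT)
        _, neg_log_z = enumerate_marginals_and_logz(graph, params)
        assert bethe_free_energy(graph, state, params) == pytest.approx(neg_log_z, abs=1e-8)


def test_bethe_single_variable_closed_form():
    # one positive sole-pair factor, beta=0.5, eps=0: Z = beta, F = -ln 0.5
    graph = _graph(Factor(("p", "q"), True, (0,)), n_vars=1)
    params = ModelParams(epsilon=0.0, beta=0.5)
    state = run_bp(graph, params, **TIGHT)
    assert bethe_free_energy(graph, state, params) == pytest.approx(np.log(2.0), abs=1e-10)


def test_bethe_additive_over_disjoint_components():
    graph1 = _graph(
        Factor(("p", "q"), True, (0, 1)), Factor(("r", "s"), False, (1, 2)), n_vars=3
    )
    doubled = _graph(
        Factor(("p", "q"), True, (0, 1)),
        Factor(("r", "s"), False, (1, 2)),
        Factor(("p2", "q2"), True, (3, 4)),
        Factor(("r2", "s2"), False, (4, 5)),
        n_vars=6,
    )
    params = ModelParams(epsilon=0.05, beta=0.3)
    f1 = bethe_free_energy(graph1, run_bp(graph1, params, **TIGHT), params)
    f2 = bethe_free_energy(doubled, run_bp(doubled, params, **TIGHT), params)
    assert f2 == pytest.approx(2.0 * f1, abs=1e-9)


def test_bethe_rejects_factors_over_degree_cap():
    graph = _graph(Factor(("p", "q"), True, tuple(range(5))), n_vars=5)
    params = ModelParams(epsilon=0.02, beta=0.2)
    state = run_bp(graph, params)
    with pytest.raises(ValueError, match="degree"):
        bethe_free_energy(graph, state, params, degree_cap=4)


# -------------------------------------------------------------- loopy graphs
def test_loopy_beliefs_close_to_exact_marginals():
    """On small loopy graphs, converged beliefs stay within 0.05 of the exact
    marginals for >= 90% of variables (regression property, fixed seed)."""
    rng = np.random.default_rng(2024)
    n_good, n_total = 0, 0
    for _ in range(30):
        graph = random_loopy_graph(rng)
        params = ModelParams(
            epsilon=float(rng.uniform(0.01, 0.2)), beta=float(rng.uniform(0.1, 0.5))
        )
        state = run_bp(graph, params, max_iter=2000, tol=1e-10)
        if not state.converged:
            continue
        marg, _ = enumerate_marginals_and_logz(graph, params)
        n_good += int(np.sum(np.abs(state.beliefs - marg) <= 0.05))
        n_total += graph.n_vars
    assert n_total > 0
    assert n_good / n_total >= 0.90


# ------------------------------------------------------ closed-form posteriors
def test_single_positive_sole_pair_posterior():
    graph = _graph(Factor(("p", "q"), True, (0,)), n_vars=1)
    state = run_bp(graph, ModelParams(epsilon=0.02, beta=0.2), **TIGHT)
    expected = 0.2 / (0.2 + 0.8 * 0.02)
    assert state.beliefs[0] == pytest.approx(expected, abs=1e-9)
    assert state.beliefs[0] == pytest.approx(0.9259, abs=1e-4)


def test_single_negative_sole_pair_posterior():
    graph = _graph(Factor(("p", "q"), False, (0,)), n_vars=1)
    state = run_bp(graph, ModelParams(epsilon=0.02, beta=0.2), **TIGHT)
    expected = (0.2 * 0.02) / (0.2 * 0.02 + 0.8)
    assert state.beliefs[0] == pytest.approx(expected, abs=1e-9)
    assert state.beliefs[0] == pytest.approx(0.00498, abs=1e-5)


def test_hard_positive_constraint_forces_belief_one():
    graph = _graph(Factor(("p", "q"), True, (0,)), n_vars=1)
    for beta in (0.1, 0.5, 0.9):
        state = run_bp(graph, ModelParams(epsilon=0.0, beta=beta), **TIGHT)
        assert state.beliefs[0] == pytest.approx(1.0, abs=1e-9)


def test_beliefs_monotone_in_beta_on_single_factor_graphs():
    graph = _graph(Factor(("p", "q"), True, (0, 1)), n_vars=2)
    prev = -1.0
    for beta in np.linspace(0.05, 0.9, 10):
        state = run_bp(graph, ModelParams(epsilon=0.05, beta=float(beta)), **TIGHT)
        assert state.beliefs[0] > prev
        prev = state.beliefs[0]


def test_sole_pair_lower_bound_exceeds_cutoff_at_reference_params():
    bound = sole_pair_lower_bound(ModelParams(epsilon=0.02, beta=0.2))
    assert bound == pytest.approx(0.9259, abs=1e-4)
    assert bound > 0.85


# ---------------------------------------------------------- graph construction
def test_build_factor_graph_single_domain_positive():
    assignments = {"At3g29350": _asn("At3g29350", ["PF01627"]), "At4g29170": _asn("At4g29170", ["PF03962"])}
    graph, n_excluded = build_factor_graph([("At3g29350", "At4g29170")], [], assignments)
    assert graph.n_vars == 1 and len(graph.factors) == 1
    assert graph.variables[0] == ("PF01627", "PF03962")
    assert graph.factors[0].positive and n_excluded == 0


def test_build_factor_graph_variable_count_matches_enumeration():
    rng = np.random.default_rng(5)
    domains = [f"PF{i}" for i in range(8)]
    assignments = {
        f"P{i}": _asn(f"P{i}", rng.choice(domains, size=int(rng.integers(1, 4)), replace=False))
        for i in range(8)
    }
    pos = [("P0", "P1"), ("P2", "P3"), ("P0", "P4")]
    neg = [("P5", "P6"), ("P1", "P7"), ("P2", "P6"), ("P3", "P7"), ("P4", "P5"), ("P0", "P7")]
    graph, _ = build_factor_graph(pos, neg, assignments)
    brute = set()
    for p, q in pos + neg:
        brute |= {
            tuple(sorted((a, b)))
            for a in assignments[p].domains
            for b in assignments[q].domains
        }
    assert graph.n_vars == len(brute)
    assert set(graph.variables) == brute


def test_build_factor_graph_excludes_unannotated_and_requires_training():
    assignments = {"P0": _asn("P0", ["PF1"])}
    graph, n_excluded = build_factor_graph([("P0", "P0"), ("P0", "missing")], [], assignments)
    assert n_excluded == 1 and len(graph.factors) == 1
    with pytest.raises(ValueError, match="empty training"):
        build_factor_graph([("missing1", "missing2")], [], assignments)


def test_build_factor_graph_prunes_high_degree_factors():
    many_p = [f"A{i}" for i in range(6)]
    many_q = [f"B{i}" for i in range(6)]
    assignments = {"P": _asn("P", many_p), "Q": _asn("Q", many_q)}
    with pytest.warns(UserWarning, match="pruned"):
        graph, _ = build_factor_graph([("P", "Q")], [], assignments, degree_cap=16)
    assert len(graph.factors[0].vars) == 16  # 36 candidates capped


# ------------------------------------------------------------------- fitting
def test_fit_parameters_single_point_grid():
    graph = _graph(Factor(("p", "q"), True, (0,)), Factor(("r", "s"), False, (1,)), n_vars=2)
    fit = fit_parameters(graph, [0.3], [0.05])
    assert fit.best.beta == 0.3 and fit.best.epsilon == 0.05
    assert len(fit.surface) == 1 and fit.surface.converged.all()


def test_fit_parameters_rejects_empty_grids():
    graph = _graph(Factor(("p", "q"), True, (0,)), n_vars=1)
    with pytest.raises(ValueError):
        fit_parameters(graph, [], [0.05])


# ------------------------------------------------------------------ selection
def test_select_ddis_cutoff_validation_sole_flag_and_d4_overlap():
    graph = _graph(
        Factor(("p", "q"), True, (0,)),  # sole-pair positive -> belief ~0.926
        Factor(("r", "s"), False, (1,)),  # negative -> belief ~0.005
        n_vars=2,
    )
    params = ModelParams(epsilon=0.02, beta=0.2)
    state = run_bp(graph, params, **TIGHT)
    d4 = KnownDDISet(pairs={graph.variables[0], ("PFX", "PFY")})
    result = select_ddis(graph, state, 0.85, d4)
    assert result.selected == {graph.variables[0]}
    assert result.sole_pairs == {graph.variables[0]}
    assert result.overlap_d4 == 1
    # union with the known set for downstream prediction is plain set arithmetic
    assert len(result.selected | d4.pairs) == 2

    with pytest.raises(ValueError):
        select_ddis(graph, state, 1.01, d4)
    with pytest.raises(ValueError):
        select_ddis(graph, state, 0.0, d4)
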