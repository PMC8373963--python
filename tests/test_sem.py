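"""Piecewise SEM: standardization, d-separation, Fisher's C, pruning and
effect decomposition."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aphidweb.datasets import eds_path_diagram, es_path_diagram
from aphidweb.sem import (
    PathDiagram,
    dsep_basis_set,
    effect_decomposition,
    fishers_c,
    fit_path_model,
    prune_and_refit,
    standardize,
)


def chain_data(n=200, betas=(0.7, 0.6), seed=0):
    """x -> y -> z chain with unit-variance nodes."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = betas[0] * x + np.sqrt(1 - betas[0] ** 2) * rng.standard_normal(n)
    z = betas[1] * y + np.sqrt(1 - betas[1] ** 2) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


# ---------------------------------------------------------------------------
# standardization


def test_standardize_moments_and_exact_values():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 30.0, 20.0]})
    z = standardize(df)
    assert np.allclose(z.mean(), 0, atol=1e-12)
    assert np.allclose(z.std(ddof=1), 1, atol=1e-12)
    assert list(z["a"]) == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_is_idempotent():
    z = standardize(chain_data())
    z2 = standardize(z)
    assert np.allclose(z, z2, atol=1e-12)


def test_standardize_names_zero_variance_column():
    df = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
    with pytest.raises(ValueError, match="flat"):
        standardize(df)


# ---------------------------------------------------------------------------
# diagram and basis set


def test_diagram_rejects_cycles():
    with pytest.raises(ValueError):
        PathDiagram([("a", "b"), ("b", "c"), ("c", "a")])


def test_basis_set_of_chain():
    claims = dsep_basis_set(PathDiagram([("x", "y"), ("y", "z")]))
    assert len(claims) == 1
    assert (claims[0]["x"], claims[0]["y"]) == ("x", "z")
    assert claims[0]["conditioning"] == ["y"]


def test_basis_set_of_complete_dag_is_empty():
    nodes = ["a", "b", "c", "d"]
    edges = [(u, v) for u, v in itertools.combinations(nodes, 2)]
    assert dsep_basis_set(PathDiagram(edges)) == []


def test_basis_set_of_four_node_chain():
    """diversity -> Gq -> richness -> ES: three claims, conditioned on the
    union of both nodes' parents."""
    d = PathDiagram([("div", "gq"), ("gq", "rich"), ("rich", "es")])
    claims = {(c["x"], c["y"]): c["conditioning"] for c in dsep_basis_set(d)}
    assert claims == {
        ("div", "rich"): ["gq"],
        ("div", "es"): ["rich"],
        ("gq", "es"): ["div", "rich"],
    }


def test_basis_set_skips_exogenous_pairs():
    # two exogenous causes of a common child are not a testable claim here
    d = PathDiagram([("a", "c"), ("b", "c")])
    assert dsep_basis_set(d) == []


# ---------------------------------------------------------------------------
# Fisher's C


def test_fishers_c_arithmetic():
    c, df, p = fishers_c([0.5, 0.5])
    assert c == pytest.approx(-4 * np.log(0.5))
    assert df == 4
    assert p == pytest.approx(stats.chi2.sf(c, 4))


def test_fishers_c_saturated_model():
    assert fishers_c([]) == (0.0, 0, 1.0)


def test_fishers_c_boundary_pvalues():
    c, df, p = fishers_c([1.0])
    assert (c, df, p) == (0.0, 2, 1.0)
    c, df, p = fishers_c([0.0, 0.5])
    assert np.isinf(c) and p == 0.0


# ---------------------------------------------------------------------------
# fitting


def test_single_edge_beta_equals_pearson_correlation():
    data = chain_data()
    fit = fit_path_model(PathDiagram([("x", "y")]), data[["x", "y"]])
    r = np.corrcoef(data["x"], data["y"])[0, 1]
    assert fit.diagram.beta("x", "y") == pytest.approx(r, abs=1e-12)


def test_diagram_without_edges_has_no_equations():
    data = chain_data()
    fit = fit_path_model(PathDiagram([], nodes=["x", "y"]), data[["x", "y"]])
    assert fit.equations == {}
    assert fit.df == 0  # the only claim pair is exogenous-exogenous


def test_chain_fit_recovers_standardized_slopes():
    data = chain_data(n=4000, betas=(0.7, 0.6), seed=3)
    fit = fit_path_model(PathDiagram([("x", "y"), ("y", "z")]), data)
    assert fit.diagram.beta("x", "y") == pytest.approx(0.7, abs=0.05)
    assert fit.diagram.beta("y", "z") == pytest.approx(0.6, abs=0.05)
    assert fit.global_p > 0.001  # true structure rarely rejected


# ---------------------------------------------------------------------------
# pruning


def test_prune_removes_noise_predictor():
    rng = np.random.default_rng(8)
    n = 300
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)  # no effect on y
    y = 0.8 * x + 0.6 * rng.standard_normal(n)
    data = pd.DataFrame({"x": x, "noise": noise, "y": y})
    fit = prune_and_refit(PathDiagram([("x", "y"), ("noise", "y")]), data, "y")
    assert ("noise", "y") not in fit.diagram.edges
    assert any("noise" in line for line in fit.pruning_log)
    assert ("x", "y") in fit.diagram.edges


def test_prune_keeps_all_significant_edges():
    data = chain_data(n=500, seed=9)
    diagram = PathDiagram([("x", "y"), ("y", "z")])
    fit = prune_and_refit(diagram, data, "z")
    assert fit.diagram.edges == diagram.edges
    assert fit.pruning_log == []


def test_prune_alpha_one_removes_nothing():
    rng = np.random.default_rng(10)
    n = 100
    data = pd.DataFrame(
        {"x": rng.standard_normal(n), "w": rng.standard_normal(n), "y": rng.standard_normal(n)}
    )
    fit = prune_and_refit(PathDiagram([("x", "y"), ("w", "y")]), data, "y", alpha=1.0)
    assert len(fit.diagram.edges) == 2


def test_prune_is_idempotent():
    rng = np.random.default_rng(12)
    n = 200
    x = rng.standard_normal(n)
    n1, n2 = rng.standard_normal((2, n))
    y = 0.7 * x + 0.7 * rng.standard_normal(n)
    data = pd.DataFrame({"x": x, "n1": n1, "n2": n2, "y": y})
    first = prune_and_refit(
        PathDiagram([("x", "y"), ("n1", "y"), ("n2", "y")]), data, "y"
    )
    second = prune_and_refit(first.diagram, data[first.diagram.nodes], "y")
    assert second.diagram.edges == first.diagram.edges
    assert second.pruning_log == []


def test_prune_stops_before_disconnecting_response():
    rng = np.random.default_rng(13)
    n = 60
    data = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.standard_normal(n)})
    fit = prune_and_refit(PathDiagram([("x", "y")]), data, "y")
    assert ("x", "y") in fit.diagram.edges
    assert any("disconnect" in line for line in fit.pruning_log)


# ---------------------------------------------------------------------------
# effect decomposition


def test_single_chain_indirect_product():
    d = PathDiagram([("a", "b", 0.5), ("b", "c", 0.4)])
    eff = effect_decomposition(d, "c").set_index("predictor")
    assert eff.loc["a", "direct"] == 0.0
    assert eff.loc["a", "indirect"] == pytest.approx(0.2)
    assert eff.loc["a", "total"] == pytest.approx(0.2)
    assert eff.loc["b", "total"] == pytest.approx(0.4)


def test_reference_es_diagram_totals():
    eff = effect_decomposition(es_path_diagram(), "parasitism").set_index("predictor")
    assert eff.loc["parasitoid_richness", "total"] == pytest.approx(-0.524, abs=1e-3)
    assert eff.loc["generality", "total"] == pytest.approx(-0.363, abs=1e-3)
    assert eff.loc["parasitoid_diversity", "total"] == pytest.approx(-0.326, abs=1e-3)


def test_reference_eds_diagram_totals():
    eff = effect_decomposition(eds_path_diagram(), "hyperparasitism").set_index("predictor")
    assert eff.loc["vulnerability", "total"] == pytest.approx(0.514, abs=1e-3)
    assert eff.loc["hyperparasitoid_diversity", "total"] == pytest.approx(0.424, abs=1e-3)
    assert eff.loc["secondary_crops", "total"] == pytest.approx(-0.231, abs=1e-3)


def _random_dag(rng, n_nodes):
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < 0.4:
            edges.append((nodes[i], nodes[j], rng.normal()))
    return PathDiagram(edges, nodes=nodes)


def _brute_force_effects(diagram, source, target):
    """Depth-first enumeration of all directed paths, multiplying betas."""
    g = diagram.graph
    direct = g.edges[source, target]["beta"] if g.has_edge(source, target) else 0.0
    indirect = 0.0
    stack = [(source, [source], 1.0)]
    while stack:
        node, path, prod = stack.pop()
        for succ in g.successors(node):
            if succ == target:
                if len(path) >= 2:
                    indirect += prod * g.edges[node, succ]["beta"]
            elif succ not in path:
                stack.append((succ, path + [succ], prod * g.edges[node, succ]["beta"]))
    return direct, indirect


def test_decomposition_matches_brute_force_on_random_dags():
    rng = np.random.default_rng(99)
    for _ in range(50):
        d = _random_dag(rng, int(rng.integers(3, 9)))
        target = d.nodes[-1]
        eff = effect_decomposition(d, target).set_index("predictor")
        for node in d.nodes:
            if node == target:
                continue
            direct, indirect = _brute_force_effects(d, node, target)
            assert eff.loc[node, "direct"] == pytest.approx(direct, abs=1e-10)
            assert eff.loc[node, "indirect"] == pytest.approx(indirect, abs=1e-10)


@given(st.integers(0, 10_000))
@settings(max_examples=100, derandomize=True)
def test_decomposition_additivity(seed):
    """total = direct + indirect for every predictor, on arbitrary DAGs."""
    rng = np.random.default_rng(seed)
    d = _random_dag(rng, 6)
    eff = effect_decomposition(d, d.nodes[-1])
    assert np.allclose(eff["total"], eff["direct"] + eff["indirect"], atol=1e-12)
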