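"""Piecewise structural-equation path analysis.

A path model is an acyclic directed graph over observed, standardized
variables.  Instead of fitting one global covariance model, each
endogenous node is fitted by its own ordinary least-squares regression on
its parents; the standardized slopes are the path coefficients shown on
the diagram.  Global goodness of fit is judged through the directed
separation tests: each conditional-independence claim implied by a
missing edge is tested with a partial regression, and the claim p-values
are combined into Fisher's C statistic

    C = -2 * sum(ln p_i),

which is chi-square distributed with 2k degrees of freedom (k claims)
when the causal structure is correct.

Effect decomposition follows the usual path-tracing arithmetic: the
direct effect of a predictor on the ultimate response is the coefficient
of the direct edge (0 when absent), the indirect effect is the sum over
all directed paths of length >= 2 of the product of coefficients along
the path, and the total effect is their sum.  Paths are enumerated
exhaustively, which is exact and transparent for the small diagrams used
here (at most a handful of nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PathDiagram",
    "SEMFit",
    "standardize",
    "fit_path_model",
    "dsep_basis_set",
    "test_dsep_claims",
    "fishers_c",
    "prune_and_refit",
    "effect_decomposition",
]


class PathDiagram:
    """Acyclic directed graph of cause -> effect relations.

    Edges may carry a fitted (or externally supplied) standardized
    coefficient ``beta`` and a p-value ``p``.
    """

    def __init__(self, edges, nodes=None):
        self.graph = nx.DiGraph()
        if nodes:
            self.graph.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                self.graph.add_edge(u, v)
            else:
                u, v, beta = edge
                self.graph.add_edge(u, v, beta=float(beta))
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("path diagram must be acyclic")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    @property
    def endogenous(self) -> list[str]:
        return [n for n in self.nodes if self.graph.in_degree(n) > 0]

    @property
    def exogenous(self) -> list[str]:
        return [n for n in self.nodes if self.graph.in_degree(n) == 0]

    def beta(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["beta"])

    def set_beta(self, u: str, v: str, beta: float, p: float | None = None) -> None:
        self.graph.edges[u, v]["beta"] = float(beta)
        if p is not None:
            self.graph.edges[u, v]["p"] = float(p)

    def copy(self) -> "PathDiagram":
        new = PathDiagram([])
        new.graph = self.graph.copy()
        return new

    def topological_index(self) -> dict[str, int]:
        """Deterministic topological position of every node."""
        order = list(nx.lexicographical_topological_sort(self.graph))
        return {n: i for i, n in enumerate(order)}

    def __repr__(self) -> str:
        return f"PathDiagram({self.edges})"


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column to mean 0, sample SD 1 (n-1 denominator).

    Raises ``ValueError`` naming any zero-variance column.
    """
    out = {}
    for col in data.columns:
        x = data[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize zero-variance column {col!r}")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=data.index)


@dataclass
class SEMFit:
    """Result of a piecewise SEM fit.

    ``equations`` maps each endogenous node to its standardized
    coefficients, p-values and R^2; ``claims`` lists the directed
    separation tests; ``fisher_c``/``df``/``global_p`` summarise global
    fit; ``effects`` holds the direct/indirect/total decomposition toward
    the ultimate response when one was given.
    """

    diagram: PathDiagram
    equations: dict[str, dict] = field(default_factory=dict)
    claims: list[dict] = field(default_factory=list)
    fisher_c: float = 0.0
    df: int = 0
    global_p: float = 1.0
    effects: pd.DataFrame | None = None
    pruning_log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "edges": [
                {
                    "from": u,
                    "to": v,
                    "beta": float(self.diagram.graph.edges[u, v].get("beta", float("nan"))),
                    "p": float(self.diagram.graph.edges[u, v].get("p", float("nan"))),
                }
                for u, v in self.diagram.edges
            ],
            "equations": {
                node: {
                    "beta": {k: float(v) for k, v in eq["beta"].items()},
                    "p": {k: float(v) for k, v in eq["p"].items()},
                    "r_squared": float(eq["r_squared"]),
                }
                for node, eq in self.equations.items()
            },
            "claims": [
                {
                    "x": c["x"],
                    "y": c["y"],
                    "conditioning": list(c["conditioning"]),
                    "p": float(c["p"]),
                }
                for c in self.claims
            ],
            "fisher_c": float(self.fisher_c),
            "df": int(self.df),
            "global_p": float(self.global_p),
            "pruning_log": list(self.pruning_log),
        }
        if self.effects is not None:
            d["effects"] = [
                {
                    "predictor": row["predictor"],
                    "direct": round(float(row["direct"]), 3),
                    "indirect": round(float(row["indirect"]), 3),
                    "total": round(float(row["total"]), 3),
                }
                for _, row in self.effects.iterrows()
            ]
        return d


def _ols_equation(y: str, xs: list[str], data: pd.DataFrame):
    X = sm.add_constant(data[xs].astype(float), has_constant="add")
    res = sm.OLS(data[y].astype(float), X).fit()
    return res


def fit_path_model(diagram: PathDiagram, data: pd.DataFrame) -> SEMFit:
    """Fit every structural equation of the diagram by OLS.

    The data are standardized first, so each slope is a standardized path
    coefficient; for a single-parent equation it equals the Pearson
    correlation.  The fitted betas and p-values are written back onto the
    diagram's edges.
    """
    missing = [n for n in diagram.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"diagram nodes missing from data: {missing}")
    z = standardize(data[diagram.nodes])
    fitted = diagram.copy()
    equations: dict[str, dict] = {}
    for node in fitted.nodes:
        parents = fitted.parents(node)
        if not parents:
            continue
        if len(z) <= len(parents) + 1:
            raise ValueError(f"too few observations to fit equation for {node!r}")
        res = _ols_equation(node, parents, z)
        betas = res.params.drop("const")
        pvals = res.pvalues.drop("const")
        equations[node] = {"beta": betas, "p": pvals, "r_squared": float(res.rsquared)}
        for parent in parents:
            fitted.set_beta(parent, node, betas[parent], pvals[parent])
    fit = SEMFit(diagram=fitted, equations=equations)
    claims = test_dsep_claims(fitted, z)
    fit.claims = claims
    fit.fisher_c, fit.df, fit.global_p = fishers_c([c["p"] for c in claims])
    return fit


def dsep_basis_set(diagram: PathDiagram) -> list[dict]:
    """Independence claims implied by the missing edges of the diagram.

    One claim per unordered pair of non-adjacent nodes of which at least
    one is endogenous, conditioned on the union of both nodes' parents.
    Claims are ordered deterministically (topological position, then
    name); within each claim ``y`` is the node later in topological
    order, the one regressed on ``x`` plus the conditioning set.
    """
    topo = diagram.topological_index()
    g = diagram.graph
    claims = []
    nodes = sorted(g.nodes, key=lambda n: (topo[n], n))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            if g.in_degree(a) == 0 and g.in_degree(b) == 0:
                continue
            cond = sorted((set(g.predecessors(a)) | set(g.predecessors(b))) - {a, b})
            claims.append({"x": a, "y": b, "conditioning": cond})
    return claims


def test_dsep_claims(diagram: PathDiagram, z: pd.DataFrame) -> list[dict]:
    """p-values of the basis-set claims via partial regressions.

    Each claim (x independent of y given C) is tested by regressing y on
    x and C and reading the p-value of the x coefficient.
    """
    claims = dsep_basis_set(diagram)
    for claim in claims:
        xs = [claim["x"], *claim["conditioning"]]
        res = _ols_equation(claim["y"], xs, z)
        claim["p"] = float(res.pvalues[claim["x"]])
    return claims


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C over the claim p-values: (C, df, global p).

    C = -2 sum(ln p); df = 2 x number of claims; global p from the upper
    tail of the chi-square.  An empty basis set gives C = 0 with df = 0:
    the model is saturated and cannot be rejected (global p = 1).  Any
    claim p of exactly 0 yields an infinite C, a decisive rejection.
    """
    ps = list(p_values)
    if not ps:
        return 0.0, 0, 1.0
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("claim p-values must lie in [0, 1]")
    if any(p == 0 for p in ps):
        return float("inf"), 2 * len(ps), 0.0
    c = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def prune_and_refit(
    diagram: PathDiagram,
    data: pd.DataFrame,
    ultimate_response: str,
    alpha: float = 0.05,
) -> SEMFit:
    """Remove nonsignificant paths and refit until stable.

    In each round the removable edges are (a) edges into the ultimate
    response whose coefficient has p >= alpha and (b) outgoing edges of
    exogenous nodes that have no significant outgoing path left.  The
    single edge with the largest p is removed, orphaned nodes are
    dropped, and the model is refitted; every removal is logged.  If
    pruning would leave the ultimate response without any parent, the
    process stops with a warning in the log and the last fit is returned.
    """
    if ultimate_response not in diagram.graph.nodes:
        raise ValueError(f"ultimate response {ultimate_response!r} not in diagram")
    current = diagram.copy()
    log: list[str] = []
    fit = fit_path_model(current, data)
    while True:
        g = fit.diagram.graph
        removable: list[tuple[float, str, str]] = []
        for u, v, attrs in g.edges(data=True):
            p = attrs.get("p", 0.0)
            if p < alpha:
                continue
            if v == ultimate_response:
                removable.append((p, u, v))
            elif g.in_degree(u) == 0 and not any(
                g.edges[u, w].get("p", 1.0) < alpha for w in g.successors(u)
            ):
                removable.append((p, u, v))
        if not removable:
            break
        p, u, v = max(removable)
        if v == ultimate_response and g.in_degree(ultimate_response) == 1:
            log.append(
                f"stopped: removing {u}->{v} (p={p:.3f}) would disconnect the "
                "ultimate response from all predictors"
            )
            break
        log.append(f"removed {u}->{v} (p={p:.3f})")
        pruned = fit.diagram.copy()
        pruned.graph.remove_edge(u, v)
        for node in list(pruned.graph.nodes):
            if pruned.graph.degree(node) == 0:
                pruned.graph.remove_node(node)
                log.append(f"dropped isolated node {node}")
        fit = fit_path_model(pruned, data)
    fit.pruning_log = log
    fit.effects = effect_decomposition(fit.diagram, ultimate_response)
    return fit


def _all_paths(diagram: PathDiagram, source: str, target: str) -> list[list[str]]:
    """Every directed path source -> ... -> target (depth-first)."""
    return [list(p) for p in nx.all_simple_paths(diagram.graph, source, target)]


def effect_decomposition(diagram: PathDiagram, response: str) -> pd.DataFrame:
    """Direct, indirect and total effects of every node on the response.

    Requires every edge of the diagram to carry a ``beta`` coefficient.
    Direct = coefficient of the edge into the response (0 if absent);
    indirect = sum over directed paths of length >= 2 of the product of
    edge coefficients; total = direct + indirect.  Values are kept at
    full precision; callers round for presentation.
    """
    if response not in diagram.graph.nodes:
        raise ValueError(f"response {response!r} not in diagram")
    for u, v in diagram.edges:
        if "beta" not in diagram.graph.edges[u, v]:
            raise ValueError(f"edge {u}->{v} has no fitted coefficient")
    rows = []
    for node in diagram.nodes:
        if node == response:
            continue
        direct = (
            diagram.beta(node, response) if diagram.graph.has_edge(node, response) else 0.0
        )
        indirect = 0.0
        for path in _all_paths(diagram, node, response):
            if len(path) < 3:
                continue
            prod = 1.0
            for u, v in zip(path[:-1], path[1:]):
                prod *= diagram.beta(u, v)
            indirect += prod
        rows.append(
            {"predictor": node, "direct": direct, "indirect": indirect, "total": direct + indirect}
        )
    return pd.DataFrame(rows)
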