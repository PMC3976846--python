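"""Discrete Bayesian networks over syndrome variables.

Pipeline: discretize the (integer-valued) syndrome columns, learn a DAG by
a two-phase greedy score search (forward edge additions then backward
deletions, maximizing a decomposable BIC score), fit conditional probability
tables by maximum likelihood, and answer joint / marginal queries exactly.

Discretization keeps columns with at most four distinct values untouched
and otherwise bins into ``itvnum = floor(log2(#unique)) + 1`` equal-width
intervals of [0, max], so a column with 13 distinct levels collapses to 4
bins.  Inference is exact variable elimination with a min-degree ordering;
on the network sizes this package targets (tens of nodes, small
cardinalities) it is equivalent to, and simpler than, a junction tree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationSpec",
    "DiscreteBayesNet",
    "discretize",
    "discretize_frame",
    "bic_score",
    "family_score",
    "greedy_structure_search",
    "fit_cpts_mle",
    "joint_probability",
    "marginal",
]


@dataclass(frozen=True)
class DiscretizationSpec:
    """How one column was discretized (pass-through or equal-width bins)."""

    itvnum: int
    max_value: float
    pass_through: bool

    def apply(self, column: np.ndarray) -> np.ndarray:
        column = np.asarray(column)
        if self.pass_through:
            return column.astype(int)
        binned = np.floor(column * self.itvnum / self.max_value).astype(int)
        return np.minimum(binned, self.itvnum - 1)


def discretize(column: np.ndarray) -> tuple[np.ndarray, DiscretizationSpec]:
    """Discretize one non-negative column.

    Columns with <= 4 distinct values (including constants) pass through
    unchanged; otherwise values are floor-binned into itvnum equal-width
    intervals with the top edge clamped, so exactly ``itvnum`` labels are
    producible and zero maps to bin 0.
    """
    column = np.asarray(column)
    if np.any(column < 0):
        raise ValueError("values must be non-negative")
    n_unique = len(np.unique(column))
    if n_unique <= 4:
        spec = DiscretizationSpec(n_unique, float(column.max(initial=0)), True)
        return spec.apply(column), spec
    itvnum = int(math.floor(math.log2(n_unique))) + 1
    spec = DiscretizationSpec(itvnum, float(column.max()), False)
    return spec.apply(column), spec


def discretize_frame(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, DiscretizationSpec]]:
    out = {}
    specs = {}
    for col in df.columns:
        out[col], specs[col] = discretize(df[col].to_numpy())
    return pd.DataFrame(out, index=df.index), specs


# ---------------------------------------------------------------------------
# structure scoring and search


def _cardinalities(data: pd.DataFrame) -> dict[str, int]:
    # states assumed to be 0..max observed label
    return {c: int(data[c].max()) + 1 for c in data.columns}


def family_score(
    data: pd.DataFrame, node: str, parents: tuple[str, ...]
) -> float:
    """BIC contribution of one node given its parents.

    log-likelihood of the node's column under the MLE CPT minus
    0.5 * ln(n) * (r - 1) * q free parameters, with r the node cardinality
    and q the number of parent configurations.
    """
    n = len(data)
    card = _cardinalities(data)
    r = card[node]
    q = int(np.prod([card[p] for p in parents])) if parents else 1
    cols = list(parents) + [node]
    counts = data.groupby(cols, observed=True).size()
    if parents:
        parent_counts = data.groupby(list(parents), observed=True).size()
        ll = 0.0
        for key, n_ijk in counts.items():
            parent_key = key[:-1] if len(parents) > 1 else key[0]
            ll += n_ijk * math.log(n_ijk / parent_counts[parent_key])
    else:
        ll = float(sum(c * math.log(c / n) for c in counts))
    return ll - 0.5 * math.log(n) * (r - 1) * q


def bic_score(dag: nx.DiGraph, data: pd.DataFrame) -> float:
    """Decomposable BIC of a DAG: sum of per-family scores."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph must be acyclic")
    return sum(
        family_score(data, node, tuple(sorted(dag.predecessors(node))))
        for node in dag.nodes
    )


def greedy_structure_search(
    data: pd.DataFrame, max_parents: int = 4
) -> nx.DiGraph:
    """Two-phase greedy BIC search over DAGs.

    Forward phase: repeatedly apply the single edge addition with the
    largest positive score improvement (respecting acyclicity and the
    parent limit).  Backward phase: repeatedly apply the best
    score-improving edge deletion.  Ties break lexicographically on the
    (source, target) pair, so the result is deterministic.
    """
    if data.shape[1] < 2:
        return _trivial(data)
    nodes = list(data.columns)
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def fam(node: str, parents: tuple[str, ...]) -> float:
        key = (node, parents)
        if key not in cache:
            cache[key] = family_score(data, node, parents)
        return cache[key]

    # forward: additions
    while True:
        best: tuple[float, str, str] | None = None
        for u, v in sorted(product(nodes, nodes)):
            if u == v or dag.has_edge(u, v):
                continue
            parents = tuple(sorted(dag.predecessors(v)))
            if len(parents) >= max_parents:
                continue
            if nx.has_path(dag, v, u):  # would close a cycle
                continue
            delta = fam(v, tuple(sorted(parents + (u,)))) - fam(v, parents)
            if delta > 1e-12 and (best is None or delta > best[0] + 1e-12):
                best = (delta, u, v)
        if best is None:
            break
        dag.add_edge(best[1], best[2])

    # backward: deletions
    while True:
        best = None
        for u, v in sorted(dag.edges):
            parents = tuple(sorted(dag.predecessors(v)))
            reduced = tuple(x for x in parents if x != u)
            delta = fam(v, reduced) - fam(v, parents)
            if delta > 1e-12 and (best is None or delta > best[0] + 1e-12):
                best = (delta, u, v)
        if best is None:
            break
        dag.remove_edge(best[1], best[2])
    return dag


def _trivial(data: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(data.columns)
    return g


# ---------------------------------------------------------------------------
# parameters and inference


@dataclass
class DiscreteBayesNet:
    """DAG + per-node CPTs.

    ``cpts[node]`` is an array of shape (card(parent_1), ..., card(parent_k),
    card(node)) with rows (last axis) summing to 1; ``parents[node]`` fixes
    the axis order.
    """

    cardinalities: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray] = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return list(self.cardinalities)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, pars in self.parents.items():
            g.add_edges_from((p, child) for p in pars)
        return g

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cardinalities": self.cardinalities,
            "parents": {k: list(v) for k, v in self.parents.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscreteBayesNet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {k: int(v) for k, v in payload["cardinalities"].items()},
            {k: tuple(v) for k, v in payload["parents"].items()},
            {k: np.asarray(v) for k, v in payload["cpts"].items()},
        )

    def to_dot(self) -> str:
        lines = ["digraph syndromes {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for child, pars in self.parents.items():
            for p in pars:
                lines.append(f'  "{p}" -> "{child}";')
        lines.append("}")
        return "\n".join(lines)


def fit_cpts_mle(dag: nx.DiGraph, data: pd.DataFrame) -> DiscreteBayesNet:
    """Maximum-likelihood CPTs: count(child, parents) / count(parents).

    Parent configurations never observed in the data receive a uniform row.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph must be acyclic")
    card = _cardinalities(data)
    parents = {n: tuple(sorted(dag.predecessors(n))) for n in dag.nodes}
    cpts: dict[str, np.ndarray] = {}
    for node in dag.nodes:
        pars = parents[node]
        shape = tuple(card[p] for p in pars) + (card[node],)
        counts = np.zeros(shape)
        idx_cols = data[list(pars) + [node]].to_numpy()
        for row in idx_cols:
            counts[tuple(row)] += 1
        totals = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = counts / totals
        cpt[np.broadcast_to(totals == 0, cpt.shape)] = 1.0 / card[node]
        cpts[node] = cpt
    return DiscreteBayesNet({n: card[n] for n in dag.nodes}, parents, cpts)


def joint_probability(bn: DiscreteBayesNet, assignment: dict[str, int]) -> float:
    """P(full assignment) as the product of CPT entries."""
    missing = set(bn.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes: {sorted(missing)}")
    prob = 1.0
    for node in bn.nodes:
        state = assignment[node]
        if not 0 <= state < bn.cardinalities[node]:
            raise ValueError(f"state {state} out of range for {node!r}")
        idx = tuple(assignment[p] for p in bn.parents[node]) + (state,)
        prob *= float(bn.cpts[node][idx])
    return prob


class _Factor:
    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.variables = variables
        self.table = table

    def reduce(self, var: str, state: int) -> "_Factor":
        ax = self.variables.index(var)
        return _Factor(
            self.variables[:ax] + self.variables[ax + 1:],
            np.take(self.table, state, axis=ax),
        )

    def multiply(self, other: "_Factor") -> "_Factor":
        variables = self.variables + tuple(
            v for v in other.variables if v not in self.variables
        )
        a = _expand(self, variables)
        b = _expand(other, variables)
        return _Factor(variables, a * b)

    def marginalize(self, var: str) -> "_Factor":
        ax = self.variables.index(var)
        return _Factor(
            self.variables[:ax] + self.variables[ax + 1:],
            self.table.sum(axis=ax),
        )


def _expand(factor: _Factor, variables: tuple[str, ...]) -> np.ndarray:
    """Reorder/reshape a factor's table to broadcast over ``variables``."""
    present = [v for v in variables if v in factor.variables]
    perm = [factor.variables.index(v) for v in present]
    table = np.transpose(factor.table, perm)
    dims = iter(table.shape)
    shape = [next(dims) if v in factor.variables else 1 for v in variables]
    return table.reshape(shape)


def marginal(
    bn: DiscreteBayesNet,
    query: list[str],
    evidence: dict[str, int] | None = None,
) -> tuple[np.ndarray, bool]:
    """Exact posterior P(query | evidence) by variable elimination.

    Returns the (normalized) distribution over the query variables' joint
    states along with a validity flag; the flag is False (and the table is
    all-NaN) when the evidence has zero probability.
    """
    evidence = dict(evidence or {})
    if set(query) & set(evidence):
        raise ValueError("query and evidence must be disjoint")
    factors = []
    for node in bn.nodes:
        variables = bn.parents[node] + (node,)
        f = _Factor(variables, bn.cpts[node].astype(float))
        for var, state in evidence.items():
            if var in f.variables:
                f = f.reduce(var, state)
        factors.append(f)

    hidden = [v for v in bn.nodes if v not in query and v not in evidence]
    # min-degree elimination ordering on the interaction graph
    while hidden:
        degrees = {}
        for h in hidden:
            neigh = set()
            for f in factors:
                if h in f.variables:
                    neigh.update(f.variables)
            neigh.discard(h)
            degrees[h] = len(neigh)
        var = min(hidden, key=lambda h: (degrees[h], h))
        hidden.remove(var)
        related = [f for f in factors if var in f.variables]
        factors = [f for f in factors if var not in f.variables]
        if related:
            prod = related[0]
            for f in related[1:]:
                prod = prod.multiply(f)
            factors.append(prod.marginalize(var))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    # order axes as requested
    out = _Factor(tuple(query), np.zeros([bn.cardinalities[q] for q in query]))
    table = _expand(result, tuple(query))
    out_table = np.broadcast_to(table, out.table.shape).copy()
    total = out_table.sum()
    if total <= 0:
        return np.full(out_table.shape, np.nan), False
    return out_table / total, True
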