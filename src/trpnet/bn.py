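"""Score-based Gaussian Bayesian-network structure learning.

Structures are learned by greedy hill climbing over DAGs with the BIC score.
Each node's local score is the maximum log-likelihood of its linear-Gaussian
regression on its parents minus a complexity penalty

    score(v | Pa) = loglik_ML(v ~ Pa) - (|Pa| + 2)/2 * log n

counting |Pa| coefficients, an intercept and a variance per node (the
intercept is ~0 on standardized data but is still counted — stated so B=1000
bootstrap runs are exactly reproducible). The total score is the sum over
nodes; BIC is score-equivalent, so Markov-equivalent DAGs tie, which is why
the bootstrap aggregates ADJACENCY frequency and the final network is
presented undirected.

Local scores are computed from the centered Gram matrix of the dataset, so a
hill climb costs O(moves * |Pa|^3) after a single O(n p^2) pass — this keeps
1000-fold bootstraps cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable
from .edges import EdgeSet, Provenance, canonical

Arc = tuple[str, str]


class RankDeficiencyError(ValueError):
    """A node's parent set is too large (or collinear) for its regression."""


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    arcs: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        known = set(self.nodes)
        if len(known) != len(self.nodes):
            raise ValueError("duplicate node names")
        for u, v in self.arcs:
            if u == v:
                raise ValueError(f"self-arc {u}->{v}")
            if u not in known or v not in known:
                raise ValueError(f"arc {u}->{v} references unknown node")
        if self.topological_order() is None:
            raise ValueError("arcs contain a directed cycle")

    def topological_order(self) -> list[str] | None:
        """Kahn's algorithm; None if cyclic."""
        indeg = {v: 0 for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.arcs:
            indeg[v] += 1
            children[u].append(v)
        queue = [v for v in self.nodes if indeg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop()
            order.append(v)
            for w in children[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        return order if len(order) == len(self.nodes) else None

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def skeleton(self) -> frozenset[tuple[str, str]]:
        return frozenset(canonical(u, v) for u, v in self.arcs)


def to_undirected(dag: Dag, provenance: Provenance | None = None) -> EdgeSet:
    """Forget arc directions: the presence-only adjacency set."""
    return EdgeSet.from_pairs(
        dag.skeleton(), provenance=provenance, nodes=dag.nodes
    )


class _GramScorer:
    """BIC local scores from the centered Gram matrix of one dataset."""

    def __init__(self, values: np.ndarray, names: Sequence[str]):
        x = np.asarray(values, dtype=float)
        self.n = x.shape[0]
        self.names = tuple(names)
        self.index = {v: i for i, v in enumerate(self.names)}
        xc = x - x.mean(axis=0)
        self.gram = xc.T @ xc
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self._log2pi = np.log(2 * np.pi)

    def node_score(self, node: str, parents: Iterable[str]) -> float:
        j = self.index[node]
        pa = tuple(sorted(self.index[v] for v in parents))
        key = (j, pa)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        n = self.n
        if len(pa) + 2 >= n:
            raise RankDeficiencyError(
                f"node {node!r}: {len(pa)} parents with only n={n} rows"
            )
        syy = self.gram[j, j]
        if pa:
            gpp = self.gram[np.ix_(pa, pa)]
            gpy = self.gram[pa, j]
            try:
                coef = np.linalg.solve(gpp, gpy)
            except np.linalg.LinAlgError:
                raise RankDeficiencyError(
                    f"node {node!r}: collinear parent set {pa}"
                ) from None
            rss = syy - gpy @ coef
        else:
            rss = syy
        sigma2 = max(rss / n, 1e-300)  # ML variance; floor guards exact fits
        loglik = -0.5 * n * (self._log2pi + np.log(sigma2) + 1.0)
        score = loglik - 0.5 * (len(pa) + 2) * np.log(n)
        self._cache[key] = score
        return score


def bic_score(
    table: CohortTable, dag: Dag, scorer: _GramScorer | None = None
) -> tuple[float, dict[str, float]]:
    """Decomposable BIC of a DAG on a standardized table (higher is better)."""
    if scorer is None:
        scorer = _GramScorer(table.values, table.variable_names)
    if set(dag.nodes) != set(table.variable_names):
        raise ValueError("dag nodes do not match table variables")
    per_node = {v: scorer.node_score(v, dag.parents(v)) for v in dag.nodes}
    return float(sum(per_node.values())), per_node


def _creates_cycle(parents: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u->v close a directed cycle (i.e. is u reachable from v)?"""
    stack, seen = [u], {u}
    while stack:
        w = stack.pop()
        if w == v:
            return True
        for parent in parents[w]:
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return False


def _climb(scorer: _GramScorer, start: dict[str, set[str]]) -> dict[str, set[str]]:
    """Greedy best-move search; deterministic lexicographic tie-break on
    (operation, parent, child) with operation order add < delete < reverse."""
    names = scorer.names
    parents = {v: set(pa) for v, pa in start.items()}
    node_score = {v: scorer.node_score(v, parents[v]) for v in names}
    while True:
        best_delta = 1e-10
        best_move: tuple[str, str, str] | None = None
        for u in names:
            for v in names:
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u->v
                    delta = (
                        scorer.node_score(v, parents[v] - {u}) - node_score[v]
                    )
                    move = ("delete", u, v)
                    if delta > best_delta or (
                        best_move and delta == best_delta and move < best_move
                    ):
                        best_delta, best_move = delta, move
                    # reverse u->v (becomes v->u); u must not reach v otherwise
                    parents[v].discard(u)
                    cyc = _creates_cycle(parents, v, u)
                    parents[v].add(u)
                    if not cyc:
                        delta = (
                            scorer.node_score(v, parents[v] - {u})
                            - node_score[v]
                            + scorer.node_score(u, parents[u] | {v})
                            - node_score[u]
                        )
                        move = ("reverse", u, v)
                        if delta > best_delta or (
                            best_move
                            and delta == best_delta
                            and move < best_move
                        ):
                            best_delta, best_move = delta, move
                elif v not in parents[u] and not _creates_cycle(parents, u, v):
                    delta = scorer.node_score(v, parents[v] | {u}) - node_score[v]
                    move = ("add", u, v)
                    if delta > best_delta or (
                        best_move and delta == best_delta and move < best_move
                    ):
                        best_delta, best_move = delta, move
        if best_move is None:
            return parents
        op, u, v = best_move
        if op == "add":
            parents[v].add(u)
            node_score[v] = scorer.node_score(v, parents[v])
        elif op == "delete":
            parents[v].remove(u)
            node_score[v] = scorer.node_score(v, parents[v])
        else:
            parents[v].remove(u)
            parents[u].add(v)
            node_score[v] = scorer.node_score(v, parents[v])
            node_score[u] = scorer.node_score(u, parents[u])


def _parents_to_dag(names: Sequence[str], parents: dict[str, set[str]]) -> Dag:
    return Dag(
        tuple(names),
        frozenset((u, v) for v, pa in parents.items() for u in pa),
    )


def hill_climb(
    table: CohortTable,
    seed: int | None = None,
    restarts: int = 0,
    scorer: _GramScorer | None = None,
) -> Dag:
    """BIC hill climbing from the empty graph.

    Applies the single arc addition/deletion/reversal with the greatest
    score improvement until no move improves; the result is a local optimum.
    With ``restarts`` > 0, additional seeded random starting DAGs are climbed
    and the best-scoring local optimum is returned (off by default: the
    canonical procedure is plain hill climbing).
    """
    if scorer is None:
        if table.n <= table.p:
            warnings.warn(
                f"n={table.n} <= p={table.p}: hill climbing may be unstable",
                stacklevel=2,
            )
        scorer = _GramScorer(table.values, table.variable_names)
    names = scorer.names
    best = _climb(scorer, {v: set() for v in names})
    if restarts > 0:
        rng = np.random.default_rng(seed)
        best_score = sum(scorer.node_score(v, best[v]) for v in names)
        for _ in range(restarts):
            order = list(rng.permutation(len(names)))
            start: dict[str, set[str]] = {v: set() for v in names}
            for i, j in combinations(range(len(names)), 2):
                if rng.random() < 0.2:
                    u, v = names[order[i]], names[order[j]]
                    start[v].add(u)
            cand = _climb(scorer, start)
            score = sum(scorer.node_score(v, cand[v]) for v in names)
            if score > best_score + 1e-10:
                best, best_score = cand, score
    return _parents_to_dag(names, best)


@dataclass(frozen=True)
class StrengthTable:
    """Bootstrap adjacency frequencies for every unordered node pair.

    ``strength[pair]`` is the fraction of B resamples whose learned DAG
    contains the pair in either direction (a multiple of 1/B);
    ``direction`` is the fraction of those adjacency-containing resamples
    oriented canonical-first (a < b reading a->b) — stored but not used by
    the consensus logic, which is direction-blind.
    """

    names: tuple[str, ...]
    strength: dict[tuple[str, str], float]
    direction: dict[tuple[str, str], float]
    B: int

    def __post_init__(self) -> None:
        p = len(self.names)
        if len(self.strength) != p * (p - 1) // 2:
            raise ValueError("strength table must cover all unordered pairs")
        bad = {k: v for k, v in self.strength.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"strengths outside [0,1]: {bad}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "var_a": a,
                "var_b": b,
                "strength": self.strength[(a, b)],
                "direction_frac": self.direction.get((a, b), float("nan")),
            }
            for a, b in sorted(self.strength)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def bootstrap_strengths(
    table: CohortTable,
    B: int = 1000,
    seed: int | None = None,
    restarts: int = 0,
) -> StrengthTable:
    """Learn B structures on row-resamples and aggregate adjacency frequency.

    Resamples draw n rows with replacement; the seed governs the whole
    resample sequence, so runs are reproducible bit-for-bit.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    names = tuple(table.variable_names)
    pairs = [canonical(a, b) for a, b in combinations(names, 2)]
    adj_count = {pr: 0 for pr in pairs}
    fwd_count = {pr: 0 for pr in pairs}
    n = table.n
    x = table.values
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        scorer = _GramScorer(x[rows], names)
        parents = _climb(scorer, {v: set() for v in names})
        for v, pa in parents.items():
            for u in pa:
                pr = canonical(u, v)
                adj_count[pr] += 1
                if (u, v) == pr:
                    fwd_count[pr] += 1
    strength = {pr: adj_count[pr] / B for pr in pairs}
    direction = {
        pr: (fwd_count[pr] / adj_count[pr]) if adj_count[pr] else float("nan")
        for pr in pairs
    }
    return StrengthTable(names, strength, direction, B)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class GaussianBayesianNetwork:
    """Linear-Gaussian Bayesian network model of a cohort stratum."""

    def __init__(self, table: CohortTable):
        x = table.values
        already = (
            np.allclose(x.mean(axis=0), 0, atol=1e-8)
            and np.allclose(x.std(axis=0, ddof=1), 1, atol=1e-8)
        )
        self.table = table if already else table.standardize()

    def fit(self, seed: int | None = None, restarts: int = 0) -> "BNResults":
        dag = hill_climb(self.table, seed=seed, restarts=restarts)
        score, per_node = bic_score(self.table, dag)
        return BNResults(self, dag, score, per_node)

    def fit_bootstrap(
        self, B: int = 1000, seed: int | None = None, restarts: int = 0
    ) -> StrengthTable:
        return bootstrap_strengths(self.table, B=B, seed=seed, restarts=restarts)


class BNResults:
    """A learned DAG with its BIC score and per-node decomposition."""

    def __init__(
        self,
        model: GaussianBayesianNetwork,
        dag: Dag,
        score: float,
        node_scores: dict[str, float],
    ):
        self.model = model
        self.dag = dag
        self.score = score
        self.node_scores = node_scores

    def skeleton(self, provenance: Provenance | None = None) -> EdgeSet:
        return to_undirected(self.dag, provenance=provenance)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.dag.nodes)
        for u, v in sorted(self.dag.arcs):
            g.add_edge(u, v, direction=f"{u}->{v}")
        nx.write_graphml(g, path)

    def summary(self) -> str:
        lines = [
            "Gaussian Bayesian network (BIC hill climbing)",
            f"  n = {self.model.table.n}, p = {len(self.dag.nodes)}",
            f"  BIC score = {self.score:.2f}, arcs = {len(self.dag.arcs)}",
            "",
            "  arcs (direction not interpreted):",
        ]
        for u, v in sorted(self.dag.arcs):
            lines.append(f"  {u} -> {v}")
        return "\n".join(lines)
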