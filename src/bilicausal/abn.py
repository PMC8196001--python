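"""Additive Bayesian network structure learning.

Each node's conditional distribution is a generalized linear model (identity
link for gaussian nodes, logit for bernoulli nodes); a DAG is scored by the
sum of BIC-penalized node log-likelihoods. Structure search is greedy hill
climbing over add/delete/reverse moves from a random start, and a majority
consensus network keeps directed edges present in at least a threshold
fraction of many independent searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class NodeSpec:
    """Distribution and structural constraints for one node.

    ``can_have_parents=False`` pins a node as parentless (e.g., a genotype,
    fixed at conception); ``can_have_children=False`` makes it a sink.
    """

    name: str
    distribution: str = "gaussian"  # gaussian | bernoulli
    can_have_parents: bool = True
    can_have_children: bool = True

    def __post_init__(self):
        if self.distribution not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class NetworkResult:
    edge_frequency: dict  # (parent, child) -> fraction of searches
    consensus_edges: list
    searches: list  # per-search parent-set dicts
    scores: list
    threshold: float
    best_dag: dict = field(default_factory=dict)
    best_score: float = float("-inf")


def _design(data: pd.DataFrame, parents: tuple) -> tuple[np.ndarray, int, bool]:
    """Intercept + parent columns; collinear columns dropped via pivoted QR."""
    n = len(data)
    cols = [np.ones(n)]
    for p in parents:
        cols.append(data[p].to_numpy(dtype=float))
    x = np.column_stack(cols)
    if x.shape[1] == 1:
        return x, 1, False
    # rank detection through QR with column norms
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep = diag > tol
    collinear = not keep.all()
    if collinear:
        # greedy re-selection: keep columns that increase rank
        kept = [0]
        for j in range(1, x.shape[1]):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
        x = x[:, kept]
    return x, x.shape[1], collinear


def node_score(child: NodeSpec, parents: tuple, data: pd.DataFrame) -> float:
    """BIC-penalized GLM log-likelihood of a node given its parents.

    Gaussian nodes use the closed-form normal log-likelihood at the MLE
    variance; bernoulli nodes use a logistic fit. Perfect separation or
    non-convergence yields a finite penalized score rather than an error.
    Collinear parent columns are dropped, so duplicated parents score as one.
    """
    if child.name in parents:
        raise ValueError("parent set must exclude the child")
    y = data[child.name].to_numpy(dtype=float)
    n = y.size
    x, rank, _ = _design(data, tuple(parents))
    if child.distribution == "gaussian":
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        s2 = max(float(resid @ resid) / n, 1e-300)
        ll = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
        k = rank + 1  # coefficients + variance
    else:
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            ll = float(fit.llf)
            if not np.isfinite(ll) or not fit.mle_retvals.get("converged", True):
                raise ValueError("logit did not converge")
        except Exception:
            # separation / non-convergence: ridge-stabilized likelihood
            try:
                with np.errstate(all="ignore"):
                    model = sm.Logit(y, x)
                    params = model.fit_regularized(alpha=1e-3, disp=0).params
                    ll = float(model.loglike(params))
            except Exception:
                ll = -1e10  # flagged-degenerate score; never preferred
        k = rank
    return ll - 0.5 * k * math.log(n)


class _ScoreCache:
    def __init__(self, data: pd.DataFrame, specs: dict):
        self.data = data
        self.specs = specs
        self.cache: dict = {}

    def __call__(self, child: str, parents: frozenset) -> float:
        key = (child, parents)
        if key not in self.cache:
            self.cache[key] = node_score(self.specs[child], tuple(sorted(parents)),
                                         self.data)
        return self.cache[key]


def _creates_cycle(parents_of: dict, parent: str, child: str) -> bool:
    """Would adding parent -> child create a directed cycle?"""
    stack, seen = [parent], set()
    while stack:
        node = stack.pop()
        if node == child:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(parents_of[node])
    return False


def assert_acyclic(parents_of: dict) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(parents_of)
    for child, parents in parents_of.items():
        for p in parents:
            g.add_edge(p, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structure contains a directed cycle")


def total_score(parents_of: dict, scorer: _ScoreCache) -> float:
    return sum(scorer(c, frozenset(ps)) for c, ps in parents_of.items())


def search_once(data: pd.DataFrame, specs: list[NodeSpec], seed: int,
                max_parents: int = 4,
                scorer: _ScoreCache | None = None) -> tuple[dict, float]:
    """One greedy hill-climbing search from a seed-dependent random start.

    Moves are edge additions, deletions and reversals, applied steepest-ascent
    until no move improves the total BIC score. Returns (parent sets, score).
    """
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    spec_map = {s.name: s for s in specs}
    names = [s.name for s in specs]
    if scorer is None:
        scorer = _ScoreCache(data, spec_map)
    rng = np.random.default_rng(seed)

    def allowed(parent, child):
        return (parent != child and spec_map[child].can_have_parents
                and spec_map[parent].can_have_children)

    # random start: random topological order, sparse edges
    order = list(names)
    rng.shuffle(order)
    parents_of = {n: set() for n in names}
    for i, child in enumerate(order):
        for parent in order[:i]:
            if allowed(parent, child) and rng.random() < 0.15 \
                    and len(parents_of[child]) < max_parents:
                parents_of[child].add(parent)

    current = total_score(parents_of, scorer)
    while True:
        best_gain, best_move = 1e-9, None
        for child in names:
            base = scorer(child, frozenset(parents_of[child]))
            for parent in names:
                if parent == child:
                    continue
                if parent in parents_of[child]:
                    # delete
                    gain = scorer(child, frozenset(parents_of[child] - {parent})) - base
                    if gain > best_gain:
                        best_gain, best_move = gain, ("del", parent, child)
                    # reverse
                    if (allowed(child, parent)
                            and len(parents_of[parent]) < max_parents
                            and not _creates_cycle(
                                {**parents_of,
                                 child: parents_of[child] - {parent}},
                                child, parent)):
                        g1 = scorer(child, frozenset(parents_of[child] - {parent})) - base
                        pbase = scorer(parent, frozenset(parents_of[parent]))
                        g2 = scorer(parent, frozenset(parents_of[parent] | {child})) - pbase
                        if g1 + g2 > best_gain:
                            best_gain, best_move = g1 + g2, ("rev", parent, child)
                else:
                    if (allowed(parent, child)
                            and len(parents_of[child]) < max_parents
                            and not _creates_cycle(parents_of, parent, child)):
                        gain = scorer(child, frozenset(parents_of[child] | {parent})) - base
                        if gain > best_gain:
                            best_gain, best_move = gain, ("add", parent, child)
        if best_move is None:
            break
        op, parent, child = best_move
        if op == "add":
            parents_of[child].add(parent)
        elif op == "del":
            parents_of[child].remove(parent)
        else:
            parents_of[child].remove(parent)
            parents_of[parent].add(child)
        current += best_gain

    assert_acyclic(parents_of)
    return {c: frozenset(ps) for c, ps in parents_of.items()}, total_score(parents_of, scorer)


def consensus(data: pd.DataFrame, specs: list[NodeSpec], n_searches: int = 200,
              threshold: float = 0.5, seed: int = 7,
              max_parents: int = 4) -> NetworkResult:
    """Majority-consensus network across independent heuristic searches.

    Directed edges present in at least ``threshold`` of the locally optimal
    networks make the consensus; the full edge-frequency table is reported.
    """
    if n_searches < 1:
        raise ValueError("n_searches must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    spec_map = {s.name: s for s in specs}
    scorer = _ScoreCache(data, spec_map)
    seeds = np.random.SeedSequence(seed).generate_state(n_searches) % (2**31)
    searches, scores = [], []
    counts: dict = {}
    best_dag, best_score = None, float("-inf")
    for s in seeds:
        dag, score = search_once(data, specs, int(s), max_parents=max_parents,
                                 scorer=scorer)
        searches.append(dag)
        scores.append(score)
        if score > best_score:
            best_dag, best_score = dag, score
        for child, parents in dag.items():
            for p in parents:
                counts[(p, child)] = counts.get((p, child), 0) + 1
    freq = {e: c / n_searches for e, c in counts.items()}
    cons = sorted(e for e, f in freq.items() if f >= threshold)
    return NetworkResult(
        edge_frequency=freq,
        consensus_edges=cons,
        searches=searches,
        scores=scores,
        threshold=threshold,
        best_dag=best_dag,
        best_score=best_score,
    )


def to_dot(edges, nodes=None) -> str:
    lines = ["digraph consensus {"]
    for n in (list(nodes) if nodes is not None else []):
        lines.append(f'  "{n}";')
    for p, c in edges:
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines)
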