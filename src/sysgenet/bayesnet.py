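"""Bayesian network reconstruction with eQTL structure priors and consensus.

The causal-network layer: genes are selected by expression variance or eQTL
strength, genetics builds asymmetric structure priors (a gene with a cis
eQTL may parent genes with trans eQTLs at the same marker, never the
reverse), many networks are learned from bootstrap resamples with different
seeds, edges present in more than a retention threshold of the ensemble
form a consensus network, and remaining directed cycles are broken by
removing each loop's most weakly supported edge.

Structure search is score-based hill climbing (add / delete / reverse
moves with random restarts) maximizing BIC.  The default data model
discretizes each gene into 3 states by deterministic one-dimensional
k-means (low / medium / high expression); a linear-Gaussian BIC mode is
available via ``score="gaussian"``.  "Allowed" prior edges receive a
log-score bonus; forbidden edges are hard constraints never proposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EQTLTable",
    "StructurePrior",
    "NetworkEnsemble",
    "ConsensusNetwork",
    "select_genes",
    "build_priors",
    "discretize_expression",
    "learn_network",
    "build_ensemble",
    "build_consensus",
    "break_cycles",
    "union_networks",
    "enumerate_dags",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EQTLTable:
    """Rows of (gene, marker, association strength, cis/trans label)."""

    table: pd.DataFrame  # columns: gene, snp, strength, kind

    def __post_init__(self):
        need = {"gene", "snp", "strength", "kind"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"eQTL table missing columns {need - set(self.table.columns)}")
        bad = set(self.table["kind"]) - {"cis", "trans"}
        if bad:
            raise ValueError(f"invalid eQTL labels {bad}")
        if (self.table["strength"].fillna(0) < 0).any():
            raise ValueError("negative eQTL strength")


@dataclass
class StructurePrior:
    """Allowed (bonus) and forbidden (hard) ordered gene pairs."""

    allowed: set = field(default_factory=set)
    forbidden: set = field(default_factory=set)

    def __post_init__(self):
        both = self.allowed & self.forbidden
        if both:
            raise ValueError(f"pairs both allowed and forbidden: {sorted(both)[:5]}")


@dataclass
class NetworkEnsemble:
    """Independently learned DAGs over one gene set, with their seeds."""

    graphs: list
    seeds: list

    def __post_init__(self):
        if self.graphs:
            nodes = set(self.graphs[0].nodes)
            for g in self.graphs:
                if set(g.nodes) != nodes:
                    raise ValueError("ensemble graphs have differing node sets")


@dataclass
class ConsensusNetwork:
    """Directed graph whose edges carry ensemble frequency in (0, 1]."""

    graph: nx.DiGraph
    threshold: float
    removed_edges: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene selection and priors
# ---------------------------------------------------------------------------

def select_genes(
    expression: pd.DataFrame,
    eqtl: EQTLTable | None = None,
    variance_quantile: float = 0.8,
    eqtl_cutoff: float = np.inf,
) -> list:
    """Union of top-variance genes and genes with a strong eQTL.

    Keeps the top ``1 - variance_quantile`` fraction of genes by expression
    variance (ties broken by gene id; selection size ceil((1-q) n)) plus any
    gene whose eQTL strength reaches ``eqtl_cutoff``.
    """
    if expression.empty:
        raise ValueError("empty expression matrix")
    var = expression.var(axis=1, ddof=1)
    n_top = int(np.ceil((1.0 - variance_quantile) * len(var)))
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    chosen = set(order[:n_top])
    if eqtl is not None and np.isfinite(eqtl_cutoff):
        strong = eqtl.table.loc[eqtl.table["strength"] >= eqtl_cutoff, "gene"]
        chosen |= set(strong) & set(expression.index)
    return [g for g in expression.index if g in chosen]


def build_priors(eqtl: EQTLTable) -> StructurePrior:
    """Genetics-based structure priors from cis/trans eQTL co-mapping.

    For each marker, every gene with a cis eQTL there is an allowed parent
    of every gene with a coincident trans eQTL; the reverse orientation
    (trans-only gene -> cis gene at a shared marker) is forbidden.  A gene
    labeled both cis and trans at one marker is treated as cis (warning).
    """
    allowed, forbidden = set(), set()
    for snp, grp in eqtl.table.groupby("snp"):
        cis = set(grp.loc[grp["kind"] == "cis", "gene"])
        trans = set(grp.loc[grp["kind"] == "trans", "gene"])
        dual = cis & trans
        if dual:
            warnings.warn(
                f"genes {sorted(dual)} are both cis and trans at {snp}; treating as cis",
                stacklevel=2,
            )
            trans -= dual
        for c in cis:
            for t in trans:
                if c != t:
                    allowed.add((c, t))
                    forbidden.add((t, c))
    # a pair allowed somewhere cannot be forbidden elsewhere: allowed wins
    forbidden -= allowed
    return StructurePrior(allowed=allowed, forbidden=forbidden)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def discretize_expression(expression: pd.DataFrame, n_states: int = 3) -> np.ndarray:
    """Per-gene 1-D k-means into ``n_states`` ordered levels.

    Deterministic Lloyd iteration initialized at evenly spaced quantiles;
    returns an int array (n_samples, n_genes).
    """
    X = expression.to_numpy(dtype=float).T  # samples x genes
    out = np.empty(X.shape, dtype=np.int64)
    qs = (np.arange(n_states) + 0.5) / n_states
    for j in range(X.shape[1]):
        x = X[:, j]
        centers = np.quantile(x, qs)
        if np.allclose(centers, centers[0]):
            out[:, j] = 0
            continue
        for _ in range(100):
            lab = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
            new = np.array(
                [x[lab == k].mean() if (lab == k).any() else centers[k]
                 for k in range(n_states)]
            )
            if np.allclose(new, centers):
                break
            centers = new
        out[:, j] = lab
    return out


class _Scorer:
    """Cached per-node local scores (BIC + prior bonus) for structure search."""

    def __init__(self, data: np.ndarray, mode: str, prior: StructurePrior,
                 node_names: list, prior_bonus: float):
        self.data = data                      # samples x genes
        self.mode = mode
        self.prior = prior
        self.names = node_names
        self.bonus = prior_bonus
        self.n = data.shape[0]
        self.cache: dict = {}
        if mode == "discrete":
            self.card = np.array([int(data[:, j].max()) + 1 for j in range(data.shape[1])])

    def local(self, node: int, parents: frozenset) -> float:
        key = (node, parents)
        if key in self.cache:
            return self.cache[key]
        if self.mode == "discrete":
            s = self._bic_discrete(node, sorted(parents))
        else:
            s = self._bic_gaussian(node, sorted(parents))
        for p in parents:
            if (self.names[p], self.names[node]) in self.prior.allowed:
                s += self.bonus
        self.cache[key] = s
        return s

    def _bic_discrete(self, node: int, parents: list) -> float:
        y = self.data[:, node]
        r = self.card[node]
        if parents:
            dims = tuple(int(self.card[p]) for p in parents) + (r,)
            flat = np.ravel_multi_index(
                tuple(self.data[:, p] for p in parents) + (y,), dims
            )
            counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(-1, r)
        else:
            counts = np.bincount(y, minlength=r)[None, :]
        nij = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(counts / nij), 0.0).sum()
        q = counts.shape[0]
        return float(ll) - 0.5 * np.log(self.n) * q * (r - 1)

    def _bic_gaussian(self, node: int, parents: list) -> float:
        y = self.data[:, node]
        if parents:
            X = np.column_stack([np.ones(self.n)] + [self.data[:, p] for p in parents])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
        else:
            rss = float(np.sum((y - y.mean()) ** 2))
        rss = max(rss, 1e-12)
        k = len(parents) + 2
        ll = -0.5 * self.n * (np.log(2 * np.pi * rss / self.n) + 1)
        return ll - 0.5 * np.log(self.n) * k


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _creates_cycle(children: list, u: int, v: int) -> bool:
    """Would adding u->v create a directed cycle (i.e. can v reach u)?"""
    stack = [v]
    seen = {v}
    while stack:
        x = stack.pop()
        if x == u:
            return True
        for y in children[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return False


def learn_network(
    expression: pd.DataFrame,
    prior: StructurePrior | None = None,
    seed: int = 0,
    score: str = "discrete",
    max_parents: int = 3,
    n_restarts: int = 2,
    prior_bonus: float = np.log(10.0),
) -> nx.DiGraph:
    """BIC hill climbing over DAGs with structure-prior constraints.

    Random-restart greedy search over add/delete/reverse moves; forbidden
    edges are never proposed, allowed edges earn ``prior_bonus`` on the
    child's local score.  Constant genes are dropped with a warning.
    Deterministic given ``seed``.
    """
    if expression.shape[1] < 20:
        warnings.warn("fewer than 20 samples; network learning will be unstable",
                      stacklevel=2)
    if expression.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    const = expression.var(axis=1) == 0
    if const.any():
        warnings.warn(f"dropping constant genes: {list(expression.index[const])}",
                      stacklevel=2)
        expression = expression.loc[~const]
    if prior is None:
        prior = StructurePrior()

    names = list(expression.index)
    idx = {g: i for i, g in enumerate(names)}
    ng = len(names)
    forb = {(idx[u], idx[v]) for u, v in prior.forbidden if u in idx and v in idx}

    if score == "discrete":
        data = discretize_expression(expression)
    elif score == "gaussian":
        data = expression.to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown score mode {score!r}")
    scorer = _Scorer(data, score, prior, names, prior_bonus)
    rng = np.random.default_rng(seed)

    def climb(parents: list) -> tuple:
        children = [set() for _ in range(ng)]
        for v in range(ng):
            for u in parents[v]:
                children[u].add(v)
        local = [scorer.local(v, frozenset(parents[v])) for v in range(ng)]
        while True:
            best_gain, best_move = 1e-10, None
            for u in range(ng):
                for v in range(ng):
                    if u == v:
                        continue
                    if u in parents[v]:
                        # delete u->v
                        gain = scorer.local(v, frozenset(parents[v] - {u})) - local[v]
                        if gain > best_gain:
                            best_gain, best_move = gain, ("del", u, v)
                        # reverse u->v
                        if (
                            (v, u) not in forb
                            and len(parents[u]) < max_parents
                            and not _reverse_cycles(children, u, v)
                        ):
                            gain = (
                                scorer.local(v, frozenset(parents[v] - {u}))
                                - local[v]
                                + scorer.local(u, frozenset(parents[u] | {v}))
                                - local[u]
                            )
                            if gain > best_gain:
                                best_gain, best_move = gain, ("rev", u, v)
                    else:
                        # add u->v
                        if (
                            (u, v) not in forb
                            and len(parents[v]) < max_parents
                            and not _creates_cycle(children, u, v)
                        ):
                            gain = scorer.local(v, frozenset(parents[v] | {u})) - local[v]
                            if gain > best_gain:
                                best_gain, best_move = gain, ("add", u, v)
            if best_move is None:
                break
            op, u, v = best_move
            if op == "add":
                parents[v].add(u)
                children[u].add(v)
            elif op == "del":
                parents[v].discard(u)
                children[u].discard(v)
            else:
                parents[v].discard(u)
                children[u].discard(v)
                parents[u].add(v)
                children[v].add(u)
            local[v] = scorer.local(v, frozenset(parents[v]))
            local[u] = scorer.local(u, frozenset(parents[u]))
        return sum(local), parents

    def _reverse_cycles(children: list, u: int, v: int) -> bool:
        # after removing u->v, would v->u create a cycle (u reaches v)?
        children[u].discard(v)
        bad = _creates_cycle(children, v, u)
        children[u].add(v)
        return bad

    best_score, best_parents = -np.inf, None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            parents = [set() for _ in range(ng)]
        else:
            parents = _random_dag(ng, forb, max_parents, rng)
        s, p = climb(parents)
        if s > best_score:
            best_score, best_parents = s, p

    g = nx.DiGraph()
    g.add_nodes_from(names)
    for v in range(ng):
        for u in best_parents[v]:
            g.add_edge(names[u], names[v])
    assert nx.is_directed_acyclic_graph(g)
    return g


def _random_dag(ng: int, forb: set, max_parents: int, rng) -> list:
    order = rng.permutation(ng)
    rank = np.empty(ng, dtype=int)
    rank[order] = np.arange(ng)
    parents = [set() for _ in range(ng)]
    for u in range(ng):
        for v in range(ng):
            if u != v and rank[u] < rank[v] and (u, v) not in forb:
                if len(parents[v]) < max_parents and rng.random() < 1.5 / ng:
                    parents[v].add(u)
    return parents


def enumerate_dags(nodes: list):
    """Yield every DAG on the given nodes (tractable for <= 4 nodes)."""
    pairs = list(permutations(nodes, 2))
    for r in range(len(pairs) + 1):
        for edges in combinations(pairs, r):
            if any((v, u) in edges for u, v in edges):
                continue
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            if nx.is_directed_acyclic_graph(g):
                yield g


# ---------------------------------------------------------------------------
# ensemble, consensus, cycles, union
# ---------------------------------------------------------------------------

def build_ensemble(
    expression: pd.DataFrame,
    prior: StructurePrior | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    bootstrap: bool = True,
    **learn_kwargs,
) -> NetworkEnsemble:
    """Learn ``n_runs`` networks with seeds base_seed..base_seed+n_runs-1.

    Each run optionally bootstrap-resamples the samples (default on) before
    structure search, so the ensemble reflects both search and sampling
    variability.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    graphs, seeds = [], []
    n = expression.shape[1]
    for k in range(n_runs):
        run_seed = base_seed + k
        if bootstrap:
            rs = np.random.default_rng(run_seed)
            cols = rs.integers(n, size=n)
            expr_k = expression.iloc[:, cols]
        else:
            expr_k = expression
        graphs.append(learn_network(expr_k, prior=prior, seed=run_seed, **learn_kwargs))
        seeds.append(run_seed)
    return NetworkEnsemble(graphs=graphs, seeds=seeds)


def build_consensus(ensemble: NetworkEnsemble, threshold: float = 0.30) -> ConsensusNetwork:
    """Edges appearing in strictly more than ``threshold`` of runs."""
    if not ensemble.graphs:
        raise ValueError("empty ensemble")
    n_runs = len(ensemble.graphs)
    counts: dict = {}
    for g in ensemble.graphs:
        for e in g.edges():
            counts[e] = counts.get(e, 0) + 1
    cg = nx.DiGraph()
    cg.add_nodes_from(ensemble.graphs[0].nodes)
    for (u, v), c in sorted(counts.items()):
        freq = c / n_runs
        if freq > threshold:
            cg.add_edge(u, v, frequency=freq)
    return ConsensusNetwork(graph=cg, threshold=threshold)


def _shortest_cycle(g: nx.DiGraph):
    """Shortest directed cycle as an edge list, or None (deterministic)."""
    best = None
    for u in sorted(g.nodes):
        # BFS from u over successors; find shortest path back to u
        preds = {u: None}
        frontier = [u]
        found = None
        while frontier and found is None:
            nxt = []
            for x in frontier:
                for y in sorted(g.successors(x)):
                    if y == u:
                        found = x
                        break
                    if y not in preds:
                        preds[y] = x
                        nxt.append(y)
                if found is not None:
                    break
            frontier = nxt
        if found is not None:
            rev = [found]
            x = found
            while preds[x] is not None:
                x = preds[x]
                rev.append(x)
            path = rev[::-1]  # u ... found
            cycle = [(path[i], path[i + 1]) for i in range(len(path) - 1)]
            cycle.append((found, u))
            if best is None or len(cycle) < len(best):
                best = cycle
    return best


def break_cycles(consensus: ConsensusNetwork) -> ConsensusNetwork:
    """Remove, per remaining loop, its most weakly supported edge.

    Cycles are found shortest-first; within a cycle the minimum-frequency
    edge is removed (ties by lexicographically smallest (u, v)).  Removed
    edges are logged on the result.
    """
    g = consensus.graph.copy()
    removed = list(consensus.removed_edges)
    while not nx.is_directed_acyclic_graph(g):
        cycle = _shortest_cycle(g)
        weakest = min(
            cycle, key=lambda e: (g.edges[e].get("frequency", 1.0), e)
        )
        removed.append((weakest[0], weakest[1], g.edges[weakest].get("frequency", 1.0)))
        g.remove_edge(*weakest)
    return ConsensusNetwork(graph=g, threshold=consensus.threshold, removed_edges=removed)


def union_networks(g1: nx.DiGraph, g2: nx.DiGraph, names=("net1", "net2")) -> nx.DiGraph:
    """Node and edge union; shared edges keep max frequency + provenance."""
    out = nx.DiGraph()
    for g, name in ((g1, names[0]), (g2, names[1])):
        out.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            if out.has_edge(u, v):
                prev = out.edges[u, v]
                prev["frequency"] = max(
                    prev.get("frequency", 0.0), data.get("frequency", 0.0)
                )
                prev["provenance"] = prev.get("provenance", []) + [name]
            else:
                out.add_edge(
                    u, v,
                    frequency=data.get("frequency", 0.0),
                    provenance=[name],
                )
    return out
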