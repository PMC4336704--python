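"""Subnetwork extraction, co-regulation permutation test, and enrichment.

Seed-based neighborhoods: a gene set of interest ("seeds") plus all nodes
within undirected shortest distance d induces a subnetwork; d defaults to 2
for small seed sets (< 50 in-network seeds) and 1 otherwise.

Co-regulation: the average unweighted shortest distance over all in-network
pairs of a gene set, compared against same-size uniformly drawn node sets;
the empirical p is the fraction of permuted averages strictly below the
observed one (an add-one corrected variant is available).

Enrichment: one-sided Fisher's exact test (hypergeometric upper tail), its
conservative EASE variant (overlap reduced by one), fold enrichment, a
Bonferroni reporting threshold over tested sets, and a node-label-shuffle
empirical p for subnetwork/gene-set overlaps.

Distances and neighborhoods are always computed on the underlying
undirected graph, also for directed (Bayesian) networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "SubnetworkSpec",
    "CoRegResult",
    "ContingencyTable",
    "EnrichmentResult",
    "choose_depth",
    "extract_subnetwork",
    "avg_shortest_distance",
    "coreg_permutation_test",
    "fisher_exact",
    "ease_score",
    "fold_enrichment",
    "enrich_gene_sets",
    "shuffle_empirical_p",
    "subnetwork_overlap",
]

_FULL_MATRIX_MAX_NODES = 3000


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SubnetworkSpec:
    """Seed set plus neighborhood depth policy."""

    seeds: list
    d: int | None = None          # None -> apply the seed-count rule
    seed_threshold: int = 50

    def __post_init__(self):
        if self.d is not None and self.d not in (0, 1, 2):
            raise ValueError("neighborhood depth d must be 0, 1 or 2")
        if self.seed_threshold < 1:
            raise ValueError("seed threshold must be >= 1")


@dataclass
class CoRegResult:
    """Observed average shortest distance with its permutation null."""

    observed: float
    n_perm: int
    n_below: int
    p: float
    n_pairs: int
    n_disconnected_pairs: int

    def formatted_p(self) -> str:
        if self.p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p:g}"


@dataclass
class ContingencyTable:
    """Overlap counts for enrichment: k of n query genes hit a set of K in N."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"inconsistent overlap k={self.k}, n={self.n}, K={self.K}")
        if self.n > self.N or self.K > self.N:
            raise ValueError("set sizes exceed background size")


@dataclass
class EnrichmentResult:
    set_id: str
    table: ContingencyTable
    fold: float
    fet_p: float
    ease_p: float
    shuffle_p: float | None = None
    reported: bool = False


# ---------------------------------------------------------------------------
# subnetworks and distances
# ---------------------------------------------------------------------------

def choose_depth(seed_count: int, threshold: int = 50) -> int:
    """Neighborhood depth rule: d = 2 below the threshold, else 1."""
    if seed_count < 1:
        raise ValueError("seed count must be >= 1")
    return 2 if seed_count < threshold else 1


def extract_subnetwork(network: nx.Graph, seeds, spec: SubnetworkSpec | None = None) -> nx.Graph:
    """Induced subgraph on seeds plus their d-step undirected neighbors.

    Seeds absent from the network are dropped with a warning; if none
    remain this is an error.  ``spec.d=None`` applies the seed-count rule
    to the number of in-network seeds.
    """
    if spec is None:
        spec = SubnetworkSpec(seeds=list(seeds))
    in_net = [s for s in seeds if s in network]
    dropped = set(seeds) - set(in_net)
    if dropped:
        import warnings

        warnings.warn(f"{len(dropped)} seed(s) not in network; dropped", stacklevel=2)
    if not in_net:
        raise ValueError("no seed present in the network")
    d = spec.d if spec.d is not None else choose_depth(len(in_net), spec.seed_threshold)

    und = network.to_undirected(as_view=False) if network.is_directed() else network
    nodes = set(in_net)
    frontier = set(in_net)
    for _ in range(d):
        nxt = set()
        for x in frontier:
            nxt.update(und.neighbors(x))
        nxt -= nodes
        nodes |= nxt
        frontier = nxt
    return network.subgraph(nodes).copy()


def _distance_matrix(network: nx.Graph):
    """(nodes list, index dict, sparse adjacency) for csgraph BFS."""
    und = network.to_undirected(as_view=True) if network.is_directed() else network
    nodes = list(und.nodes)
    index = {x: i for i, x in enumerate(nodes)}
    rows, cols = [], []
    for u, v in und.edges():
        if u == v:
            continue
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    adj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(nodes), len(nodes))
    )
    return nodes, index, adj


def _mean_pair_distance(D: np.ndarray, idx: np.ndarray):
    """Mean finite pairwise distance among D[idx][:, idx] upper triangle."""
    sub = D[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    finite = np.isfinite(vals)
    n_disc = int((~finite).sum())
    if finite.sum() == 0:
        return np.nan, 0, n_disc
    return float(vals[finite].mean()), int(finite.sum()), n_disc


def avg_shortest_distance(network: nx.Graph, gene_set) -> CoRegResult:
    """Average unweighted shortest distance over in-network pairs of a set.

    Pairs in different components are excluded from the mean and counted.
    Returns a :class:`CoRegResult` with the permutation fields zeroed.
    """
    members = [g for g in gene_set if g in network]
    if len(members) < 2:
        raise ValueError("need at least 2 in-network genes")
    nodes, index, adj = _distance_matrix(network)
    idx = np.array([index[g] for g in members])
    D = shortest_path(adj, method="D", unweighted=True, indices=idx)
    sub = D[:, idx]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    finite = np.isfinite(vals)
    mean = float(vals[finite].mean()) if finite.any() else np.nan
    return CoRegResult(
        observed=mean, n_perm=0, n_below=0, p=np.nan,
        n_pairs=int(finite.sum()), n_disconnected_pairs=int((~finite).sum()),
    )


def coreg_permutation_test(
    network: nx.Graph,
    gene_set,
    n_perm: int = 10_000,
    seed: int = 0,
    add_one: bool = False,
) -> CoRegResult:
    """Permutation test of co-regulation via average shortest distance.

    Draws ``n_perm`` same-size node sets uniformly without replacement and
    counts permuted averages strictly below the observed one; empirical
    p = count / n_perm (or (count+1)/(n_perm+1) with ``add_one``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = [g for g in gene_set if g in network]
    if len(members) < 2:
        raise ValueError("need at least 2 in-network genes")
    rng = np.random.default_rng(seed)
    nodes, index, adj = _distance_matrix(network)
    n_nodes = len(nodes)
    k = len(members)
    idx_obs = np.sort([index[g] for g in members])

    if n_nodes <= _FULL_MATRIX_MAX_NODES:
        D = shortest_path(adj, method="D", unweighted=True).astype(np.float32)
        obs, n_pairs, n_disc = _mean_pair_distance(D, idx_obs)
        below = 0
        for _ in range(n_perm):
            perm = rng.choice(n_nodes, size=k, replace=False)
            m, _, _ = _mean_pair_distance(D, perm)
            if np.isfinite(m) and m < obs:
                below += 1
    else:
        def set_mean(idx):
            Dk = shortest_path(adj, method="D", unweighted=True, indices=idx)
            sub = Dk[:, idx]
            iu = np.triu_indices(len(idx), k=1)
            vals = sub[iu]
            finite = np.isfinite(vals)
            return (
                float(vals[finite].mean()) if finite.any() else np.nan,
                int(finite.sum()),
                int((~finite).sum()),
            )

        obs, n_pairs, n_disc = set_mean(idx_obs)
        below = 0
        for _ in range(n_perm):
            perm = np.sort(rng.choice(n_nodes, size=k, replace=False))
            m, _, _ = set_mean(perm)
            if np.isfinite(m) and m < obs:
                below += 1

    if add_one:
        p = (below + 1) / (n_perm + 1)
    else:
        p = below / n_perm
    return CoRegResult(
        observed=obs, n_perm=n_perm, n_below=below, p=p,
        n_pairs=n_pairs, n_disconnected_pairs=n_disc,
    )


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def fisher_exact(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher's exact p: P(X >= k), X hypergeometric."""
    return float(
        min(1.0, stats.hypergeom.sf(table.k - 1, table.N, table.K, table.n))
    )


def ease_score(table: ContingencyTable) -> float:
    """EASE score: Fisher's exact p after removing one overlapping gene.

    The overlap k is replaced by max(k - 1, 0) with margins unchanged
    (jackknife penalty); k = 0 or 1 gives p = 1.
    """
    k = max(table.k - 1, 0)
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, table.N, table.K, table.n)))


def fold_enrichment(table: ContingencyTable) -> float:
    """(k/n) / (K/N): observed overlap fraction over its null expectation."""
    if table.n == 0 or table.K == 0:
        return np.nan
    return (table.k / table.n) / (table.K / table.N)


def enrich_gene_sets(
    query_set,
    collection: dict,
    background,
    min_size: int = 11,
    max_size: int = 1499,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list:
    """FET/EASE/fold enrichment of a query set against a gene-set collection.

    Sets are filtered to in-background size within [min_size, max_size]
    (the defaults realise an exclusive (10, 1500) window); the reporting
    flag marks sets with FET p below alpha divided by the number of tested
    sets (Bonferroni; ``correction="bh"`` uses Benjamini-Hochberg instead).
    """
    background = set(background)
    query = set(query_set) & background
    if not set(query_set) <= background:
        missing = set(query_set) - background
        if missing == set(query_set):
            raise ValueError("query set disjoint from background")
    N = len(background)
    n = len(query)

    tested = []
    for set_id, members in collection.items():
        inter = set(members) & background
        if not (min_size <= len(inter) <= max_size):
            continue
        tested.append((set_id, inter))
    if not tested:
        return []

    results = []
    for set_id, inter in tested:
        k = len(query & inter)
        table = ContingencyTable(k=k, n=n, K=len(inter), N=N)
        results.append(
            EnrichmentResult(
                set_id=set_id,
                table=table,
                fold=fold_enrichment(table),
                fet_p=fisher_exact(table),
                ease_p=ease_score(table),
            )
        )
    m = len(results)
    if correction == "bonferroni":
        for r in results:
            r.reported = r.fet_p < alpha / m
    elif correction == "bh":
        ps = np.array([r.fet_p for r in results])
        order = np.argsort(ps)
        passed = np.zeros(m, dtype=bool)
        thresh = 0.0
        for rank, i in enumerate(order, start=1):
            if ps[i] <= rank / m * alpha:
                thresh = ps[i]
        passed = ps <= thresh if thresh > 0 else passed
        for r, ok in zip(results, passed):
            r.reported = bool(ok)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results.sort(key=lambda r: (r.fet_p, r.set_id))
    return results


def shuffle_empirical_p(
    network: nx.Graph,
    subnetwork,
    gene_set,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Node-label-shuffle empirical p for a subnetwork / gene-set overlap.

    The subnetwork's node *positions* are held fixed while node labels of
    the whole network are permuted; each permutation re-reads the
    subnetwork under the new labels and recomputes the overlap FET p.
    Empirical p = fraction of permuted p's <= the observed p.
    """
    labels = np.array(list(network.nodes), dtype=object)
    pos_of = {x: i for i, x in enumerate(labels)}
    sub_nodes = set(subnetwork.nodes) if hasattr(subnetwork, "nodes") else set(subnetwork)
    if not sub_nodes <= set(labels):
        raise ValueError("subnetwork nodes not all in network")
    positions = np.array([pos_of[x] for x in sub_nodes])
    gene_set = set(gene_set) & set(labels)
    N = len(labels)
    n = len(sub_nodes)
    K = len(gene_set)

    in_set = np.zeros(N, dtype=bool)
    for g in gene_set:
        in_set[pos_of[g]] = True

    def fet_of_k(k: int) -> float:
        return fisher_exact(ContingencyTable(k=k, n=n, K=K, N=N))

    k_obs = len(sub_nodes & gene_set)
    p_obs = fet_of_k(k_obs)

    rng = np.random.default_rng(seed)
    p_cache = {k_obs: p_obs}
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        # node at position i now carries label labels[perm[i]]
        k = int(in_set[perm[positions]].sum())
        if k not in p_cache:
            p_cache[k] = fet_of_k(k)
        if p_cache[k] <= p_obs:
            count += 1
    return count / n_perm


def subnetwork_overlap(subA, subB, background) -> EnrichmentResult:
    """FET/EASE/fold overlap of two subnetworks against a background."""
    a = set(subA.nodes) if hasattr(subA, "nodes") else set(subA)
    b = set(subB.nodes) if hasattr(subB, "nodes") else set(subB)
    if not a or not b:
        raise ValueError("empty subnetwork")
    bg = set(background.nodes) if hasattr(background, "nodes") else set(background)
    if not (a <= bg and b <= bg):
        raise ValueError("subnetworks must lie within the background")
    table = ContingencyTable(k=len(a & b), n=len(a), K=len(b), N=len(bg))
    return EnrichmentResult(
        set_id="overlap",
        table=table,
        fold=fold_enrichment(table),
        fet_p=fisher_exact(table),
        ease_p=ease_score(table),
    )


def enrichment_to_frame(results: list) -> pd.DataFrame:
    """Flatten enrichment results to the standard output table."""
    rows = [
        {
            "set_id": r.set_id,
            "k": r.table.k,
            "n": r.table.n,
            "K": r.table.K,
            "N": r.table.N,
            "fold": r.fold,
            "fet_p": r.fet_p,
            "ease_p": r.ease_p,
            "shuffle_p": r.shuffle_p,
            "reported": r.reported,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["set_id", "k", "n", "K", "N", "fold", "fet_p", "ease_p", "shuffle_p", "reported"],
    )
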