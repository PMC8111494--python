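"""Two-stage clustering of the scored interaction network.

The scored network is thresholded, dense overlapping regions are found by
greedy cohesiveness maximization on the unweighted graph (ClusterOne-style:
cohesiveness f(V) = w_in / (w_in + w_bound + penalty*|V|)), and each dense
region is re-partitioned by Markov clustering (MCL) on its weighted
subgraph.  Members lacking any supra-threshold within-cluster edge are
then dropped.  Sweeping (threshold, density, overlap, inflation) over a
grid and scoring each clustering with the k-clique precision/recall gives
a precision-ranked family of clusterings; five are selected and unioned
into a final map with confidence tiers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import ComplexSet, ScoredNetwork, TIER_NAMES
from .kclique_eval import weighted_kpr

# Sweep grids (score thresholds descending; the product is 2,835 combos).
DEFAULT_SCORE_THRESHOLDS = (
    1.0, 0.99, 0.97, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1,
    0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001,
)
DEFAULT_MAX_OVERLAPS = (0.6, 0.7, 0.8)
DEFAULT_DENSITIES = (0.1, 0.2, 0.3, 0.35, 0.4)
DEFAULT_INFLATIONS = (1.2, 2, 3, 4, 5, 7, 9, 11, 15)


@dataclass(frozen=True)
class ClusteringParams:
    """One point of the two-stage clustering parameter space."""

    score_threshold: float
    c1_density: float = 0.3
    c1_max_overlap: float = 0.8
    mcl_inflation: float = 2.0
    c1_penalty: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0,1]")
        if self.c1_density <= 0 or self.c1_max_overlap <= 0 or self.c1_penalty < 0:
            raise ValueError("ClusterOne parameters must be positive")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")


# Confidence-ranked parameter sets selected for the published full-scale
# map, highest precision first: (threshold, density, overlap, inflation).
DEFAULT_SELECTED_PARAMS = (
    ClusteringParams(1.0, 0.4, 0.6, 9),
    ClusteringParams(0.7, 0.4, 0.6, 9),
    ClusteringParams(0.5, 0.4, 0.7, 4),
    ClusteringParams(0.04, 0.4, 0.7, 2),
    ClusteringParams(0.02, 0.1, 0.6, 2),
)


def threshold_network(scores: ScoredNetwork, t: float) -> nx.Graph:
    """Keep edges with score >= t; isolated nodes are dropped (nodes only
    exist through surviving edges)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    g = nx.Graph()
    for (a, b), s in scores.items():
        if s >= t:
            g.add_edge(a, b, weight=s)
    if g.number_of_edges() == 0:
        warnings.warn(f"thresholding at {t} left an empty graph", stacklevel=2)
    return g


def _cohesiveness(w_in: float, w_bound: float, size: int, penalty: float) -> float:
    denom = w_in + w_bound + penalty * size
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(graph: nx.Graph, seed_node, penalty: float) -> frozenset:
    """Greedy grow/shrink from a seed, accepting only strict cohesiveness
    increases; unit edge weights."""
    cluster = {seed_node}
    w_in = 0.0
    w_bound = float(graph.degree(seed_node))
    coh = _cohesiveness(w_in, w_bound, 1, penalty)
    while True:
        best_move = None  # (new_coh, kind, node, new_w_in, new_w_bound)
        # candidate additions: neighbors of the cluster
        frontier = set()
        for v in cluster:
            frontier.update(graph.neighbors(v))
        frontier -= cluster
        for v in sorted(frontier):
            inside = sum(1 for u in graph.neighbors(v) if u in cluster)
            outside = graph.degree(v) - inside
            nw_in = w_in + inside
            nw_bound = w_bound - inside + outside
            nc = _cohesiveness(nw_in, nw_bound, len(cluster) + 1, penalty)
            if nc > coh and (best_move is None or nc > best_move[0]):
                best_move = (nc, "add", v, nw_in, nw_bound)
        # candidate removals (never drop the seed or go below 1)
        if len(cluster) > 1:
            for v in sorted(cluster):
                if v == seed_node:
                    continue
                inside = sum(1 for u in graph.neighbors(v) if u in cluster)
                outside = graph.degree(v) - inside
                nw_in = w_in - inside
                nw_bound = w_bound + inside - outside
                nc = _cohesiveness(nw_in, nw_bound, len(cluster) - 1, penalty)
                if nc > coh and (best_move is None or nc > best_move[0]):
                    best_move = (nc, "remove", v, nw_in, nw_bound)
        if best_move is None:
            return frozenset(cluster)
        coh, kind, v, w_in, w_bound = best_move
        if kind == "add":
            cluster.add(v)
        else:
            cluster.remove(v)


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _merge_overlapping(clusters: list[frozenset], max_overlap: float) -> list[frozenset]:
    """Union clusters whose overlap score omega = |A∩B|^2/(|A||B|) reaches
    ``max_overlap``; repeated to a fixed point (each round strictly
    decreases the cluster count, so this terminates)."""
    current = sorted(set(clusters), key=lambda c: (-len(c), sorted(c)))
    changed = True
    while changed:
        changed = False
        out: list[frozenset] = []
        for c in current:
            merged = False
            for i, kept in enumerate(out):
                if _overlap_score(c, kept) >= max_overlap:
                    out[i] = kept | c
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(c)
        current = sorted(set(out), key=lambda c: (-len(c), sorted(c)))
    return current


def _density(graph: nx.Graph, nodes: frozenset) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    e = graph.subgraph(nodes).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def cluster_one(
    graph: nx.Graph,
    density_threshold: float = 0.3,
    max_overlap: float = 0.8,
    penalty: float = 2.0,
    min_size: int = 3,
) -> list[frozenset]:
    """Greedy cohesiveness clustering of the (unweighted) graph.

    Seeds are taken in descending degree order, skipping nodes already
    covered by a grown cluster.  Overlapping clusters merge at overlap
    score >= ``max_overlap``; clusters below ``density_threshold`` or
    ``min_size`` are discarded.
    """
    if graph.number_of_nodes() == 0:
        return []
    seeds = sorted(graph.nodes, key=lambda v: (-graph.degree(v), v))
    covered: set = set()
    raw: list[frozenset] = []
    for s in seeds:
        if s in covered:
            continue
        c = _grow_cluster(graph, s, penalty)
        raw.append(c)
        covered |= c
    merged = _merge_overlapping(raw, max_overlap)
    return [
        c
        for c in merged
        if len(c) >= min_size and _density(graph, c) >= density_threshold
    ]


def mcl(
    subgraph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_floor: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    stochasticity_log: list | None = None,
) -> list[frozenset]:
    """Markov clustering of a weighted subgraph.

    The column-stochastic flow matrix is iterated (expand: matrix power;
    inflate: entrywise power + renormalize; prune entries < prune_floor)
    to convergence; clusters are the connected components of the limit
    flow.  Self-loops with weight equal to the node's maximum incident
    weight are added before normalization.  ``stochasticity_log``, when
    given, collects the max deviation of column sums from 1 after every
    inflation step.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(subgraph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    if n == 1:
        return [frozenset(nodes)]
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in subgraph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M = M / M.sum(axis=0, keepdims=True)
        if stochasticity_log is not None:
            stochasticity_log.append(float(np.abs(M.sum(axis=0) - 1.0).max()))
        M[M < prune_floor] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning current partition", stacklevel=2)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rs, cs = np.nonzero(M)
    support.add_edges_from(zip(rs.tolist(), cs.tolist()))
    return [frozenset(nodes[i] for i in comp) for comp in nx.connected_components(support)]


def two_stage_cluster(scores: ScoredNetwork, params: ClusteringParams) -> list[frozenset]:
    """Threshold -> ClusterOne (unweighted) -> MCL per dense region
    (weighted) -> post-filter.

    The post-filter removes cluster members with no within-cluster edge
    scoring at or above the threshold, then drops clusters below size 2.
    Output order is deterministic (size descending, then members).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = threshold_network(scores, params.score_threshold)
    dense = cluster_one(
        graph,
        density_threshold=params.c1_density,
        max_overlap=params.c1_max_overlap,
        penalty=params.c1_penalty,
    )
    clusters: list[frozenset] = []
    for region in dense:
        sub = graph.subgraph(region)
        clusters.extend(mcl(sub, inflation=params.mcl_inflation))

    filtered: list[frozenset] = []
    for c in clusters:
        keep = set()
        for v in c:
            for u in c:
                if u != v and graph.has_edge(u, v) and graph[u][v]["weight"] >= params.score_threshold:
                    keep.add(v)
                    break
        if len(keep) >= 2:
            filtered.append(frozenset(keep))
    uniq = sorted(set(filtered), key=lambda c: (-len(c), sorted(c)))
    return uniq


def parameter_sweep(
    scores: ScoredNetwork,
    train_complexes: ComplexSet,
    score_thresholds: tuple[float, ...] = DEFAULT_SCORE_THRESHOLDS,
    max_overlaps: tuple[float, ...] = DEFAULT_MAX_OVERLAPS,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    inflations: tuple[float, ...] = DEFAULT_INFLATIONS,
    max_samples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every parameter combination with the k-clique weighted
    precision/recall against the training complexes.

    Returns one row per combination with columns for every parameter plus
    kpr_precision / kpr_recall / n_clusters.  The ClusterOne stage is
    shared across inflations of the same (threshold, density, overlap).
    """
    if not (score_thresholds and max_overlaps and densities and inflations):
        raise ValueError("all parameter grids must be non-empty")
    rows = []
    for t, d, o in itertools.product(score_thresholds, densities, max_overlaps):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = threshold_network(scores, t)
        dense = cluster_one(graph, density_threshold=d, max_overlap=o)
        for infl in inflations:
            params = ClusteringParams(t, d, o, infl)
            clusters: list[frozenset] = []
            for region in dense:
                clusters.extend(mcl(graph.subgraph(region), inflation=infl))
            filtered = []
            for c in clusters:
                keep = {
                    v
                    for v in c
                    if any(
                        graph.has_edge(u, v) and graph[u][v]["weight"] >= t
                        for u in c
                        if u != v
                    )
                }
                if len(keep) >= 2:
                    filtered.append(frozenset(keep))
            uniq = sorted(set(filtered), key=lambda c: (-len(c), sorted(c)))
            if uniq:
                res = weighted_kpr(
                    ComplexSet(uniq), train_complexes, max_samples=max_samples, seed=seed
                )
                prec, rec = res.p_weighted, res.r_weighted
            else:
                prec, rec = float("nan"), 0.0
            rows.append(
                {
                    "score_threshold": t,
                    "c1_density": d,
                    "c1_max_overlap": o,
                    "mcl_inflation": infl,
                    "kpr_precision": prec,
                    "kpr_recall": rec,
                    "n_clusters": len(uniq),
                }
            )
    return pd.DataFrame(rows)


def select_tiers(sweep: pd.DataFrame, n_tiers: int = 5) -> list[ClusteringParams]:
    """Pick ``n_tiers`` parameter sets along the precision/recall Pareto
    front, ordered from highest precision (lowest recall) to lowest.

    A deterministic stand-in for the by-eye selection a practitioner makes
    on the sweep scatter: the front is computed over non-empty clusterings
    and sampled evenly.
    """
    ok = sweep.dropna(subset=["kpr_precision"])
    ok = ok[ok["n_clusters"] > 0]
    if ok.empty:
        raise ValueError("sweep produced no non-empty clusterings")
    ok = ok.sort_values(["kpr_precision", "kpr_recall"], ascending=[False, False])
    front = []
    best_recall = -1.0
    for _, row in ok.iterrows():
        if row["kpr_recall"] > best_recall:
            front.append(row)
            best_recall = row["kpr_recall"]
    picks = np.unique(np.linspace(0, len(front) - 1, min(n_tiers, len(front))).round().astype(int))
    chosen = [front[i] for i in picks]
    return [
        ClusteringParams(
            float(r["score_threshold"]),
            float(r["c1_density"]),
            float(r["c1_max_overlap"]),
            float(r["mcl_inflation"]),
        )
        for r in chosen
    ]


def select_and_union(
    scores: ScoredNetwork,
    selected_params: tuple[ClusteringParams, ...] = DEFAULT_SELECTED_PARAMS,
) -> ComplexSet:
    """Run the two-stage clustering at each selected parameter set
    (ordered highest precision first) and union the results.

    An identical member set appearing in several tiers is kept once at
    its highest-confidence tier; near-duplicates are all kept.
    """
    tier_names = list(TIER_NAMES[: len(selected_params)])
    if len(selected_params) > len(TIER_NAMES):
        tier_names += [f"Tier{i + 1}" for i in range(len(TIER_NAMES), len(selected_params))]
    seen: set[frozenset] = set()
    complexes: list[frozenset] = []
    tiers: list[str] = []
    for name, params in zip(tier_names, selected_params):
        for c in two_stage_cluster(scores, params):
            if c in seen:
                continue
            seen.add(c)
            complexes.append(c)
            tiers.append(name)
    return ComplexSet(complexes, tiers=tiers)
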