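"""Overlapping functional-cluster (FC) detection on decay-weighted networks.

A functional cluster is a module of transcripts and mass features whose
abundance patterns cohere across samples. Detection follows the greedy
cohesiveness-growth scheme of overlapping graph clustering: the quality of
a node set C is

    f(C) = w_in(C) / (w_in(C) + w_bound(C) + penalty * |C|)

where w_in is the total weight of edges inside C and w_bound the total
weight of edges crossing the boundary. Clusters are grown from seeds in
descending weighted-degree order, greedily adding/removing the single node
that most improves f, and highly overlapping candidates (overlap score
omega(A, B) = |A n B|^2 / (|A| |B|) above a threshold) are merged.

Each cluster gets a p-value from a one-sided rank-sum comparison of its
internal edge weights against the weights of edges radiating out of it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PENALTY = 2.0
DEFAULT_OVERLAP_THRESHOLD = 0.8
DEFAULT_MIN_SIZE = 3

TRANSCRIPT = "transcript"
FEATURE = "feature"


@dataclass
class FunctionalCluster:
    """An overlapping cluster of typed nodes with its quality scores."""

    cluster_id: int
    members: frozenset  # of (kind, node_id) tuples
    decay_rate: int | None = None
    cohesiveness: float = float("nan")
    p_value: float = float("nan")
    source_ids: tuple[int, ...] = ()

    @property
    def transcripts(self) -> set:
        return {n for k, n in self.members if k == TRANSCRIPT}

    @property
    def features(self) -> set:
        return {n for k, n in self.members if k == FEATURE}

    def __len__(self) -> int:
        return len(self.members)


def network_graph(edges: pd.DataFrame) -> nx.Graph:
    """Build the bipartite weighted graph from an edge table with a
    ``weight`` column (transcript_id / feature_id ends are typed)."""
    g = nx.Graph()
    for t, f, w in edges[["transcript_id", "feature_id", "weight"]].itertuples(index=False):
        g.add_edge((TRANSCRIPT, t), (FEATURE, f), weight=float(w))
    return g


def cohesiveness(graph: nx.Graph, members: set, penalty: float = DEFAULT_PENALTY) -> float:
    """f(C) = w_in / (w_in + w_bound + penalty * |C|)."""
    if not members:
        return 0.0
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        if u not in graph:
            continue
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2.0  # counted from both ends
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(graph: nx.Graph, seed, penalty: float) -> set:
    members = {seed}
    score = cohesiveness(graph, members, penalty)
    while True:
        boundary = sorted(
            {v for u in members for v in graph[u] if v not in members}
        )
        best_delta, best_move = 0.0, None
        for v in boundary:
            s = cohesiveness(graph, members | {v}, penalty)
            if s - score > best_delta + 1e-12:
                best_delta, best_move = s - score, ("add", v)
        if len(members) > 1:
            for v in sorted(members):
                s = cohesiveness(graph, members - {v}, penalty)
                if s - score > best_delta + 1e-12:
                    best_delta, best_move = s - score, ("remove", v)
        if best_move is None:
            return members
        op, v = best_move
        members = members | {v} if op == "add" else members - {v}
        score += best_delta


def overlap_score(a: frozenset, b: frozenset) -> float:
    """omega(A, B) = |A n B|^2 / (|A| |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b)) if a and b else 0.0


def _merge_overlapping(candidates: list[frozenset], threshold: float) -> list[frozenset]:
    """Iteratively union candidate sets whose overlap score >= threshold."""
    sets = [set(c) for c in candidates]
    changed = True
    while changed:
        changed = False
        out: list[set] = []
        for s in sets:
            for o in out:
                if overlap_score(frozenset(s), frozenset(o)) >= threshold:
                    o |= s
                    changed = True
                    break
            else:
                out.append(set(s))
        sets = out
    return [frozenset(s) for s in sets]


def detect_clusters(
    graph: nx.Graph,
    min_size: int = DEFAULT_MIN_SIZE,
    penalty: float = DEFAULT_PENALTY,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    decay_rate: int | None = None,
    require_mixed: bool = True,
    compute_pvalues: bool = True,
) -> list[FunctionalCluster]:
    """Greedy cohesiveness clustering; deterministic for a given network.

    Seeds are taken from yet-unclustered nodes in descending weighted-degree
    order (ties broken by node id). Candidates with pairwise overlap score
    >= ``overlap_threshold`` are merged; clusters smaller than ``min_size``
    are discarded. With ``require_mixed`` only clusters containing at least
    one transcript and one feature are reported (the FC definition); pure
    clusters can be retained for coexpression-based merging.
    """
    if graph.number_of_nodes() == 0:
        return []
    wdeg = {n: sum(d.get("weight", 1.0) for d in graph[n].values()) for n in graph}
    order = sorted(graph.nodes, key=lambda n: (-wdeg[n], n))
    used: set = set()
    candidates: list[frozenset] = []
    for seed in order:
        if seed in used or wdeg[seed] == 0:
            continue
        members = _grow_cluster(graph, seed, penalty)
        used |= members
        candidates.append(frozenset(members))
    merged = _merge_overlapping(candidates, overlap_threshold)
    merged = [m for m in merged if len(m) >= min_size]
    if require_mixed:
        merged = [
            m
            for m in merged
            if any(k == TRANSCRIPT for k, _ in m) and any(k == FEATURE for k, _ in m)
        ]
    merged.sort(key=lambda m: tuple(sorted(m)))
    clusters = []
    for i, m in enumerate(merged, start=1):
        fc = FunctionalCluster(
            cluster_id=i,
            members=m,
            decay_rate=decay_rate,
            cohesiveness=cohesiveness(graph, set(m), penalty),
        )
        if compute_pvalues:
            fc.p_value = cluster_pvalue(fc, graph)
        clusters.append(fc)
    return clusters


def cluster_pvalue(cluster: FunctionalCluster, graph: nx.Graph) -> float:
    """One-sided rank-sum p for internal edge weights exceeding boundary ones.

    With no boundary edges the cluster is perfectly separated; the p-value
    is set to 0.0 (the minimum representable configuration) by convention.
    """
    internal, boundary = [], []
    members = cluster.members
    for u in members:
        if u not in graph:
            continue
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                if u < v:  # count undirected internal edges once
                    internal.append(w)
            else:
                boundary.append(w)
    if not internal:
        return 1.0
    if not boundary:
        return 0.0
    if len(set(internal) | set(boundary)) == 1:
        return 1.0  # no separation at all under the tie convention
    res = stats.mannwhitneyu(internal, boundary, alternative="greater")
    return float(res.pvalue)


def merge_shared_feature_clusters(clusters: list[FunctionalCluster]) -> list[FunctionalCluster]:
    """Union-find merge of clusters connected by >= 1 shared mass feature.

    Members are unioned transitively; provenance (source cluster ids) is
    retained. Idempotent: merged output shares no features across clusters.
    """
    return _merge_by_relation(
        clusters,
        lambda a, b: bool(a.features & b.features),
    )


def coexpression_merge(
    clusters: list[FunctionalCluster],
    expr_network: pd.DataFrame,
    min_weight: float,
) -> list[FunctionalCluster]:
    """Additionally merge clusters linked by a transcript-transcript
    coexpression edge of weight >= min_weight between their members."""
    strong = expr_network[expr_network["weight"] >= min_weight]
    links: dict[str, set[str]] = {}
    for a, b in strong[["transcript_a", "transcript_b"]].itertuples(index=False):
        links.setdefault(a, set()).add(b)
        links.setdefault(b, set()).add(a)

    def linked(a: FunctionalCluster, b: FunctionalCluster) -> bool:
        ta, tb = a.transcripts, b.transcripts
        return any(links.get(t, set()) & tb for t in ta)

    return _merge_by_relation(clusters, linked)


def _merge_by_relation(clusters: list[FunctionalCluster], related) -> list[FunctionalCluster]:
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if related(clusters[i], clusters[j]):
            parent[find(i)] = find(j)
    groups: dict[int, list[FunctionalCluster]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(clusters[i])
    out = []
    for new_id, group in enumerate(sorted(groups.values(), key=lambda g: g[0].cluster_id), 1):
        members = frozenset().union(*(c.members for c in group))
        sources = tuple(
            sorted({s for c in group for s in (c.source_ids or (c.cluster_id,))})
        )
        out.append(
            FunctionalCluster(
                cluster_id=new_id,
                members=members,
                decay_rate=group[0].decay_rate if len({c.decay_rate for c in group}) == 1 else None,
                cohesiveness=float("nan"),
                p_value=min(c.p_value for c in group),
                source_ids=sources,
            )
        )
    return out


def clusters_to_frame(clusters: list[FunctionalCluster]) -> pd.DataFrame:
    """Long-format member table (one row per cluster member) for the store."""
    rows = []
    for c in clusters:
        for kind, node in sorted(c.members):
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "decay_rate": c.decay_rate,
                    "kind": kind,
                    "node_id": node,
                    "cohesiveness": c.cohesiveness,
                    "p_value": c.p_value,
                    "source_ids": ";".join(map(str, c.source_ids)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "decay_rate", "kind", "node_id",
            "cohesiveness", "p_value", "source_ids",
        ],
    )


def clusters_from_frame(df: pd.DataFrame) -> list[FunctionalCluster]:
    out = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        first = grp.iloc[0]
        members = frozenset((k, n) for k, n in grp[["kind", "node_id"]].itertuples(index=False))
        dr = first["decay_rate"]
        sources = tuple(
            int(s) for s in str(first["source_ids"]).split(";") if s not in ("", "nan")
        )
        out.append(
            FunctionalCluster(
                cluster_id=int(cid),
                members=members,
                decay_rate=None if pd.isna(dr) else int(dr),
                cohesiveness=(
                    float("nan") if pd.isna(first["cohesiveness"])
                    else float(first["cohesiveness"])
                ),
                p_value=(
                    float("nan") if pd.isna(first["p_value"]) else float(first["p_value"])
                ),
                source_ids=sources,
            )
        )
    return out
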