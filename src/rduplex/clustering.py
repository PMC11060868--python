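"""Clustering of chimeric duplexes that evidence the same in-vivo helix.

Crosslinking and random fragmentation make many reads redundant: fragments
of the same duplex in different molecules yield chimeras with overlapping
arms and near-identical gap lengths g (the nucleotides strictly between the
left arm's end and the right arm's start).  Duplexes are linked in a graph
when their arms overlap and their g values differ by at most ``max_gap_diff``
(edge weight 1/(1+|dg|)), communities are found by short random walks
(walktrap, walk length 2 by default) cut at maximum modularity, and each
community's footprints are trimmed to the positions with majority read
coverage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import igraph as ig
import numpy as np
import pandas as pd

from .contact_maps import footprint_matrix, make_contact_matrix
from .io import Duplex, DuplexDataSet, Interval

__all__ = [
    "GapGraph",
    "DuplexCluster",
    "gap_value",
    "build_gap_graph",
    "walktrap_communities",
    "cluster_duplexes",
    "trim_clusters",
    "cluster_agreement",
    "modularity",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP_DIFF = 10
DEFAULT_MIN_CLUSTER_SIZE = 2
DEFAULT_TRIM_QUANTILE = 0.5
WALKTRAP_STEPS = 2


@dataclass
class GapGraph:
    """Weighted undirected graph over duplex read ids."""

    vertices: list[str]
    edges: list[tuple[str, str]]
    weights: list[float]

    def __post_init__(self) -> None:
        for (u, v), w in zip(self.edges, self.weights):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if not (0 < w <= 1):
                raise ValueError(f"edge weight {w} outside (0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DuplexCluster:
    cluster_id: str
    sampleName: str
    member_ids: frozenset[str]
    L_footprint: Interval
    R_footprint: Interval
    trimmed: bool = False
    trim_fallback: bool = False

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def gap(self) -> int:
        return max(0, self.R_footprint.start - self.L_footprint.end - 1)


def gap_value(d: Duplex) -> int:
    """Nucleotides strictly between the arms: g = R.start - L.end - 1.

    Overlapping arms (R.start <= L.end) clamp to 0.
    """
    g = d.R.start - d.L.end - 1
    if g < 0:
        log.debug("read %s: overlapping arms, g clamped to 0", d.read_id)
        return 0
    return g


def build_gap_graph(
    duplexes: list[Duplex], max_gap_diff: int = DEFAULT_MAX_GAP_DIFF
) -> GapGraph:
    """Link duplexes whose arms overlap and whose g values are similar.

    Edge (u, v) exists iff the L intervals overlap by >= 1 nt, the R
    intervals overlap by >= 1 nt, and |g(u) - g(v)| <= max_gap_diff; the
    weight is 1 / (1 + |g(u) - g(v)|).
    """
    duplexes = sorted(duplexes, key=lambda d: d.read_id)
    gaps = {d.read_id: gap_value(d) for d in duplexes}
    edges: list[tuple[str, str]] = []
    weights: list[float] = []
    # sweep over L-interval overlaps to avoid the full quadratic scan
    by_l_start = sorted(duplexes, key=lambda d: (d.L.start, d.read_id))
    for a_idx, u in enumerate(by_l_start):
        for v in by_l_start[a_idx + 1 :]:
            if v.L.start > u.L.end:
                break
            if not u.R.overlaps(v.R):
                continue
            dg = abs(gaps[u.read_id] - gaps[v.read_id])
            if dg > max_gap_diff:
                continue
            e = tuple(sorted((u.read_id, v.read_id)))
            edges.append(e)
            weights.append(1.0 / (1.0 + dg))
    order = np.argsort(
        np.array([f"{u}\t{v}" for u, v in edges], dtype=object), kind="stable"
    ) if edges else []
    return GapGraph(
        vertices=[d.read_id for d in duplexes],
        edges=[edges[i] for i in order],
        weights=[weights[i] for i in order],
    )


def modularity(
    membership: dict[str, int], graph: GapGraph
) -> float:
    """Weighted Newman modularity of a vertex partition."""
    w_total = sum(graph.weights)
    if w_total == 0:
        return 0.0
    w_in: dict[int, float] = {}
    degree: dict[str, float] = {v: 0.0 for v in graph.vertices}
    for (u, v), w in zip(graph.edges, graph.weights):
        degree[u] += w
        degree[v] += w
        if membership[u] == membership[v]:
            w_in[membership[u]] = w_in.get(membership[u], 0.0) + w
    q = 0.0
    communities = set(membership.values())
    for c in communities:
        d_c = sum(degree[v] for v in graph.vertices if membership[v] == c)
        q += w_in.get(c, 0.0) / w_total - (d_c / (2.0 * w_total)) ** 2
    return q


def walktrap_communities(graph: GapGraph, steps: int = WALKTRAP_STEPS) -> list[set[str]]:
    """Random-walk (walktrap) communities, cut at maximum modularity.

    The agglomerative merge sequence comes from igraph's walktrap with walk
    length ``steps``; every cut level of the dendrogram is then scored with
    the weighted modularity of the *full* graph and the best level is kept
    (ties broken toward fewer merges).  Isolated vertices form singleton
    communities.  Deterministic for a fixed graph.
    """
    if graph.n_vertices == 0:
        return []
    if graph.n_edges == 0:
        return [{v} for v in graph.vertices]
    idx = {v: i for i, v in enumerate(graph.vertices)}
    g = ig.Graph(
        n=graph.n_vertices, edges=[(idx[u], idx[v]) for u, v in graph.edges]
    )
    g.es["weight"] = graph.weights
    dendro = g.community_walktrap(weights="weight", steps=steps)
    merges = dendro.merges
    # replay the merge sequence, scoring every cut level incrementally:
    # Q = sum_c [ w_in(c)/W - (d(c)/2W)^2 ]
    w_total = sum(graph.weights)
    w_in: dict[int, float] = {i: 0.0 for i in range(graph.n_vertices)}
    deg: dict[int, float] = {i: 0.0 for i in range(graph.n_vertices)}
    between: dict[int, dict[int, float]] = {i: {} for i in range(graph.n_vertices)}
    for (u, v), w in zip(graph.edges, graph.weights):
        iu, iv = idx[u], idx[v]
        deg[iu] += w
        deg[iv] += w
        between[iu][iv] = between[iu].get(iv, 0.0) + w
        between[iv][iu] = between[iv].get(iu, 0.0) + w
    q = -sum((d / (2.0 * w_total)) ** 2 for d in deg.values())
    groups: dict[int, set[int]] = {i: {i} for i in range(graph.n_vertices)}
    best_q, best_level = q, 0
    next_id = graph.n_vertices
    for level, (a, b) in enumerate(merges, start=1):
        cross = between[a].pop(b, 0.0)
        between[b].pop(a, None)
        q -= (
            w_in[a] / w_total
            - (deg[a] / (2.0 * w_total)) ** 2
            + w_in[b] / w_total
            - (deg[b] / (2.0 * w_total)) ** 2
        )
        w_in[next_id] = w_in.pop(a) + w_in.pop(b) + cross
        deg[next_id] = deg.pop(a) + deg.pop(b)
        nbrs: dict[int, float] = between.pop(a)
        for c, w in between.pop(b).items():
            nbrs[c] = nbrs.get(c, 0.0) + w
        between[next_id] = nbrs
        for c, w in nbrs.items():
            between[c].pop(a, None)
            between[c].pop(b, None)
            between[c][next_id] = w
        q += w_in[next_id] / w_total - (deg[next_id] / (2.0 * w_total)) ** 2
        groups[next_id] = groups.pop(a) | groups.pop(b)
        next_id += 1
        if q > best_q + 1e-12:
            best_q, best_level = q, level
    # rebuild the partition at the best cut level
    groups = {i: {i} for i in range(graph.n_vertices)}
    next_id = graph.n_vertices
    for a, b in merges[:best_level]:
        groups[next_id] = groups.pop(a) | groups.pop(b)
        next_id += 1
    out = [{graph.vertices[i] for i in members} for members in groups.values()]
    # deterministic order: by smallest member read id
    return sorted(out, key=lambda s: min(s))


def _footprints(duplexes: list[Duplex]) -> tuple[Interval, Interval]:
    l = Interval(min(d.L.start for d in duplexes), max(d.L.end for d in duplexes))
    r = Interval(min(d.R.start for d in duplexes), max(d.R.end for d in duplexes))
    return l, r


def cluster_duplexes(
    ds: DuplexDataSet,
    max_gap_diff: int = DEFAULT_MAX_GAP_DIFF,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    steps: int = WALKTRAP_STEPS,
) -> DuplexDataSet:
    """Cluster each sample's intra-RNA duplexes; populate raw cluster tables.

    Communities smaller than ``min_cluster_size`` are discarded; raw
    footprints are the min-max spans of member arms.  Cluster-level contact
    matrices (kind "cluster", built from member duplexes) are added to the
    matrix list.  Modifies ``ds`` in place and returns it.
    """
    tx_len = ds.rna_length
    for s in ds.sample_names:
        duplexes = ds.intra_duplexes(s)
        by_id = {d.read_id: d for d in duplexes}
        graph = build_gap_graph(duplexes, max_gap_diff=max_gap_diff)
        communities = walktrap_communities(graph, steps=steps)
        clusters: list[DuplexCluster] = []
        retained: list[Duplex] = []
        for k, members in enumerate(communities):
            if len(members) < min_cluster_size:
                continue
            mem = [by_id[m] for m in sorted(members)]
            lfp, rfp = _footprints(mem)
            clusters.append(
                DuplexCluster(
                    cluster_id=f"{s}.c{len(clusters) + 1}",
                    sampleName=s,
                    member_ids=frozenset(members),
                    L_footprint=lfp,
                    R_footprint=rfp,
                )
            )
            retained.extend(mem)
        ds.clusterTableList.setdefault(s, {})["raw"] = clusters
        ds.clusterCoords = [c for c in ds.clusterCoords if c["sampleName"] != s] + [
            {
                "cluster_id": c.cluster_id,
                "sampleName": s,
                "tx_id": ds.rna_id,
                "L_start": c.L_footprint.start,
                "L_end": c.L_footprint.end,
                "R_start": c.R_footprint.start,
                "R_end": c.R_footprint.end,
            }
            for c in clusters
        ]
        ds.matrixList.setdefault(s, {})["cluster"] = make_contact_matrix(
            retained, tx_len, tx_id=ds.rna_id, kind="cluster"
        )
    return ds


def _trim_side(
    intervals: list[Interval], quantile: float
) -> tuple[Interval, bool]:
    """Maximal contiguous run of positions with coverage >= quantile * max."""
    start = min(iv.start for iv in intervals)
    end = max(iv.end for iv in intervals)
    cov = np.zeros(end - start + 1, dtype=np.int64)
    for iv in intervals:
        cov[iv.start - start : iv.end - start + 1] += 1
    threshold = quantile * cov.max()
    keep = cov >= threshold
    best_len, best_run = 0, None
    run_start = None
    for i, k in enumerate(list(keep) + [False]):
        if k and run_start is None:
            run_start = i
        elif not k and run_start is not None:
            if i - run_start > best_len:
                best_len, best_run = i - run_start, (run_start, i - 1)
            run_start = None
    if best_run is None:
        # threshold emptied the side: fall back to the modal exact interval
        mode = max(
            ((iv, intervals.count(iv)) for iv in intervals), key=lambda t: (t[1], -len(t[0]))
        )[0]
        return mode, True
    return Interval(start + best_run[0], start + best_run[1]), False


def trim_clusters(
    ds: DuplexDataSet, trim_quantile: float = DEFAULT_TRIM_QUANTILE
) -> DuplexDataSet:
    """Trim cluster footprints to the regions with the most read evidence.

    Per cluster and per side, positions covered by >= ``trim_quantile`` x
    the side's maximum coverage are kept; the trimmed footprint is the
    longest such contiguous run (always a subset of the raw footprint).
    Trimmed contact matrices (kind "trimmed", footprint rectangles weighted
    by cluster size) are added.  Modifies ``ds`` in place and returns it.
    """
    if not 0 < trim_quantile <= 1:
        raise ValueError(f"trim_quantile must be in (0, 1], got {trim_quantile}")
    for s in ds.sample_names:
        tables = ds.clusterTableList.get(s)
        if not tables or "raw" not in tables:
            raise ValueError(f"no raw clusters for sample {s!r}; run cluster_duplexes first")
        by_id = {d.read_id: d for d in ds.intra_duplexes(s)}
        trimmed: list[DuplexCluster] = []
        rects = []
        for c in tables["raw"]:
            mem = [by_id[m] for m in sorted(c.member_ids)]
            l_fp, l_fb = _trim_side([d.L for d in mem], trim_quantile)
            r_fp, r_fb = _trim_side([d.R for d in mem], trim_quantile)
            fb = l_fb or r_fb
            if fb:
                log.warning("cluster %s: trim threshold emptied a side; modal fallback", c.cluster_id)
            trimmed.append(
                replace(c, L_footprint=l_fp, R_footprint=r_fp, trimmed=True, trim_fallback=fb)
            )
            rects.append((l_fp.start, l_fp.end, r_fp.start, r_fp.end, c.size))
        tables["trimmed"] = trimmed
        ds.matrixList.setdefault(s, {})["trimmed"] = footprint_matrix(
            rects, ds.rna_length, tx_id=ds.rna_id, kind="trimmed"
        )
    return ds


def _rect_jaccard(a: DuplexCluster, b: DuplexCluster) -> float:
    """Jaccard index of the two clusters' L x R rectangles in contact space."""
    area_a = len(a.L_footprint) * len(a.R_footprint)
    area_b = len(b.L_footprint) * len(b.R_footprint)
    inter = a.L_footprint.overlap_len(b.L_footprint) * a.R_footprint.overlap_len(
        b.R_footprint
    )
    union = area_a + area_b - inter
    return inter / union if union else 0.0


def cluster_agreement(ds: DuplexDataSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate support of trimmed clusters.

    For each trimmed cluster c of sample s and each other sample t,
    support(c, t) is the best footprint Jaccard against t's clusters; the
    (s, t) entry of the agreement matrix is the mean support over s's
    clusters.  Returns (per-cluster support table, agreement matrix).
    """
    names = ds.sample_names
    if len(names) < 2:
        raise ValueError("cluster agreement needs >= 2 samples")
    trimmed = {}
    for s in names:
        tables = ds.clusterTableList.get(s, {})
        if "trimmed" not in tables:
            raise ValueError(f"no trimmed clusters for sample {s!r}; run trim_clusters first")
        trimmed[s] = tables["trimmed"]
    rows = []
    for s in names:
        for c in trimmed[s]:
            row = {"cluster_id": c.cluster_id, "sampleName": s, "size": c.size}
            for t in names:
                if t == s:
                    continue
                row[t] = max((_rect_jaccard(c, c2) for c2 in trimmed[t]), default=0.0)
            rows.append(row)
    support = pd.DataFrame(rows)
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for s, t in itertools.permutations(names, 2):
        vals = support.loc[support["sampleName"] == s, t]
        mat.loc[s, t] = float(vals.mean()) if len(vals) else 0.0
    return support, mat


def clusters_to_table(ds: DuplexDataSet, which: str = "trimmed") -> pd.DataFrame:
    """Flat TSV-ready table of clusters across samples."""
    rows = []
    for s in ds.sample_names:
        for c in ds.clusterTableList.get(s, {}).get(which, []):
            rows.append(
                (
                    c.cluster_id,
                    s,
                    c.size,
                    c.L_footprint.start,
                    c.L_footprint.end,
                    c.R_footprint.start,
                    c.R_footprint.end,
                    c.trimmed,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "sampleName",
            "size",
            "L_start",
            "L_end",
            "R_start",
            "R_end",
            "trimmed",
        ],
    )


def clusters_to_bed(ds: DuplexDataSet, path, which: str = "trimmed") -> None:
    """BED6 export of cluster footprints (0-based half-open, one line per arm)."""
    with open(path, "w") as fh:
        for s in ds.sample_names:
            for c in ds.clusterTableList.get(s, {}).get(which, []):
                for arm, iv in (("L", c.L_footprint), ("R", c.R_footprint)):
                    fh.write(
                        f"{ds.rna_id}\t{iv.start - 1}\t{iv.end}\t"
                        f"{c.cluster_id}.{arm}\t{c.size}\t+\n"
                    )
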