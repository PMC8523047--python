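"""Spatial-graph representation and spatiotemporal analyses.

The cell is represented as a spatial graph with tracked z-discs as
nodes and sarcomeres as edges. Each frame in which a tracked sarcomere
links two tracked z-discs increments the weight of the corresponding
edge, so edge weight counts observation frames. On this graph the
network distance between two sarcomeres — the number of connecting
sarcomeres separating them — is the minimum shortest-path length
between their endpoint discs plus one (adjacent sarcomeres sharing a
disc are 1 apart; a sarcomere is 0 from itself).

Further analyses: zero-lag Pearson correlation between normalized-
length series versus Euclidean and network distance; hierarchical
clustering of the series under dynamic-time-warping or Euclidean
distance; and per-series timing parameters (contraction time,
relaxation time, flat time, period, offset, peak count) from
prominence-filtered minima. The timing definitions are this module's
own: the field names the parameters without fixing an algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.signal import find_peaks

from .segment import SarcomereDetection, ZDisc
from .track import Track
from .tseries import SarcTimeSeries

__all__ = [
    "DistanceRecord",
    "build_spatial_graph",
    "network_distance",
    "correlation_vs_distance",
    "dtw_distance",
    "cluster_timeseries",
    "timeseries_parameters",
]


@dataclass
class DistanceRecord:
    """Pairwise sarcomere record: distances plus series correlation."""

    pair: tuple[int, int]
    euclidean: float
    network: float  # np.inf when disconnected
    correlation: float


def build_spatial_graph(
    zdisc_tracks: list[Track],
    sarc_tracks: list[Track],
    zdisc_detections: list[list[ZDisc]],
    sarc_detections: list[list[SarcomereDetection]],
) -> nx.Graph:
    """Build the z-disc/sarcomere spatial graph.

    Nodes are z-disc global IDs with their mean tracked position; for
    each frame, each tracked sarcomere's two local disc ids are mapped
    to global ids and the edge weight is incremented. Observations whose
    endpoint disc was never globally tracked are skipped.
    """
    g = nx.Graph()
    local_to_global: dict[tuple[int, int], int] = {}
    for tr in zdisc_tracks:
        for f, lid in tr.detections.items():
            local_to_global[(f, lid)] = tr.global_id
        pos = np.mean([tr.positions[f] for f in tr.detections], axis=0)
        g.add_node(tr.global_id, position=pos)

    for tr in sarc_tracks:
        for f, lid in tr.detections.items():
            det = sarc_detections[f][lid]
            a = local_to_global.get((f, det.zdisc_ids[0]))
            b = local_to_global.get((f, det.zdisc_ids[1]))
            if a is None or b is None or a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
                g[a][b]["angles"].append(det.angle)
            else:
                g.add_edge(a, b, weight=1, sarc_ids={tr.global_id}, angles=[det.angle])
            g[a][b]["sarc_ids"].add(tr.global_id)
    for a, b, data in g.edges(data=True):
        data["mean_angle"] = float(np.mean(data.pop("angles")))
    return g


def network_distance(
    graph: nx.Graph, edge_a: tuple[int, int], edge_b: tuple[int, int]
) -> float:
    """Number of connecting sarcomeres separating two sarcomeres.

    0 for the same edge; otherwise min over endpoint pairs of the node
    shortest-path length, plus 1. ``inf`` when disconnected.
    """
    ea = frozenset(edge_a)
    eb = frozenset(edge_b)
    for e in (edge_a, edge_b):
        if not graph.has_edge(*e):
            raise ValueError(f"edge {e} not in graph")
    if ea == eb:
        return 0.0
    best = np.inf
    for u in ea:
        for v in eb:
            try:
                d = nx.shortest_path_length(graph, u, v)
            except nx.NetworkXNoPath:
                continue
            best = min(best, d)
    return best + 1 if np.isfinite(best) else np.inf


def _sarc_edges(graph: nx.Graph) -> dict[int, tuple[int, int]]:
    """Map sarcomere global id -> its edge (first edge claiming it)."""
    out: dict[int, tuple[int, int]] = {}
    for a, b, data in sorted(graph.edges(data=True)):
        for sid in sorted(data.get("sarc_ids", ())):
            out.setdefault(sid, (a, b))
    return out


def correlation_vs_distance(
    series: list[SarcTimeSeries], graph: nx.Graph
) -> list[DistanceRecord]:
    """Zero-lag Pearson correlation of normalized-length series for every
    sarcomere pair, with Euclidean and network distances attached.
    Constant series (undefined correlation) are excluded.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    edge_of = _sarc_edges(graph)
    usable = [s for s in series if np.std(s.y) > 1e-12]
    records: list[DistanceRecord] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            corr = float(np.corrcoef(a.y, b.y)[0, 1])
            eu = float(
                np.linalg.norm(a.position.mean(axis=0) - b.position.mean(axis=0))
            )
            if a.global_id in edge_of and b.global_id in edge_of:
                nd = network_distance(graph, edge_of[a.global_id], edge_of[b.global_id])
            else:
                nd = np.inf
            records.append(
                DistanceRecord(
                    pair=(a.global_id, b.global_id),
                    euclidean=eu,
                    network=nd,
                    correlation=corr,
                )
            )
    return records


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic unconstrained dynamic-time-warping distance.

    Squared local cost accumulated over the optimal monotone alignment
    path; the returned value is the square root, so for equal-length
    series it is bounded above by the Euclidean distance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        cost_row = (a[i - 1] - b) ** 2
        for j in range(1, m + 1):
            acc[i, j] = cost_row[j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(np.sqrt(acc[n, m]))


def cluster_timeseries(
    series: list[SarcTimeSeries] | np.ndarray, metric: str = "dtw"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of normalized-length series.

    ``metric`` is "dtw" or "euclidean". Returns (linkage matrix, leaf
    order); average linkage on the condensed distance matrix, fully
    deterministic. All series must share one length.
    """
    if isinstance(series, np.ndarray):
        ys_list = [np.asarray(y) for y in np.atleast_2d(series)]
    else:
        ys_list = [np.asarray(s.y) for s in series]
    if len(ys_list) < 2:
        raise ValueError("need at least 2 series")
    if len({len(y) for y in ys_list}) != 1:
        raise ValueError("mixed-length series")
    ys = np.asarray(ys_list)
    n = len(ys)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "dtw":
                condensed.append(dtw_distance(ys[i], ys[j]))
            elif metric == "euclidean":
                condensed.append(float(np.linalg.norm(ys[i] - ys[j])))
            else:
                raise ValueError(f"unknown metric: {metric}")
    Z = linkage(np.asarray(condensed), method="average")
    return Z, leaves_list(Z)


def timeseries_parameters(y: np.ndarray, prominence_frac: float = 0.25) -> dict:
    """Timing summary of a dense normalized-length series.

    Contraction events are local minima of y with prominence at least
    ``prominence_frac`` of the series range. For each event, the
    contraction time runs from the preceding local maximum (the last
    sample before y starts strictly decreasing into the minimum) to the
    minimum, and the relaxation time from the minimum to the next local
    maximum. Period is the median inter-minimum spacing, flat time is
    period minus mean contraction and relaxation times, and offset is
    the frame of the first minimum. A series with no qualifying events
    returns an all-null summary.
    """
    y = np.asarray(y, dtype=float)
    rng = np.ptp(y)
    null = {
        "n_peaks": 0,
        "period": None,
        "contraction_time": None,
        "relaxation_time": None,
        "flat_time": None,
        "offset": None,
    }
    if rng < 1e-12:
        return null
    minima, _ = find_peaks(-y, prominence=prominence_frac * rng)
    if len(minima) == 0:
        return null

    contraction, relaxation = [], []
    for m in minima:
        i = m
        while i > 0 and y[i - 1] > y[i]:
            i -= 1
        j = m
        while j < len(y) - 1 and y[j + 1] > y[j]:
            j += 1
        contraction.append(m - i)
        relaxation.append(j - m)

    period = float(np.median(np.diff(minima))) if len(minima) > 1 else None
    c = float(np.mean(contraction))
    r = float(np.mean(relaxation))
    return {
        "n_peaks": int(len(minima)),
        "period": period,
        "contraction_time": c,
        "relaxation_time": r,
        "flat_time": (period - c - r) if period is not None else None,
        "offset": int(minima[0]),
    }
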