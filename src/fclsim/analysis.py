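"""Trajectory statistics: clusters, areas, t_c, modal pattern, dwell times.

The quantities here summarise membrane cluster dynamics: clusters are
connected components of the leg-bond graph restricted to membrane-bound
clathrins; a component only counts as a cluster when it has at least
``min_cluster_size`` members.  All modal/mean metrics are computed over
frames after ``t_c``, the first time the membrane-bound clathrin count
reaches 90% of its end-of-run value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.stats import ttest_ind

from .model_core import SiteGeometryParams
from .simulator import Frame, Trajectory

__all__ = [
    "ClusterFrame",
    "FrameStats",
    "MetricsReport",
    "DwellSegment",
    "identify_clusters",
    "hull_area",
    "cluster_area_um2",
    "compute_tc",
    "most_possible_pattern",
    "dwell_segments",
    "frames_to_stats",
    "summarize",
    "neighbor_counts",
    "area_stats",
    "compare_groups",
]

DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_HULL_PAD_NM = 5.0


@dataclass
class ClusterFrame:
    """Per-snapshot cluster labelling and membrane-projected areas."""

    frame_time_s: float
    labels: np.ndarray  # per clathrin; -1 when not in a counted cluster
    cluster_sizes: list[int]
    cluster_areas_um2: list[float]
    n_membrane_clathrin: int
    n_clusters: int
    min_cluster_size: int

    @property
    def total_area_um2(self) -> float:
        return float(sum(self.cluster_areas_um2))

    @property
    def max_area_um2(self) -> float:
        return max(self.cluster_areas_um2) if self.cluster_areas_um2 else 0.0


@dataclass
class FrameStats:
    """Reduced per-frame statistics consumed by :func:`summarize`."""

    times_s: np.ndarray
    n_membrane: np.ndarray
    n_clusters: np.ndarray
    total_area_um2: np.ndarray
    max_area_um2: Optional[np.ndarray] = None


@dataclass
class DwellSegment:
    value: int
    duration_s: float
    censored: bool


@dataclass
class MetricsReport:
    tc_s: float
    modal_cluster_number: int
    mean_mean_cluster_size_um2: float
    mean_dwelling_time_s: float
    cluster_number_freq: dict
    modal_sizes_um2: np.ndarray
    modal_dwells_s: np.ndarray
    min_cluster_size: int
    dwell_mean_censored_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "tc_s": self.tc_s,
            "modal_cluster_number": int(self.modal_cluster_number),
            "mean_mean_cluster_size_um2": self.mean_mean_cluster_size_um2,
            "mean_dwelling_time_s": self.mean_dwelling_time_s,
            "cluster_number_freq": {int(k): float(v) for k, v in self.cluster_number_freq.items()},
            "min_cluster_size": self.min_cluster_size,
            "dwell_mean_censored_fallback": self.dwell_mean_censored_fallback,
        }


# ---------------------------------------------------------------------------
# cluster identification

def _connected_components(n: int, edges: Iterable[tuple[int, int]]) -> np.ndarray:
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def identify_clusters(
    frame: Frame,
    geom: SiteGeometryParams,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    pad_nm: float = DEFAULT_HULL_PAD_NM,
) -> ClusterFrame:
    """Label membrane clusters in one snapshot and measure their areas.

    Clusters are connected components of the clathrin-clathrin bond graph
    restricted to membrane-bound clathrins; components smaller than
    ``min_cluster_size`` are not counted.
    """
    from .model_core import site_positions_many

    n = len(frame.clat_pos)
    mem = np.asarray(frame.clat_mem, dtype=bool)
    edges = []
    bond = frame.leg_bond
    for i in range(n):
        if not mem[i]:
            continue
        for s in range(3):
            j = int(bond[i, s, 0])
            if j >= 0 and i < j and mem[j]:
                edges.append((i, j))
    comp = _connected_components(n, edges)
    labels = np.full(n, -1, dtype=np.int64)
    sizes: list[int] = []
    areas: list[float] = []
    next_label = 0
    for c in np.unique(comp[mem]) if mem.any() else []:
        members = np.flatnonzero((comp == c) & mem)
        if len(members) < min_cluster_size:
            continue
        labels[members] = next_label
        sizes.append(len(members))
        pts = site_positions_many(
            frame.clat_pos[members], frame.clat_quat[members], geom
        )[:, :, :2].reshape(-1, 2)
        pts = np.vstack([pts, frame.clat_pos[members, :2]])
        areas.append(hull_area(pts, pad_nm) / 1e6)  # nm^2 -> um^2
        next_label += 1
    return ClusterFrame(
        frame_time_s=frame.time_s,
        labels=labels,
        cluster_sizes=sizes,
        cluster_areas_um2=areas,
        n_membrane_clathrin=int(mem.sum()),
        n_clusters=next_label,
        min_cluster_size=min_cluster_size,
    )


def hull_area(points: np.ndarray, pad: float = 0.0) -> float:
    """Area of the convex hull of 2D points dilated by ``pad``.

    ``hull area + perimeter * pad + pi * pad^2`` (exact for the Minkowski
    sum of a convex set with a disc).  Degenerate point sets fall back to
    the dilated-segment/disc formula.  Units follow the input coordinates.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return np.pi * pad**2
    try:
        hull = ConvexHull(uniq)
        return float(hull.volume + hull.area * pad + np.pi * pad**2)
    except QhullError:
        # collinear: dilated segment
        d = np.linalg.norm(uniq[:, None, :] - uniq[None, :, :], axis=-1)
        length = float(d.max())
        return 2.0 * pad * length + np.pi * pad**2


def cluster_area_um2(points_nm: np.ndarray, pad_nm: float = DEFAULT_HULL_PAD_NM) -> float:
    """Padded convex hull area of nm coordinates, in um^2."""
    return hull_area(points_nm, pad_nm) / 1e6


# ---------------------------------------------------------------------------
# time-series metrics

def compute_tc(
    times_s: np.ndarray, counts: np.ndarray, t_end_s: Optional[float] = None
) -> float:
    """First time the count reaches 90% of its value at ``t_end_s``.

    Returns 0 when the end count is 0.
    """
    times_s = np.asarray(times_s, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times_s.size == 0:
        raise ValueError("empty trace")
    if t_end_s is None:
        t_end_s = times_s[-1]
    end_idx = int(np.searchsorted(times_s, t_end_s, side="right")) - 1
    end_count = counts[end_idx]
    if end_count == 0:
        return 0.0
    hits = np.flatnonzero(counts >= 0.9 * end_count)
    return float(times_s[hits[0]])


def most_possible_pattern(series: Sequence[int]) -> tuple[int, dict]:
    """Modal cluster-number value and its frequency table.

    Ties are broken toward the smaller cluster number.
    """
    arr = np.asarray(series, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty series")
    values, counts = np.unique(arr, return_counts=True)
    freq = {int(v): float(c) / arr.size for v, c in zip(values, counts)}
    mode = int(values[np.argmax(counts)])  # np.unique sorts ascending: ties -> smaller
    return mode, freq


def dwell_segments(series: Sequence[int], frame_interval_s: float) -> list[DwellSegment]:
    """Run-length encode a uniformly sampled cluster-number series.

    Duration = run length x frame interval.  The first and last runs are
    flagged censored (their true duration extends beyond the trace).
    """
    arr = np.asarray(series)
    if arr.size == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    out = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        out.append(
            DwellSegment(
                value=int(arr[a]),
                duration_s=float((b - a) * frame_interval_s),
                censored=(k == 0 or k == len(starts) - 1),
            )
        )
    return out


def frames_to_stats(
    traj: Trajectory,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    pad_nm: float = DEFAULT_HULL_PAD_NM,
) -> FrameStats:
    """Reduce trajectory frames to the per-frame series the metrics use."""
    times, n_mem, n_clu, tot, mx = [], [], [], [], []
    for fr in traj.frames:
        cf = identify_clusters(fr, traj.geom, min_cluster_size, pad_nm)
        times.append(cf.frame_time_s)
        n_mem.append(cf.n_membrane_clathrin)
        n_clu.append(cf.n_clusters)
        tot.append(cf.total_area_um2)
        mx.append(cf.max_area_um2)
    return FrameStats(
        times_s=np.array(times),
        n_membrane=np.array(n_mem),
        n_clusters=np.array(n_clu),
        total_area_um2=np.array(tot),
        max_area_um2=np.array(mx),
    )


def summarize(
    stats: FrameStats,
    t_end_s: Optional[float] = None,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> MetricsReport:
    """Post-t_c modal pattern, mean-of-mean cluster size and mean dwell time.

    The size metric averages (total cluster area / cluster count) over the
    frames whose cluster count equals the modal value; a modal value of 0
    yields size 0.  Dwell means exclude censored boundary segments; when
    every modal segment is censored the censored mean is reported and
    flagged.
    """
    times = stats.times_s
    if times.size == 0:
        raise ValueError("no frames")
    if t_end_s is None:
        t_end_s = float(times[-1])
    tc = compute_tc(times, stats.n_membrane, t_end_s)
    post = times >= tc
    if not post.any():
        raise ValueError("no frames after t_c")
    n_clusters_post = stats.n_clusters[post]
    mode, freq = most_possible_pattern(n_clusters_post)

    modal_frames = post & (stats.n_clusters == mode)
    if mode == 0:
        mean_size = 0.0
        modal_sizes = np.zeros(0)
    else:
        modal_sizes = stats.total_area_um2[modal_frames] / mode
        mean_size = float(np.mean(modal_sizes))

    if times.size > 1:
        frame_interval = float(np.median(np.diff(times)))
    else:
        frame_interval = 0.0
    segments = dwell_segments(n_clusters_post, frame_interval)
    modal_uncensored = [s.duration_s for s in segments if s.value == mode and not s.censored]
    fallback = False
    if modal_uncensored:
        mean_dwell = float(np.mean(modal_uncensored))
        modal_dwells = np.array(modal_uncensored)
    else:
        modal_all = [s.duration_s for s in segments if s.value == mode]
        mean_dwell = float(np.mean(modal_all)) if modal_all else float("nan")
        modal_dwells = np.array(modal_all)
        fallback = True

    return MetricsReport(
        tc_s=tc,
        modal_cluster_number=mode,
        mean_mean_cluster_size_um2=mean_size,
        mean_dwelling_time_s=mean_dwell,
        cluster_number_freq=freq,
        modal_sizes_um2=modal_sizes,
        modal_dwells_s=modal_dwells,
        min_cluster_size=min_cluster_size,
        dwell_mean_censored_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# point-pattern statistics (external centroid/area tables)

def neighbor_counts(centroids_um: np.ndarray, window_um: float = 1.0) -> np.ndarray:
    """Number of OTHER points inside the axis-aligned window x window
    square centered on each point (closed boundaries)."""
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    half = window_um / 2.0
    tree = cKDTree(pts)
    counts = np.array(
        [len(tree.query_ball_point(p, half, p=np.inf)) - 1 for p in pts], dtype=np.int64
    )
    return counts


def area_stats(areas: Sequence[float]) -> dict:
    """Box-plot summary: median, type-7 quartiles, Tukey 1.5 IQR whiskers.

    Whiskers are the extreme data points inside the fences; values beyond
    them are listed as outliers.
    """
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(a, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = a[(a >= lo_fence) & (a <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": a[(a < lo_fence) | (a > hi_fence)].tolist(),
        "n": int(a.size),
    }


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> tuple[float, float]:
    """Unpaired two-sample t-test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance")
    res = ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
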