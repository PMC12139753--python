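"""Generators with known ground truth for testing the analysis operations.

The cluster-number dynamics are emulated by a Markov chain whose modal
state, dwell-time distribution and per-state cluster sizes are known in
closed form; point patterns come with embedded brute-force neighbor
counts.  Nothing here runs the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import FrameStats
from .model_core import SiteGeometryParams

__all__ = [
    "SyntheticTrajectorySpec",
    "SyntheticPointPatternSpec",
    "make_cluster_trace",
    "make_bond_graph",
    "make_point_pattern",
]


@dataclass
class SyntheticTrajectorySpec:
    transition_matrix: np.ndarray  # (K+1, K+1) over cluster numbers 0..K
    frame_interval_s: float = 0.1
    duration_s: float = 100.0
    size_lognorm_mu: float = -3.5  # log um^2 per cluster
    size_lognorm_sigma: float = 0.2
    n_membrane: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        self.transition_matrix = tm


@dataclass
class SyntheticPointPatternSpec:
    domain_um: float = 10.0
    n_points: int = 50
    placement: str = "uniform"  # or "matern"
    parent_intensity_per_um2: float = 0.1  # matern only
    cluster_radius_um: float = 0.5  # matern only
    area_lognorm_mu: float = -3.5
    area_lognorm_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement not in ("uniform", "matern"):
            raise ValueError("placement must be 'uniform' or 'matern'")


def _stationary_distribution(tm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tm.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def make_cluster_trace(spec: SyntheticTrajectorySpec) -> tuple[FrameStats, dict]:
    """Markov-chain cluster-number series plus its exact ground truth.

    Ground truth: stationary distribution, its modal state (ties toward
    the smaller state), expected dwell time per state
    ``frame_interval / (1 - p_self)`` and the expected per-cluster mean
    area ``exp(mu + sigma^2/2)``.
    """
    rng = np.random.default_rng(spec.seed)
    tm = spec.transition_matrix
    n_states = tm.shape[0]
    n_frames = int(round(spec.duration_s / spec.frame_interval_s)) + 1
    pi = _stationary_distribution(tm)
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = rng.choice(n_states, p=pi)
    cdf = np.cumsum(tm, axis=1)
    u = rng.random(n_frames - 1)
    for k in range(1, n_frames):
        states[k] = np.searchsorted(cdf[states[k - 1]], u[k - 1])
    # per-frame total area: n_clusters draws from the lognormal size law
    total_area = np.zeros(n_frames)
    for k in range(n_frames):
        n = states[k]
        if n > 0:
            total_area[k] = np.exp(
                rng.normal(spec.size_lognorm_mu, spec.size_lognorm_sigma, size=n)
            ).sum()
    times = np.arange(n_frames) * spec.frame_interval_s
    stats = FrameStats(
        times_s=times,
        n_membrane=np.full(n_frames, spec.n_membrane),
        n_clusters=states,
        total_area_um2=total_area,
        max_area_um2=None,
    )
    mode = int(np.flatnonzero(pi == pi.max())[0])
    expected_dwell = {
        s: spec.frame_interval_s / (1.0 - tm[s, s]) if tm[s, s] < 1.0 else np.inf
        for s in range(n_states)
    }
    ground_truth = {
        "stationary": pi,
        "mode": mode,
        "expected_dwell_s": expected_dwell,
        "expected_mean_cluster_area_um2": float(
            np.exp(spec.size_lognorm_mu + spec.size_lognorm_sigma**2 / 2.0)
        ),
    }
    return stats, ground_truth


def make_bond_graph(
    size_list: list[int],
    geom: Optional[SiteGeometryParams] = None,
    seed: int = 0,
    spacing_factor: float = 3.0,
) -> "object":
    """Snapshot-like fixture: flat bonded patches of the requested sizes.

    Patches are laid out on a line, far enough apart never to touch; every
    bond is geometrically consistent (5 nm head-to-head).  Returns a
    :class:`fclsim.simulator.Frame` with all members membrane-bound and the
    first member of each patch adaptor-anchored.
    """
    from .protocols import _honeycomb_patch
    from .simulator import Frame
    from .model_core import yaw_quat

    if geom is None:
        geom = SiteGeometryParams()
    if any(s < 1 for s in size_list):
        raise ValueError("sizes must be >= 1")
    n_total = sum(size_list)
    pos = np.zeros((n_total, 3))
    quat = np.zeros((n_total, 4))
    leg_bond = np.full((n_total, 3, 2), -1, dtype=np.int64)
    clat_ap2 = np.full(n_total, -1, dtype=np.int64)
    ap2_pos = np.zeros((len(size_list), 2))
    offset = 0
    a = geom.bonded_center_distance_nm
    for pi_, size in enumerate(size_list):
        # generous per-patch spacing along x
        cx = pi_ * spacing_factor * a * (max(size_list) + 2)
        centers, yaws, bonds = _honeycomb_patch(size, geom, np.array([cx, 0.0]))
        centers[:, 2] = geom.membrane_anchor_z_nm
        pos[offset : offset + size] = centers
        quat[offset : offset + size] = [yaw_quat(phi) for phi in yaws]
        for i, si, j, sj in bonds:
            leg_bond[offset + i, si] = (offset + j, sj)
            leg_bond[offset + j, sj] = (offset + i, si)
        clat_ap2[offset] = pi_
        ap2_pos[pi_] = centers[0, :2]
        offset += size
    ap2_bond = np.arange(len(size_list), dtype=np.int64)
    # make ap2_bond point back at the anchored member of each patch
    anchored = np.flatnonzero(clat_ap2 >= 0)
    ap2_bond = anchored[np.argsort(clat_ap2[anchored])]
    return Frame(
        time_s=0.0,
        clat_pos=pos,
        clat_quat=quat,
        clat_mem=np.ones(n_total, dtype=bool),
        leg_bond=leg_bond,
        clat_ap2=clat_ap2,
        ap2_pos=ap2_pos,
        ap2_bond=ap2_bond,
    )


def make_point_pattern(spec: SyntheticPointPatternSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Centroid/area table plus embedded brute-force neighbor counts.

    The returned DataFrame has columns (x_um, y_um, area_um2); the second
    element holds O(n^2) neighbor counts for a 1 um x 1 um window.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.domain_um
    if spec.placement == "uniform":
        xy = rng.uniform(0, L, size=(spec.n_points, 2))
    else:
        n_parents = max(1, rng.poisson(spec.parent_intensity_per_um2 * L * L))
        parents = rng.uniform(0, L, size=(n_parents, 2))
        idx = rng.integers(n_parents, size=spec.n_points)
        xy = parents[idx] + rng.uniform(
            -spec.cluster_radius_um, spec.cluster_radius_um, size=(spec.n_points, 2)
        )
        xy = np.clip(xy, 0, L)
    areas = np.exp(rng.normal(spec.area_lognorm_mu, spec.area_lognorm_sigma, spec.n_points))
    table = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "area_um2": areas})
    # brute-force O(n^2) window counts, closed boundaries
    counts = np.zeros(spec.n_points, dtype=np.int64)
    for i in range(spec.n_points):
        inside = (np.abs(xy[:, 0] - xy[i, 0]) <= 0.5) & (np.abs(xy[:, 1] - xy[i, 1]) <= 0.5)
        counts[i] = int(inside.sum()) - 1
    return table, counts
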