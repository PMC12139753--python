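"""Shared test fixtures/oracles importable from any test module."""

import numpy as np

from fclsim.model_core import (
    BoxGeometry,
    KineticParams,
    SiteGeometryParams,
    yaw_quat,
)
from fclsim.simulator import SimState


def make_state(
    clat_pos,
    box=None,
    geom=None,
    kin=None,
    clat_quat=None,
    clat_mem=None,
    ap2_pos=None,
    seed=0,
):
    """Hand-assembled SimState for unit tests."""
    clat_pos = np.asarray(clat_pos, dtype=float).reshape(-1, 3)
    n = len(clat_pos)
    if box is None:
        box = BoxGeometry(edge_nm=1000.0)
    if geom is None:
        geom = SiteGeometryParams()
    if kin is None:
        kin = KineticParams()
    if clat_quat is None:
        clat_quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    if clat_mem is None:
        clat_mem = np.zeros(n, dtype=bool)
    if ap2_pos is None:
        ap2_pos = np.zeros((0, 2))
    return SimState(
        box=box,
        geom=geom,
        kin=kin,
        clat_pos=clat_pos,
        clat_quat=clat_quat,
        clat_mem=clat_mem,
        ap2_pos=ap2_pos,
        rng=np.random.default_rng(seed),
    )


def make_dimer_state(n_pairs, kin, box_nm=100000.0, spacing=200.0):
    """n_pairs far-separated leg-bonded dimers on the membrane."""
    geom = SiteGeometryParams()
    a = geom.bonded_center_distance_nm
    pos = []
    quats = []
    per_row = int(np.floor(box_nm / spacing))
    for k in range(n_pairs):
        x = (k % per_row) * spacing + spacing / 2
        y = (k // per_row) * spacing + spacing / 2
        z = geom.membrane_anchor_z_nm
        pos.append([x, y, z])
        pos.append([x + a, y, z])
        quats.append(yaw_quat(0.0))
        quats.append(yaw_quat(np.pi))
    state = make_state(
        np.array(pos),
        box=BoxGeometry(edge_nm=box_nm),
        kin=kin,
        clat_quat=np.array(quats),
        clat_mem=np.ones(2 * n_pairs, dtype=bool),
        ap2_pos=np.array([p[:2] for p in pos]),
    )
    for k in range(n_pairs):
        i, j = 2 * k, 2 * k + 1
        state.leg_bond[i, 0] = (j, 0)
        state.leg_bond[j, 0] = (i, 0)
    state.clat_ap2[:] = np.arange(2 * n_pairs)
    state.ap2_bond[:] = np.arange(2 * n_pairs)
    state.invalidate()
    return state


def oracle_components(n, edges):
    """Brute-force BFS connected components."""
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        queue, comp = [start], []
        seen.add(start)
        while queue:
            v = queue.pop()
            comp.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(sorted(comp))
    return comps


def oracle_hull_area(points):
    """Monotone-chain convex hull + shoelace area."""
    pts = sorted(map(tuple, np.asarray(points, dtype=float)))
    pts = [np.array(p) for p in dict.fromkeys(pts)]
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0
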