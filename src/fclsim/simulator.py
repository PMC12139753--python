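"""Per-timestep engine: dissociation, association, diffusion, bookkeeping.

Stepping order within one timestep is fixed: dissociation events are tested
first, then association events, and finally every molecule or assembled
complex that did not react receives a Brownian update.  A molecule takes
part in at most one reaction per step and a reacted molecule does not
diffuse in that step.

Association uses a Doi/contact scheme: a free site pair within the reaction
radius ``sigma_react_nm`` is accepted with probability ``1 - exp(-lam*dt)``
where ``lam`` is calibrated so that the macroscopic association flux in a
well-mixed dilute system equals ``k_on * [A] * [B]`` (see
:func:`calibrate_lambda_3d`).  When both partners are membrane bound the 3D
rate is first converted to a 2D one by dividing by ``rate_2d_lengthscale_nm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import units
from .model_core import (
    BoxGeometry,
    KineticParams,
    SiteGeometryParams,
    bound_partner_pose,
    leg_local_coords,
    quat_mul,
    quat_to_matrix,
    site_positions_many,
    yaw_quat,
)

__all__ = [
    "SimState",
    "Frame",
    "Trajectory",
    "ComplexView",
    "dissociation_probability",
    "cluster_diffusion",
    "combine_diffusion",
    "doi_rate_3d",
    "calibrate_lambda_3d",
    "calibrate_lambda_2d",
    "step",
    "run",
]

MAX_MOVE_RETRIES = 100


# ---------------------------------------------------------------------------
# elementary kinetics

def dissociation_probability(k_off: float, dt: float) -> float:
    """Per-step bond-break probability ``1 - exp(-k_off * dt)``."""
    if k_off < 0 or dt <= 0:
        raise ValueError("k_off must be >= 0 and dt > 0")
    return -np.expm1(-k_off * dt)


def combine_diffusion(d_values: np.ndarray, n: int) -> float:
    """Cluster diffusion coefficient ``(sum_i D_i^(-1/n))^(-n)``.

    ``n = 1`` for translation, ``n = 3`` for rotation.
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one component")
    if np.any(d <= 0):
        return 0.0
    return float(np.sum(d ** (-1.0 / n)) ** (-float(n)))


def cluster_diffusion(components: list[tuple[float, float]]) -> tuple[float, float]:
    """(D_trans, D_rot) of a complex from its members' coefficients."""
    if not components:
        raise ValueError("empty component list")
    dt_vals = np.array([c[0] for c in components])
    dr_vals = np.array([c[1] for c in components])
    return combine_diffusion(dt_vals, 1), combine_diffusion(dr_vals, 3)


def doi_rate_3d(lam: float, sigma_nm: float, d_rel_nm2_s: float) -> float:
    """Macroscopic 3D rate (nm^3/s) of the Doi model.

    ``k = 4 pi D sigma (1 - tanh(beta)/beta)`` with
    ``beta = sigma * sqrt(lam / D)``; reduces to the reaction-limited
    ``lam * (4/3) pi sigma^3`` for small ``lam``.
    """
    if lam == 0:
        return 0.0
    beta = sigma_nm * np.sqrt(lam / d_rel_nm2_s)
    return 4.0 * np.pi * d_rel_nm2_s * sigma_nm * (1.0 - np.tanh(beta) / beta)


def calibrate_lambda_3d(k_on_nm3_s: float, sigma_nm: float, d_rel_nm2_s: float) -> float:
    """Intrinsic contact rate ``lam`` (1/s) reproducing ``k_on`` in 3D."""
    if k_on_nm3_s == 0:
        return 0.0
    k_diff = 4.0 * np.pi * d_rel_nm2_s * sigma_nm
    if k_on_nm3_s >= k_diff:
        raise ValueError(
            f"k_on={k_on_nm3_s:.3g} nm^3/s exceeds the diffusion limit "
            f"{k_diff:.3g} nm^3/s for sigma={sigma_nm} nm"
        )
    v_sigma = 4.0 / 3.0 * np.pi * sigma_nm**3
    lam0 = k_on_nm3_s / v_sigma  # reaction-limited guess
    if k_on_nm3_s < 1e-3 * k_diff:
        # correction negligible below 0.1% of the diffusion limit
        return lam0
    f = lambda lam: doi_rate_3d(lam, sigma_nm, d_rel_nm2_s) - k_on_nm3_s
    hi = lam0
    while f(hi) < 0:
        hi *= 4.0
    return float(brentq(f, lam0 * 0.5, hi, rtol=1e-12))


def calibrate_lambda_2d(k_on_nm2_s: float, sigma_nm: float) -> float:
    """Intrinsic contact rate for a 2D disc of radius ``sigma`` (reaction-limited)."""
    if k_on_nm2_s == 0:
        return 0.0
    return k_on_nm2_s / (np.pi * sigma_nm**2)


# ---------------------------------------------------------------------------
# state

@dataclass
class ComplexView:
    """One diffusing unit: a bond-connected component plus its adaptors."""

    clathrins: np.ndarray  # indices
    ap2s: np.ndarray  # indices of bound adaptors
    membrane: bool
    d_trans_um2_s: float
    d_rot_s: float


@dataclass
class Frame:
    time_s: float
    clat_pos: np.ndarray
    clat_quat: np.ndarray
    clat_mem: np.ndarray
    leg_bond: np.ndarray
    clat_ap2: np.ndarray
    ap2_pos: np.ndarray
    ap2_bond: np.ndarray


@dataclass
class Trajectory:
    frames: list[Frame]
    events: list[tuple]
    geom: SiteGeometryParams
    kin: KineticParams
    box: BoxGeometry
    skipped_moves: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])


class SimState:
    """Array-backed simulation state.

    Clathrin ``i`` has pose ``clat_pos[i]``/``clat_quat[i]``; its leg bonds
    are ``leg_bond[i, s] = (partner, partner_site)`` or ``(-1, -1)`` and its
    adaptor bond ``clat_ap2[i]`` (adaptor index or -1).  Adaptors live on
    the membrane plane; ``ap2_pos`` stores xy only.
    """

    def __init__(
        self,
        box: BoxGeometry,
        geom: SiteGeometryParams,
        kin: KineticParams,
        clat_pos: np.ndarray,
        clat_quat: np.ndarray,
        clat_mem: np.ndarray,
        ap2_pos: np.ndarray,
        rng: np.random.Generator,
        time_s: float = 0.0,
    ):
        self.box = box
        self.geom = geom
        self.kin = kin
        self.clat_pos = np.array(clat_pos, dtype=float).reshape(-1, 3)
        self.clat_quat = np.array(clat_quat, dtype=float).reshape(-1, 4)
        self.clat_mem = np.array(clat_mem, dtype=bool).reshape(-1)
        self.ap2_pos = np.array(ap2_pos, dtype=float).reshape(-1, 2)
        self.rng = rng
        self.time_s = float(time_s)
        n, m = len(self.clat_pos), len(self.ap2_pos)
        self.leg_bond = np.full((n, 3, 2), -1, dtype=np.int64)
        self.clat_ap2 = np.full(n, -1, dtype=np.int64)
        self.ap2_bond = np.full(m, -1, dtype=np.int64)
        self.event_log: list[tuple] = []
        self.skipped_moves = 0
        self.forced_ap2_unbinds = 0
        self._comp_cache: Optional[tuple[np.ndarray, list[np.ndarray]]] = None
        self._bonds_cache: Optional[np.ndarray] = None
        self._rates: Optional[dict] = None

    # -- structure -----------------------------------------------------

    @property
    def n_clathrin(self) -> int:
        return len(self.clat_pos)

    @property
    def n_ap2(self) -> int:
        return len(self.ap2_pos)

    def invalidate(self) -> None:
        self._comp_cache = None
        self._bonds_cache = None

    def invalidate_bonds(self) -> None:
        """Bond table changed without altering component topology."""
        self._bonds_cache = None

    def merge_components(self, i: int, j: int) -> None:
        """Incremental cache update after a bond joined two components."""
        if self._comp_cache is None:
            return
        labels, members = self._comp_cache
        li, lj = int(labels[i]), int(labels[j])
        if li == lj:
            return
        keep, drop = (li, lj) if li < lj else (lj, li)
        labels[labels == drop] = keep
        labels[labels > drop] -= 1
        members[keep] = np.concatenate([members[keep], members[drop]])
        members.pop(drop)

    def bonded_pairs_array(self) -> np.ndarray:
        """(K, 2) canonical clathrin index pairs joined by a leg bond."""
        return self.bonded_pairs_with_sites()[:, [0, 2]]

    def bonded_pairs(self) -> list[tuple[int, int]]:
        """Canonical clathrin index pairs joined by a leg bond."""
        return [(int(a), int(b)) for a, b in self.bonded_pairs_array()]

    def components(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """(labels, member-lists) of leg-bond connected components."""
        if self._comp_cache is not None:
            return self._comp_cache
        n = self.n_clathrin
        pairs = self.bonded_pairs_array()
        if len(pairs) == 0:
            labels = np.arange(n, dtype=np.int64)
            members = [np.array([i]) for i in range(n)]
        else:
            if n <= 64:
                parent = np.arange(n)

                def find(a: int) -> int:
                    while parent[a] != a:
                        parent[a] = parent[parent[a]]
                        a = parent[a]
                    return a

                for i, j in pairs:
                    ri, rj = find(int(i)), find(int(j))
                    if ri != rj:
                        parent[ri] = rj
                roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
                _, labels = np.unique(roots, return_inverse=True)
                labels = labels.astype(np.int64)
            else:
                from scipy.sparse import coo_matrix
                from scipy.sparse.csgraph import connected_components

                adj = coo_matrix(
                    (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
                )
                _, labels = connected_components(adj, directed=False)
                labels = labels.astype(np.int64)
            order = np.argsort(labels, kind="stable")
            cuts = np.flatnonzero(np.diff(labels[order])) + 1
            members = np.split(order, cuts)
        self._comp_cache = (labels, members)
        return self._comp_cache

    def unit_diffusion(self, n_clat: int, n_ap2_bound: int, membrane: bool) -> tuple[float, float]:
        """(D_trans, D_rot) of a unit with the given composition (cached)."""
        key = (n_clat, n_ap2_bound, membrane)
        cache = getattr(self, "_unit_d_cache", None)
        if cache is None:
            cache = self._unit_d_cache = {}
        hit = cache.get(key)
        if hit is not None:
            return hit
        kin = self.kin
        if membrane:
            d = [kin.d_clat_mem_trans_um2_s] * n_clat + [kin.d_ap2_trans_um2_s] * n_ap2_bound
            dr = [kin.d_clat_mem_rot_s] * n_clat
        else:
            d = [kin.d_clat_trans_um2_s] * n_clat
            dr = [kin.d_clat_rot_s] * n_clat
        out = (combine_diffusion(np.array(d), 1), combine_diffusion(np.array(dr), 3))
        cache[key] = out
        return out

    def units(self) -> list[ComplexView]:
        """Diffusing units: components with their adaptors (free adaptors excluded)."""
        _, members = self.components()
        out = []
        for mem_idx in members:
            ap2s = self.clat_ap2[mem_idx]
            ap2s = ap2s[ap2s >= 0]
            membrane = bool(self.clat_mem[mem_idx].any())
            d_t, d_r = self.unit_diffusion(len(mem_idx), len(ap2s), membrane)
            out.append(
                ComplexView(
                    clathrins=mem_idx,
                    ap2s=ap2s,
                    membrane=membrane,
                    d_trans_um2_s=d_t,
                    d_rot_s=d_r,
                )
            )
        return out

    # -- rate tables ---------------------------------------------------

    def refresh_rates(self) -> None:
        kin, geom = self.kin, self.geom
        sigma = kin.sigma_react_nm
        k_cc = units.rate_uM_to_nm3(kin.k_clat_clat_on_uM_s)
        k_ca = units.rate_uM_to_nm3(kin.k_clat_ap2_on_uM_s)
        d_cc_3 = units.um2_s_to_nm2_s(kin.d_clat_trans_um2_s + kin.d_clat_mem_trans_um2_s)
        d_ca_3 = units.um2_s_to_nm2_s(kin.d_clat_trans_um2_s + kin.d_ap2_trans_um2_s)

        def lam3(k_on: float, d_rel: float) -> float:
            if k_on == 0:
                return 0.0
            k_diff = 4.0 * np.pi * d_rel * sigma
            if k_on >= 0.95 * k_diff:
                # requested rate is at/above the diffusion limit of the
                # contact scheme: saturate the contact reactivity
                warnings.warn(
                    f"k_on={k_on:.3g} nm^3/s is diffusion limited "
                    f"(k_diff={k_diff:.3g}); clamping contact rate",
                    stacklevel=3,
                )
                return 400.0 * d_rel / sigma**2  # beta = 20: k ~ 0.95 k_diff
            return calibrate_lambda_3d(k_on, sigma, d_rel)

        lam3_cc = lam3(k_cc, d_cc_3)
        lam3_ca = lam3(k_ca, d_ca_3)
        ell = kin.rate_2d_lengthscale_nm
        lam2_cc = calibrate_lambda_2d(k_cc / ell, sigma)
        lam2_ca = calibrate_lambda_2d(k_ca / ell, sigma)
        dt = kin.dt_s
        self._unit_d_cache = {}
        self._rates = {
            "p3_cc": -np.expm1(-lam3_cc * dt),
            "p2_cc": -np.expm1(-lam2_cc * dt),
            "p3_ca": -np.expm1(-lam3_ca * dt),
            "p2_ca": -np.expm1(-lam2_ca * dt),
            "p_off_cc": dissociation_probability(kin.k_clat_clat_off_s, dt),
            "p_off_ca": dissociation_probability(kin.k_clat_ap2_off_s, dt),
        }
        pmax = max(self._rates[k] for k in ("p3_cc", "p2_cc", "p3_ca", "p2_ca"))
        if pmax > 0.1:
            warnings.warn(
                f"per-step reaction probability {pmax:.3f} exceeds 0.1; "
                "consider a smaller dt",
                stacklevel=2,
            )

    @property
    def rates(self) -> dict:
        if self._rates is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.refresh_rates()
        return self._rates

    # -- helpers -------------------------------------------------------

    def site_world(self) -> np.ndarray:
        """(N, 4, 3) world site positions for all clathrins."""
        return site_positions_many(self.clat_pos, self.clat_quat, self.geom)

    def bond_exemption_needed(self) -> bool:
        """Whether bonded pairs can sit inside the hard-core cutoff.

        With the default geometry the bonded center distance (2 leg + bond)
        exceeds twice the excluded radius, so bonded pairs never trigger
        the overlap test and the exemption set can be skipped.
        """
        return (
            self.geom.bonded_center_distance_nm
            <= 2.0 * self.geom.excluded_radius_nm + 1e-9
        )

    def ap2_pos3(self) -> np.ndarray:
        """(M, 3) adaptor bead centers (z = adaptor radius)."""
        out = np.empty((self.n_ap2, 3))
        out[:, :2] = self.ap2_pos
        out[:, 2] = self.geom.ap2_radius_nm
        return out

    def anchored_components(self) -> np.ndarray:
        """Boolean per-clathrin: component holds at least one adaptor bond."""
        labels, members = self.components()
        flag = np.zeros(len(members), dtype=bool)
        flag[labels[self.clat_ap2 >= 0]] = True
        return flag[labels]

    def refresh_compartments(self) -> None:
        """Membrane flag = component anchored by >= 1 adaptor."""
        self.clat_mem = self.anchored_components()

    # -- adaptor insertion/removal (time-varying protocols) ------------

    def add_ap2(self, xy: np.ndarray) -> int:
        """Insert one adaptor at the given membrane position."""
        self.ap2_pos = np.vstack([self.ap2_pos, np.asarray(xy, dtype=float).reshape(1, 2)])
        self.ap2_bond = np.concatenate([self.ap2_bond, [-1]])
        self.event_log.append((self.time_s, "insert_ap2", self.n_ap2 - 1))
        return self.n_ap2 - 1

    def remove_ap2(self, index: int) -> None:
        """Remove one adaptor; a bound adaptor is force-unbound first."""
        i = int(self.clat_ap2_owner(index))
        if i >= 0:
            self.clat_ap2[i] = -1
            self.forced_ap2_unbinds += 1
            self.event_log.append((self.time_s, "forced_unbind_ca", i, index))
            self.invalidate()
        last = self.n_ap2 - 1
        if index != last:
            # swap-delete: relabel the last adaptor to 'index'
            self.ap2_pos[index] = self.ap2_pos[last]
            self.ap2_bond[index] = self.ap2_bond[last]
            owner = int(self.ap2_bond[index])
            if owner >= 0:
                self.clat_ap2[owner] = index
        self.ap2_pos = self.ap2_pos[:last]
        self.ap2_bond = self.ap2_bond[:last]
        self.event_log.append((self.time_s, "remove_ap2", index))
        self.invalidate()
        self.refresh_compartments()

    def clat_ap2_owner(self, ap2_index: int) -> int:
        return int(self.ap2_bond[ap2_index])

    def snapshot(self) -> Frame:
        return Frame(
            time_s=self.time_s,
            clat_pos=self.clat_pos.copy(),
            clat_quat=self.clat_quat.copy(),
            clat_mem=self.clat_mem.copy(),
            leg_bond=self.leg_bond.copy(),
            clat_ap2=self.clat_ap2.copy(),
            ap2_pos=self.ap2_pos.copy(),
            ap2_bond=self.ap2_bond.copy(),
        )

    def copy(self) -> "SimState":
        import copy as _copy

        new = SimState(
            self.box,
            self.geom,
            _copy.deepcopy(self.kin),
            self.clat_pos,
            self.clat_quat,
            self.clat_mem,
            self.ap2_pos,
            _copy.deepcopy(self.rng),
            self.time_s,
        )
        new.leg_bond = self.leg_bond.copy()
        new.clat_ap2 = self.clat_ap2.copy()
        new.ap2_bond = self.ap2_bond.copy()
        new.event_log = list(self.event_log)
        return new


# ---------------------------------------------------------------------------
# sweeps

def dissociation_sweep(state: SimState) -> tuple[np.ndarray, np.ndarray]:
    """Break bonds independently with their per-step probabilities.

    Returns (reacted_clathrin, reacted_ap2) boolean masks.  Bonds are
    visited in random order; a molecule that already reacted this step
    blocks further reactions involving it.
    """
    rng = state.rng
    rates = state.rates
    reacted_c = np.zeros(state.n_clathrin, dtype=bool)
    reacted_a = np.zeros(state.n_ap2, dtype=bool)

    events: list[tuple] = []
    cc = state.bonded_pairs_with_sites()
    ca = np.flatnonzero(state.clat_ap2 >= 0)
    n_cc, n_ca = len(cc), len(ca)
    if n_cc + n_ca == 0:
        return reacted_c, reacted_a
    # one uniform draw per bond, then conflict resolution in random order
    u = rng.random(n_cc + n_ca)
    hit = np.concatenate(
        [u[:n_cc] < rates["p_off_cc"], u[n_cc:] < rates["p_off_ca"]]
    )
    if not hit.any():
        return reacted_c, reacted_a
    order = rng.permutation(np.flatnonzero(hit))
    changed = False
    cc_changed = False
    for k in order:
        if k < n_cc:
            if u[k] >= rates["p_off_cc"]:
                continue
            i, si, j, sj = (int(x) for x in cc[k])
            if reacted_c[i] or reacted_c[j]:
                continue
            state.leg_bond[i, si] = (-1, -1)
            state.leg_bond[j, sj] = (-1, -1)
            reacted_c[i] = reacted_c[j] = True
            events.append((state.time_s, "unbind_cc", i, si, j, sj))
            changed = True
            cc_changed = True
        else:
            if u[k] >= rates["p_off_ca"]:
                continue
            i = int(ca[k - n_cc])
            a = int(state.clat_ap2[i])
            if reacted_c[i] or reacted_a[a]:
                continue
            state.clat_ap2[i] = -1
            state.ap2_bond[a] = -1
            reacted_c[i] = True
            reacted_a[a] = True
            events.append((state.time_s, "unbind_ca", i, a))
            changed = True
    if changed:
        if cc_changed:
            state.invalidate()  # component splits require a rebuild
        state.refresh_compartments()
        state.event_log.extend(events)
    return reacted_c, reacted_a


def _bonded_pairs_with_sites(state: SimState) -> np.ndarray:
    """(K, 4) array of canonical (i, site_i, j, site_j) leg bonds (cached)."""
    if state._bonds_cache is not None:
        return state._bonds_cache
    mask = state.leg_bond[:, :, 0] >= 0
    if not mask.any():
        out = np.zeros((0, 4), dtype=np.int64)
    else:
        n = state.n_clathrin
        own_i = np.broadcast_to(np.arange(n)[:, None], mask.shape)[mask]
        own_s = np.broadcast_to(np.arange(3)[None, :], mask.shape)[mask]
        other = state.leg_bond[mask]  # (K, 2)
        keep = (own_i < other[:, 0]) | ((own_i == other[:, 0]) & (own_s < other[:, 1]))
        out = np.stack(
            [own_i[keep], own_s[keep], other[keep, 0], other[keep, 1]], axis=1
        )
    state._bonds_cache = out
    return out


SimState.bonded_pairs_with_sites = _bonded_pairs_with_sites


def _unit_transform(
    state: SimState,
    members: np.ndarray,
    ap2s: np.ndarray,
    pivot_idx: int,
    new_center: np.ndarray,
    new_quat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid transform of a unit so clathrin ``pivot_idx`` reaches the new pose.

    Returns tentative (member positions, member quats, adaptor xy).
    """
    c_old = state.clat_pos[pivot_idx]
    r_old = quat_to_matrix(state.clat_quat[pivot_idx])
    r_new = quat_to_matrix(new_quat)
    r_delta = r_new @ r_old.T
    dq = _quat_from_matrix(r_delta)
    pos = (state.clat_pos[members] - c_old) @ r_delta.T + new_center
    quats = np.array([quat_mul(dq, q) for q in state.clat_quat[members]])
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    if len(ap2s):
        p3 = np.zeros((len(ap2s), 3))
        p3[:, :2] = state.ap2_pos[ap2s]
        p3 = (p3 - c_old) @ r_delta.T + new_center
        ap2_xy = p3[:, :2]
    else:
        ap2_xy = np.zeros((0, 2))
    return pos, quats, ap2_xy


def _quat_from_matrix(m: np.ndarray) -> np.ndarray:
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        return np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    i = int(np.argmax(np.diag(m)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(max(m[i, i] - m[j, j] - m[k, k] + 1.0, 0.0)) * 2
    q = np.empty(4)
    q[0] = (m[k, j] - m[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (m[j, i] + m[i, j]) / s
    q[1 + k] = (m[k, i] + m[i, k]) / s
    return q / np.linalg.norm(q)


def _overlap_ok(
    state: SimState,
    tentative_pos: np.ndarray,
    moved: np.ndarray,
    extra_bonded: Optional[set] = None,
) -> bool:
    """Hard-core check of moved clathrins against everything."""
    geom = state.geom
    cutoff = 2.0 * geom.excluded_radius_nm
    others = np.setdiff1d(np.arange(state.n_clathrin), moved, assume_unique=False)
    if state.bond_exemption_needed():
        bonded = {(min(a, b), max(a, b)) for a, b in state.bonded_pairs()}
    else:
        bonded = set()
    if extra_bonded:
        bonded |= extra_bonded
    if len(others):
        tree = cKDTree(tentative_pos[others])
        for mi, p in zip(moved, tentative_pos[moved]):
            for loc in tree.query_ball_point(p, cutoff):
                pair = (min(int(mi), int(others[loc])), max(int(mi), int(others[loc])))
                if pair not in bonded:
                    return False
    if len(moved) > 1:
        tree = cKDTree(tentative_pos[moved])
        for a, b in tree.query_pairs(cutoff):
            pair = (min(int(moved[a]), int(moved[b])), max(int(moved[a]), int(moved[b])))
            if pair not in bonded:
                return False
    return True


def _self_pairs_within(pos: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs (a < b) closer than cutoff; brute force for small sets."""
    n = len(pos)
    if n <= 130:
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        iu = np.triu_indices(n, k=1)
        hit = d2[iu] <= cutoff * cutoff
        return np.stack([iu[0][hit], iu[1][hit]], axis=1)
    return cKDTree(pos).query_pairs(cutoff, output_type="ndarray")


def _cross_pairs_within(a: np.ndarray, b: np.ndarray, cutoff: float) -> list:
    """(i, j) with |a_i - b_j| <= cutoff; brute force for small sets."""
    if len(a) * len(b) <= 120000:
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        return np.argwhere(d2 <= cutoff * cutoff)
    tree = cKDTree(b)
    out = []
    for i, found in enumerate(tree.query_ball_point(a, cutoff)):
        out.extend((i, j) for j in found)
    return out


def association_sweep(
    state: SimState, reacted_c: np.ndarray, reacted_a: np.ndarray
) -> None:
    """Test every eligible free-site pair within the reaction radius.

    Eligible pairs are leg-leg pairs where at least one side is membrane
    associated (unless cytosolic dimerization is enabled) and adaptor-site /
    adaptor pairs.  Conflicts are resolved by a random visiting order;
    first accepted wins and freezes its participants.
    """
    kin, geom = state.kin, state.geom
    rates = state.rates
    sigma = kin.sigma_react_nm
    free_leg = state.leg_bond[:, :, 0] < 0  # (N, 3)
    z = state.clat_pos[:, 2]
    z_mem = geom.membrane_anchor_z_nm

    candidates: list[tuple] = []
    labels, _ = state.components()

    # ---- leg-leg
    # with cytosolic dimerization off, only membrane molecules and
    # cytosolic ones whose legs can physically reach the membrane plane
    # can form a candidate pair; the cutoff is exact, not approximate
    if kin.allow_cytosolic_dimerization:
        leg_mask = np.ones(state.n_clathrin, dtype=bool)
    else:
        leg_mask = state.clat_mem | (z <= z_mem + sigma + geom.leg_length_nm + 1e-9)
        if not state.clat_mem.any():
            leg_mask[:] = False
    leg_mol = np.flatnonzero(leg_mask & free_leg.any(axis=1))
    if len(leg_mol) >= 2:
        sub_sites = site_positions_many(
            state.clat_pos[leg_mol], state.clat_quat[leg_mol], geom
        )
        sub_free = free_leg[leg_mol]
        loc_idx = np.argwhere(sub_free)  # (K, 2): local molecule, leg
        leg_pos = sub_sites[loc_idx[:, 0], loc_idx[:, 1]]
        for a, b in _self_pairs_within(leg_pos, sigma):
            i, si = int(leg_mol[loc_idx[a, 0]]), int(loc_idx[a, 1])
            j, sj = int(leg_mol[loc_idx[b, 0]]), int(loc_idx[b, 1])
            if i == j:
                continue
            if (i, si) > (j, sj):
                i, si, j, sj = j, sj, i, si
            mem_i, mem_j = state.clat_mem[i], state.clat_mem[j]
            if not (mem_i or mem_j) and not kin.allow_cytosolic_dimerization:
                continue
            if (
                kin.require_direct_anchor
                and labels[i] != labels[j]
                and state.clat_ap2[i] < 0
                and state.clat_ap2[j] < 0
            ):
                continue
            p = rates["p2_cc"] if (mem_i and mem_j) else rates["p3_cc"]
            if p > 0:
                candidates.append(("cc", i, si, j, sj, p))

    # ---- adaptor site / adaptor (same exact reach cutoff, arm length)
    ca_mask = (state.clat_ap2 < 0) & (
        state.clat_mem
        | (z <= geom.ap2_radius_nm + sigma + geom.ap2_arm_length_nm + 1e-9)
    )
    free_site_c = np.flatnonzero(ca_mask)
    free_a = np.flatnonzero(state.ap2_bond < 0)
    if len(free_site_c) and len(free_a):
        ap3 = state.ap2_pos3()[free_a]
        site_pos = site_positions_many(
            state.clat_pos[free_site_c], state.clat_quat[free_site_c], geom
        )[:, 3]
        for ci_loc, a_loc in _cross_pairs_within(site_pos, ap3, sigma):
            i = int(free_site_c[ci_loc])
            p = rates["p2_ca"] if state.clat_mem[i] else rates["p3_ca"]
            if p > 0:
                candidates.append(("ca", i, int(free_a[a_loc]), p))

    if not candidates:
        return
    # canonical order: reaction outcomes depend only on the candidate SET
    # and the RNG stream, never on enumeration order
    candidates.sort()

    changed = False
    for k in state.rng.permutation(len(candidates)):
        cand = candidates[k]
        if cand[0] == "ca":
            _, i, a, p = cand
            if reacted_c[i] or reacted_a[a]:
                continue
            if state.clat_ap2[i] >= 0 or state.ap2_bond[a] >= 0:
                continue
            if state.rng.random() >= p:
                continue
            if _attempt_bind_ca(state, i, a):
                reacted_c[i] = True
                reacted_a[a] = True
                changed = True
        else:
            _, i, si, j, sj, p = cand
            if reacted_c[i] or reacted_c[j]:
                continue
            if state.leg_bond[i, si, 0] >= 0 or state.leg_bond[j, sj, 0] >= 0:
                continue
            if state.rng.random() >= p:
                continue
            if _attempt_bind_cc(state, i, si, j, sj, labels):
                reacted_c[i] = reacted_c[j] = True
                changed = True
                labels, _ = state.components()
    if changed:
        state.refresh_compartments()


def _attempt_bind_ca(state: SimState, i: int, a: int) -> bool:
    """Bind clathrin ``i``'s adaptor site to adaptor ``a``; may move either side."""
    from .model_core import site_positions

    geom = state.geom
    if state.clat_mem[i]:
        # anchored cluster member: pull the free adaptor under the site
        site_xy = site_positions(state.clat_pos[i], state.clat_quat[i], geom)[3, :2]
        state.ap2_pos[a] = np.clip(site_xy, 0.0, state.box.edge_nm)
    else:
        # recruit the cytosolic unit: translate it so the adaptor site of
        # clathrin i lands on the adaptor bead, flattening the molecule plane
        labels, members = state.components()
        unit = members[labels[i]]
        anchor_z = geom.membrane_anchor_z_nm
        if len(unit) == 1:
            yaw = _yaw_from_quat_vec(state.clat_quat[i])
            new_pos = np.array([state.ap2_pos[a, 0], state.ap2_pos[a, 1], anchor_z])
            tent = state.clat_pos.copy()
            tent[i] = new_pos
            if not _overlap_ok(state, tent, np.array([i])):
                return False
            state.clat_pos[i] = new_pos
            state.clat_quat[i] = yaw_quat(yaw)
        else:
            # detached flat oligomer re-anchoring: translate in xy and z only
            site_i = site_positions(state.clat_pos[i], state.clat_quat[i], geom)
            delta_xy = state.ap2_pos[a] - site_i[3, :2]
            delta_z = anchor_z - state.clat_pos[i, 2]
            tent = state.clat_pos.copy()
            tent[unit, 0] += delta_xy[0]
            tent[unit, 1] += delta_xy[1]
            tent[unit, 2] += delta_z
            if np.any(tent[unit] < 0) or np.any(tent[unit] > state.box.edge_nm):
                return False
            if not _overlap_ok(state, tent, unit):
                return False
            state.clat_pos = tent
            ap2s = state.clat_ap2[unit]
            ap2s = ap2s[ap2s >= 0]
            if len(ap2s):
                state.ap2_pos[ap2s] += delta_xy
    # adaptor bonds do not alter the leg-bond component topology
    state.clat_ap2[i] = a
    state.ap2_bond[a] = i
    state.event_log.append((state.time_s, "bind_ca", i, a))
    return True


def _yaw_from_quat_vec(q: np.ndarray) -> float:
    ex = quat_to_matrix(q)[:, 0]
    return float(np.arctan2(ex[1], ex[0]))


def _attempt_bind_cc(
    state: SimState, i: int, si: int, j: int, sj: int, labels: np.ndarray
) -> bool:
    """Head-to-head leg bond between clathrins ``i`` and ``j``.

    Same-complex pairs close a ring without movement if the geometry is
    already satisfied; otherwise the unanchored (or smaller) unit is moved
    rigidly into place, rejecting on overlap or boundary violation.
    """
    from .model_core import site_positions

    geom = state.geom
    if labels[i] == labels[j]:
        # ring closure: geometry must already be head-to-head at bond length
        s_i = site_positions(state.clat_pos[i], state.clat_quat[i], geom)[si]
        s_j = site_positions(state.clat_pos[j], state.clat_quat[j], geom)[sj]
        sep = s_j - s_i
        d = np.linalg.norm(sep)
        if abs(d - geom.bond_length_nm) > 0.5:
            return False
        u_i = (s_i - state.clat_pos[i]) / geom.leg_length_nm
        u_j = (s_j - state.clat_pos[j]) / geom.leg_length_nm
        if np.dot(u_i, u_j) > -0.999 or np.dot(sep / d, u_i) < 0.999:
            return False
        state.leg_bond[i, si] = (j, sj)
        state.leg_bond[j, sj] = (i, si)
        state.invalidate_bonds()  # ring closure: same component
        state.event_log.append((state.time_s, "bind_cc", i, si, j, sj))
        return True

    _, members = state.components()
    unit_i, unit_j = members[labels[i]], members[labels[j]]
    mem_i, mem_j = state.clat_mem[i], state.clat_mem[j]
    # choose mobile side: cytosolic over membrane, then smaller unit
    if mem_i and not mem_j:
        anchor, a_site, mobile, m_site, m_unit = i, si, j, sj, unit_j
    elif mem_j and not mem_i:
        anchor, a_site, mobile, m_site, m_unit = j, sj, i, si, unit_i
    elif len(unit_i) >= len(unit_j):
        anchor, a_site, mobile, m_site, m_unit = i, si, j, sj, unit_j
    else:
        anchor, a_site, mobile, m_site, m_unit = j, sj, i, si, unit_i
    if not state.clat_mem[anchor] and not state.kin.allow_cytosolic_dimerization:
        return False
    try:
        new_center, new_quat = bound_partner_pose(
            state.clat_pos[anchor], state.clat_quat[anchor], a_site, m_site, geom
        )
    except ValueError:
        return False
    ap2s = state.clat_ap2[m_unit]
    ap2s = ap2s[ap2s >= 0]
    pos_new, quat_new, ap2_xy = _unit_transform(
        state, m_unit, ap2s, mobile, new_center, new_quat
    )
    L = state.box.edge_nm
    if np.any(pos_new < 0) or np.any(pos_new > L):
        return False
    if len(ap2s) and (np.any(ap2_xy < 0) or np.any(ap2_xy > L)):
        return False
    tent = state.clat_pos.copy()
    tent[m_unit] = pos_new
    extra = {(min(anchor, mobile), max(anchor, mobile))}
    if not _overlap_ok(state, tent, m_unit, extra_bonded=extra):
        return False
    state.clat_pos = tent
    state.clat_quat[m_unit] = quat_new
    if len(ap2s):
        state.ap2_pos[ap2s] = ap2_xy
    state.leg_bond[anchor, a_site] = (mobile, m_site)
    state.leg_bond[mobile, m_site] = (anchor, a_site)
    state.invalidate_bonds()
    state.merge_components(anchor, mobile)
    state.event_log.append((state.time_s, "bind_cc", anchor, a_site, mobile, m_site))
    return True


def _quat_mul_many(dq: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise Hamilton product dq * q for (K, 4) arrays."""
    w1, x1, y1, z1 = dq[:, 0], dq[:, 1], dq[:, 2], dq[:, 3]
    w2, x2, y2, z2 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=1,
    )


def _reflect_into(x: np.ndarray, L: float) -> np.ndarray:
    x = np.where(x < 0, -x, x)
    return np.where(x > L, 2 * L - x, x)


def diffuse_sweep(
    state: SimState, reacted_c: np.ndarray, reacted_a: np.ndarray
) -> None:
    """Brownian update of every non-reacted unit; overlaps resampled.

    Per-axis displacement standard deviation is ``sqrt(2 D dt)`` (three
    axes for cytosolic units, two in-plane axes for membrane units);
    rotations use an angular scale ``sqrt(2 D_rot dt)``.  Overlapping
    proposals are redrawn up to ``MAX_MOVE_RETRIES`` times, then the move
    is skipped and counted.  Box boundaries reflect the unit displacement
    as a whole so rigid geometry is preserved.
    """
    kin = state.kin
    dt = kin.dt_s
    rng = state.rng
    L = state.box.edge_nm

    # free adaptors: independent in-plane moves, reflecting boundaries
    free_a = np.flatnonzero((state.ap2_bond < 0) & ~reacted_a)
    if len(free_a):
        s = np.sqrt(2.0 * units.um2_s_to_nm2_s(kin.d_ap2_trans_um2_s) * dt)
        state.ap2_pos[free_a] = _reflect_into(
            state.ap2_pos[free_a] + rng.normal(0.0, s, size=(len(free_a), 2)), L
        )

    labels, members = state.components()
    sizes = np.array([len(m) for m in members], dtype=np.int64)
    # per-component reacted flag
    comp_reacted = np.zeros(len(members), dtype=bool)
    if reacted_c.any():
        np.logical_or.at(comp_reacted, labels, reacted_c)
    bound_a = np.flatnonzero(state.ap2_bond >= 0)
    if len(bound_a) and reacted_a[bound_a].any():
        for a in bound_a[reacted_a[bound_a]]:
            comp_reacted[labels[state.ap2_bond[a]]] = True

    tent_pos = state.clat_pos.copy()
    tent_quat = state.clat_quat.copy()
    tent_ap2 = state.ap2_pos.copy()

    # ---- vectorized fast path: single-molecule units
    mono = np.flatnonzero((sizes[labels] == 1) & ~comp_reacted[labels])
    cyt_mono = mono[~state.clat_mem[mono]]
    mem_mono = mono[state.clat_mem[mono]]

    def propose_cyt_mono(idx: np.ndarray) -> None:
        if not len(idx):
            return
        s = np.sqrt(2.0 * units.um2_s_to_nm2_s(kin.d_clat_trans_um2_s) * dt)
        tent_pos[idx] = _reflect_into(
            state.clat_pos[idx] + rng.normal(0.0, s, size=(len(idx), 3)), L
        )
        if kin.d_clat_rot_s > 0:
            w = rng.normal(0.0, np.sqrt(2.0 * kin.d_clat_rot_s * dt), size=(len(idx), 3))
            angle = np.linalg.norm(w, axis=1)
            angle = np.where(angle == 0, 1e-300, angle)
            axis = w / angle[:, None]
            half = 0.5 * angle
            dq = np.concatenate([np.cos(half)[:, None], np.sin(half)[:, None] * axis], axis=1)
            q = _quat_mul_many(dq, state.clat_quat[idx])
            tent_quat[idx] = q / np.linalg.norm(q, axis=1, keepdims=True)

    def propose_mem_mono(idx: np.ndarray) -> None:
        # a membrane monomer and its adaptor share the same xy; yaw
        # rotation about the unit centroid therefore moves nothing
        if not len(idx):
            return
        d_t, d_r = state.unit_diffusion(1, 1, True)
        s = np.sqrt(2.0 * units.um2_s_to_nm2_s(d_t) * dt)
        xy = _reflect_into(
            state.clat_pos[idx, :2] + rng.normal(0.0, s, size=(len(idx), 2)), L
        )
        tent_pos[idx, :2] = xy
        tent_ap2[state.clat_ap2[idx]] = xy
        if d_r > 0:
            dphi = rng.normal(0.0, np.sqrt(2.0 * d_r * dt), size=len(idx))
            dq = np.zeros((len(idx), 4))
            dq[:, 0] = np.cos(dphi / 2.0)
            dq[:, 3] = np.sin(dphi / 2.0)
            tent_quat[idx] = _quat_mul_many(dq, state.clat_quat[idx])

    propose_cyt_mono(cyt_mono)
    propose_mem_mono(mem_mono)

    # ---- multi-molecule units
    multi = [
        c
        for c in np.flatnonzero((sizes > 1) & ~comp_reacted)
        if True
    ]
    multi_views: dict[int, ComplexView] = {}
    for c in multi:
        mem_idx = members[c]
        ap2s = state.clat_ap2[mem_idx]
        ap2s = ap2s[ap2s >= 0]
        membrane = bool(state.clat_mem[mem_idx].any())
        d_t, d_r = state.unit_diffusion(len(mem_idx), len(ap2s), membrane)
        multi_views[int(c)] = ComplexView(mem_idx, ap2s, membrane, d_t, d_r)

    def propose_multi(u: ComplexView) -> None:
        mem_idx = u.clathrins
        s = np.sqrt(2.0 * units.um2_s_to_nm2_s(u.d_trans_um2_s) * dt)
        draw = rng.normal(0.0, 1.0, size=4)
        if u.membrane:
            disp = np.array([s * draw[0], s * draw[1], 0.0])
            dphi = np.sqrt(2.0 * u.d_rot_s * dt) * draw[3] if u.d_rot_s > 0 else 0.0
            if abs(dphi) < 1e-3:
                # sub-0.2 nm site displacement for any cluster that fits the
                # box: skip the rotation update, keep the draw for stream
                # stability
                dphi = 0.0
        else:
            disp = s * draw[:3]
            dphi = 0.0  # detached flat oligomers translate without tumbling
        new_pos = state.clat_pos[mem_idx] + disp
        new_ap2 = state.ap2_pos[u.ap2s] + disp[:2] if len(u.ap2s) else None
        if dphi != 0.0:
            pivot = state.clat_pos[mem_idx].mean(axis=0)
            c_, sn = np.cos(dphi), np.sin(dphi)
            rot = np.array([[c_, -sn], [sn, c_]])
            rel = state.clat_pos[mem_idx, :2] - pivot[:2]
            new_pos[:, :2] = rel @ rot.T + pivot[:2] + disp[:2]
            tent_quat[mem_idx] = _quat_mul_many(
                yaw_quat(dphi)[None, :], state.clat_quat[mem_idx]
            )
            if new_ap2 is not None:
                rel_a = state.ap2_pos[u.ap2s] - pivot[:2]
                new_ap2 = rel_a @ rot.T + pivot[:2] + disp[:2]
        else:
            tent_quat[mem_idx] = state.clat_quat[mem_idx]
        # reflect the unit displacement off the walls, preserving shape
        lo = new_pos.min(axis=0)
        hi = new_pos.max(axis=0)
        if new_ap2 is not None:
            lo[:2] = np.minimum(lo[:2], new_ap2.min(axis=0))
            hi[:2] = np.maximum(hi[:2], new_ap2.max(axis=0))
        if np.any(lo < 0) or np.any(hi > L):
            axes = (0, 1) if u.membrane else (0, 1, 2)
            for ax in axes:
                shift = 0.0
                if lo[ax] < 0:
                    shift = -2.0 * lo[ax]
                elif hi[ax] > L:
                    shift = 2.0 * (L - hi[ax])
                if shift:
                    if hi[ax] - lo[ax] > L or min(-lo[ax], hi[ax] - L) * 2 > L:
                        shift = -lo[ax] if lo[ax] < 0 else (L - hi[ax])
                    new_pos[:, ax] += shift
                    if ax < 2 and new_ap2 is not None:
                        new_ap2[:, ax] += shift
        tent_pos[mem_idx] = new_pos
        if new_ap2 is not None:
            tent_ap2[u.ap2s] = new_ap2

    for c in multi:
        propose_multi(multi_views[c])

    # ---- overlap resolution: resample offending mover units
    mover_comps = set(int(labels[i]) for i in mono) | set(int(c) for c in multi)
    if state.n_clathrin > 1:
        if state.bond_exemption_needed():
            bonded = {(int(a), int(b)) for a, b in state.bonded_pairs_array()}
        else:
            bonded = set()
        cutoff = 2.0 * state.geom.excluded_radius_nm

        def bad_components() -> set[int]:
            tree = cKDTree(tent_pos)
            bad: set[int] = set()
            for a, b in tree.query_pairs(cutoff):
                pair = (min(int(a), int(b)), max(int(a), int(b)))
                if pair in bonded:
                    continue
                for m in pair:
                    lb = int(labels[m])
                    if lb in mover_comps:
                        bad.add(lb)
            return bad

        def revert(lb: int) -> np.ndarray:
            mem_idx = members[lb]
            tent_pos[mem_idx] = state.clat_pos[mem_idx]
            tent_quat[mem_idx] = state.clat_quat[mem_idx]
            ap2s = state.clat_ap2[mem_idx]
            ap2s = ap2s[ap2s >= 0]
            if len(ap2s):
                tent_ap2[ap2s] = state.ap2_pos[ap2s]
            return mem_idx

        tries = 0
        while True:
            bad = bad_components()
            if not bad:
                break
            tries += 1
            for lb in sorted(bad):
                mem_idx = revert(lb)
                if tries >= MAX_MOVE_RETRIES:
                    state.skipped_moves += 1  # frozen in place this step
                    state.event_log.append(
                        (state.time_s, "skipped_move", int(mem_idx[0]))
                    )
                    continue
                if lb in multi_views:
                    propose_multi(multi_views[lb])
                elif state.clat_mem[mem_idx[0]]:
                    propose_mem_mono(mem_idx)
                else:
                    propose_cyt_mono(mem_idx)
            if tries >= MAX_MOVE_RETRIES:
                break

    state.clat_pos = tent_pos
    # renormalize each step: repeated rigid transforms amplify scale drift
    state.clat_quat = tent_quat / np.linalg.norm(tent_quat, axis=1, keepdims=True)
    state.ap2_pos = tent_ap2
    state.time_s += dt


def step(state: SimState) -> SimState:
    """One timestep: dissociation, association, then diffusion of non-reacted units."""
    reacted_c, reacted_a = dissociation_sweep(state)
    association_sweep(state, reacted_c, reacted_a)
    diffuse_sweep(state, reacted_c, reacted_a)
    return state


def run(
    state: SimState,
    duration_s: float,
    frame_interval_s: float,
    controller: Optional[Callable[[SimState], None]] = None,
) -> Trajectory:
    """Advance the state for ``duration_s``, recording a frame every
    ``frame_interval_s`` (plus the initial state).  ``controller`` is
    invoked before every step (used by time-varying protocols).
    """
    dt = state.kin.dt_s
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if frame_interval_s < dt:
        raise ValueError("frame_interval must be >= dt")
    n_steps = int(round(duration_s / dt))
    stride = max(1, int(round(frame_interval_s / dt)))
    frames = [state.snapshot()]
    for k in range(1, n_steps + 1):
        if controller is not None:
            controller(state)
        step(state)
        if k % stride == 0 or k == n_steps:
            frames.append(state.snapshot())
    return Trajectory(
        frames=frames,
        events=list(state.event_log),
        geom=state.geom,
        kin=state.kin,
        box=state.box,
        skipped_moves=state.skipped_moves,
    )
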