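"""Domain types and rigid-body geometry.

A clathrin triskelion is a rigid planar body: three leg sites at 120 degrees
in the molecule plane plus one adaptor-binding site on the axis normal to
that plane.  Membrane-bound clathrins keep their plane parallel to z = 0
with the adaptor arm pointing down.  All geometric operations here are pure
functions over coordinates; the time-stepping engine lives in
:mod:`fclsim.simulator`.

Coordinates: nm, right-handed, z up from the membrane plane z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Compartment",
    "LateralBoundary",
    "BoxGeometry",
    "SiteGeometryParams",
    "KineticParams",
    "ClathrinMolecule",
    "AP2Molecule",
    "PlacementError",
    "leg_local_coords",
    "site_positions",
    "yaw_quat",
    "quat_mul",
    "quat_rotate",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "random_quat",
    "place_bound_pair",
    "detect_overlap",
    "overlapping_pairs",
    "apply_boundaries",
]


class Compartment(str, Enum):
    CYTOSOL = "cytosol"
    MEMBRANE = "membrane"


class LateralBoundary(str, Enum):
    REFLECTING = "reflecting"
    PERIODIC = "periodic"


@dataclass(frozen=True)
class BoxGeometry:
    """Cubic simulation domain; the z = 0 face is the membrane plane."""

    edge_nm: float = 1000.0
    lateral_boundary: LateralBoundary = LateralBoundary.REFLECTING

    def __post_init__(self) -> None:
        if self.edge_nm <= 0:
            raise ValueError("edge_nm must be positive")

    @property
    def edge_um(self) -> float:
        return self.edge_nm / 1e3

    def contains(self, pos: np.ndarray) -> np.ndarray:
        p = np.asarray(pos, dtype=float)
        return np.all((p >= 0.0) & (p <= self.edge_nm), axis=-1)


@dataclass(frozen=True)
class SiteGeometryParams:
    """Site-arm lengths and hard-core geometry.

    ``bond_length_nm`` is the head-to-head separation of two bound leg
    sites; ``excluded_radius_nm`` the hard-core radius of a clathrin
    (non-bonded centers may not come closer than twice this value).
    """

    bond_length_nm: float = 5.0
    excluded_radius_nm: float = 10.0
    leg_length_nm: float = 21.0
    ap2_arm_length_nm: float = 10.0
    ap2_radius_nm: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "bond_length_nm",
            "excluded_radius_nm",
            "leg_length_nm",
            "ap2_arm_length_nm",
            "ap2_radius_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def membrane_anchor_z_nm(self) -> float:
        """Height of a membrane-bound clathrin center above z = 0."""
        return self.ap2_arm_length_nm + self.ap2_radius_nm

    @property
    def bonded_center_distance_nm(self) -> float:
        """Center-to-center distance of two leg-bonded clathrins."""
        return 2.0 * self.leg_length_nm + self.bond_length_nm


@dataclass
class KineticParams:
    """Rates, diffusion coefficients and stepping parameters.

    Values not printed in the source material (off-rates, adaptor
    diffusion, rotational diffusion) are repository defaults; every field
    is exposed through the configuration schema.
    """

    k_clat_clat_on_uM_s: float = 1.83
    k_clat_clat_off_s: float = 1.0
    k_clat_ap2_on_uM_s: float = 2.0
    k_clat_ap2_off_s: float = 0.5
    d_clat_trans_um2_s: float = 13.0
    d_clat_rot_s: float = 1.0e4
    d_clat_mem_trans_um2_s: float = 0.5
    d_clat_mem_rot_s: float = 1.0e3
    d_ap2_trans_um2_s: float = 0.5
    dt_s: float = 3.0e-6
    sigma_react_nm: float = 10.0
    rate_2d_lengthscale_nm: float = 20.0
    allow_cytosolic_dimerization: bool = False
    # the clathrin-clathrin rate is the rate of binding TO an adaptor-bound
    # clathrin: new inter-complex leg bonds require a directly anchored partner
    require_direct_anchor: bool = True

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        for name in (
            "k_clat_clat_on_uM_s",
            "k_clat_clat_off_s",
            "k_clat_ap2_on_uM_s",
            "k_clat_ap2_off_s",
            "d_clat_trans_um2_s",
            "d_clat_rot_s",
            "d_clat_mem_trans_um2_s",
            "d_clat_mem_rot_s",
            "d_ap2_trans_um2_s",
            "sigma_react_nm",
            "rate_2d_lengthscale_nm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ClathrinMolecule:
    """View of one triskelion: pose plus per-site bond references.

    ``leg_bonds[i]`` is ``(partner_clathrin_id, partner_site)`` or ``None``;
    ``ap2_bond`` is the bound adaptor id or ``None``.
    """

    id: int
    center: np.ndarray
    quat: np.ndarray
    compartment: Compartment
    leg_bonds: list = field(default_factory=lambda: [None, None, None])
    ap2_bond: Optional[int] = None

    def sites(self, geom: SiteGeometryParams) -> np.ndarray:
        """(4, 3) world positions: legs 0..2 then the adaptor site."""
        return site_positions(self.center, self.quat, geom)


@dataclass
class AP2Molecule:
    """Membrane-resident adaptor; position is confined to z = 0."""

    id: int
    position: np.ndarray  # (2,) xy on the membrane, nm
    bond: Optional[int] = None  # clathrin id


class PlacementError(ValueError):
    """Raised when a binding transform cannot be satisfied."""


# ---------------------------------------------------------------------------
# quaternions (scalar-first, unit)

def quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=float) @ quat_to_matrix(q).T


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = axis / n
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def yaw_quat(phi: float) -> np.ndarray:
    """Rotation by ``phi`` about +z (the membrane normal)."""
    return np.array([np.cos(phi / 2.0), 0.0, 0.0, np.sin(phi / 2.0)])


def yaw_of_quat(q: np.ndarray) -> float:
    """Yaw angle of the rotated local +x axis projected on the xy plane."""
    ex = quat_rotate(q, np.array([1.0, 0.0, 0.0]))
    return float(np.arctan2(ex[1], ex[0]))


def random_quat(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Shoemake)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.array(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ]
    )


# ---------------------------------------------------------------------------
# site geometry

LEG_ANGLES = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])


def leg_local_coords(geom: SiteGeometryParams) -> np.ndarray:
    """(4, 3) local site coordinates: three legs in-plane, adaptor arm -z."""
    legs = np.zeros((4, 3))
    legs[:3, 0] = geom.leg_length_nm * np.cos(LEG_ANGLES)
    legs[:3, 1] = geom.leg_length_nm * np.sin(LEG_ANGLES)
    legs[3, 2] = -geom.ap2_arm_length_nm
    return legs


def site_positions(
    center: np.ndarray, quat: np.ndarray, geom: SiteGeometryParams
) -> np.ndarray:
    return np.asarray(center, dtype=float) + leg_local_coords(geom) @ quat_to_matrix(quat).T


def site_positions_many(
    centers: np.ndarray, quats: np.ndarray, geom: SiteGeometryParams
) -> np.ndarray:
    """(N, 4, 3) site positions for N molecules; vectorized."""
    centers = np.asarray(centers, dtype=float)
    quats = np.asarray(quats, dtype=float)
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    mats = np.empty((len(quats), 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - w * z)
    mats[:, 0, 2] = 2 * (x * z + w * y)
    mats[:, 1, 0] = 2 * (x * y + w * z)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - w * x)
    mats[:, 2, 0] = 2 * (x * z - w * y)
    mats[:, 2, 1] = 2 * (y * z + w * x)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    local = leg_local_coords(geom)  # (4, 3)
    return centers[:, None, :] + np.einsum("nij,sj->nsi", mats, local)


# ---------------------------------------------------------------------------
# binding placement

def place_bound_pair(
    clat_a: ClathrinMolecule,
    site_a: int,
    clat_b: ClathrinMolecule,
    site_b: int,
    geom: SiteGeometryParams,
) -> tuple[ClathrinMolecule, ClathrinMolecule]:
    """Pose molecule B so sites ``site_a``/``site_b`` bind head-to-head.

    A is treated as anchored and is never moved.  The returned B pose has
    the two bound sites ``bond_length_nm`` apart, collinear with the A leg
    direction, with both molecule planes coplanar and parallel to z = 0.
    """
    if site_a not in (0, 1, 2) or site_b not in (0, 1, 2):
        raise PlacementError("leg site index must be 0, 1 or 2")
    if clat_a.leg_bonds[site_a] is not None:
        raise PlacementError(f"site {site_a} of clathrin {clat_a.id} is occupied")
    if clat_b.leg_bonds[site_b] is not None:
        raise PlacementError(f"site {site_b} of clathrin {clat_b.id} is occupied")

    new_center, new_quat = bound_partner_pose(
        clat_a.center, clat_a.quat, site_a, site_b, geom
    )
    clat_b = ClathrinMolecule(
        id=clat_b.id,
        center=new_center,
        quat=new_quat,
        compartment=clat_a.compartment,
        leg_bonds=list(clat_b.leg_bonds),
        ap2_bond=clat_b.ap2_bond,
    )
    clat_a.leg_bonds[site_a] = (clat_b.id, site_b)
    clat_b.leg_bonds[site_b] = (clat_a.id, site_a)
    return clat_a, clat_b


def bound_partner_pose(
    center_a: np.ndarray,
    quat_a: np.ndarray,
    site_a: int,
    site_b: int,
    geom: SiteGeometryParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Pose (center, quat) for a partner bound head-to-head at A's leg.

    The partner plane is made parallel to A's plane (flat, z-up), the
    partner leg antiparallel to A's leg; works for any anchored yaw of A
    as long as A itself is flat.
    """
    site_world = site_positions(center_a, quat_a, geom)[site_a]
    u = site_world - np.asarray(center_a, dtype=float)
    u_norm = np.linalg.norm(u)
    if u_norm == 0:
        raise PlacementError("degenerate leg direction")
    u = u / u_norm
    if abs(u[2]) > 1e-9:
        raise PlacementError("anchored molecule plane is not parallel to z = 0")
    alpha = np.arctan2(u[1], u[0])
    # partner leg must point along -u: yaw + leg_angle = alpha + pi
    yaw_b = alpha + np.pi - LEG_ANGLES[site_b]
    target_site = site_world + geom.bond_length_nm * u
    center_b = target_site + geom.leg_length_nm * u
    center_b[2] = center_a[2]
    return center_b, yaw_quat(yaw_b)


# ---------------------------------------------------------------------------
# overlap and boundaries

def overlapping_pairs(
    centers: np.ndarray,
    bonded_pairs: Sequence[tuple[int, int]],
    geom: SiteGeometryParams,
) -> list[tuple[int, int]]:
    """Non-bonded index pairs with center distance < 2 * excluded radius."""
    from scipy.spatial import cKDTree

    centers = np.asarray(centers, dtype=float)
    if len(centers) < 2:
        return []
    cutoff = 2.0 * geom.excluded_radius_nm
    tree = cKDTree(centers)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return []
    bonded = {(min(a, b), max(a, b)) for a, b in bonded_pairs}
    out = []
    for a, b in pairs:
        key = (int(min(a, b)), int(max(a, b)))
        if key not in bonded:
            out.append(key)
    return out


def detect_overlap(
    centers: np.ndarray,
    bonded_pairs: Sequence[tuple[int, int]],
    geom: SiteGeometryParams,
    which: Optional[Sequence[int]] = None,
) -> bool:
    """True iff any non-bonded clathrin pair violates the hard core.

    ``which`` restricts the test to pairs touching the given molecule
    indices (e.g. the ones that just moved).
    """
    pairs = overlapping_pairs(centers, bonded_pairs, geom)
    if which is None:
        return bool(pairs)
    wanted = set(int(i) for i in which)
    return any(a in wanted or b in wanted for a, b in pairs)


def apply_boundaries(pos: np.ndarray, box: BoxGeometry) -> np.ndarray:
    """Fold a point position back into the box.

    z is always reflected; x/y are reflected or wrapped depending on the
    lateral boundary.  Idempotent for in-box points.  Displacements larger
    than the box edge indicate a pathological dt/D combination and raise.
    """
    p = np.array(pos, dtype=float)
    L = box.edge_nm
    if np.any(np.abs(p - L / 2.0) > 1.5 * L):
        raise ValueError("position more than one box length outside the domain")
    # reflecting fold
    def reflect(x: np.ndarray) -> np.ndarray:
        x = np.mod(x, 2.0 * L)
        return np.where(x > L, 2.0 * L - x, x)

    if box.lateral_boundary is LateralBoundary.PERIODIC:
        p[..., 0] = np.mod(p[..., 0], L)
        p[..., 1] = np.mod(p[..., 1], L)
    else:
        p[..., 0] = reflect(p[..., 0])
        p[..., 1] = reflect(p[..., 1])
    p[..., 2] = reflect(p[..., 2])
    return p
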