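"""Experiment drivers: initial conditions, parameter sweeps, growth-factor
stimulus schedules and the well-mixed validation harness.

The ``desk_preset`` is a deliberately scaled-down configuration (smaller
box, copy numbers scaled to keep concentrations, larger timestep, seconds
of simulated time) so sweeps and stimulus runs finish on a laptop; every
test that exercises trend directions uses it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import units
from .analysis import MetricsReport, frames_to_stats, summarize
from .config import SimConfig, config_hash
from .model_core import (
    LEG_ANGLES,
    SiteGeometryParams,
    random_quat,
    site_positions_many,
    yaw_quat,
)
from .simulator import (
    SimState,
    Trajectory,
    calibrate_lambda_3d,
    combine_diffusion,
    dissociation_probability,
    run,
)

__all__ = [
    "desk_preset",
    "random_initial_state",
    "single_cluster_initial_state",
    "SweepSpec",
    "run_sweep",
    "EGFSchedule",
    "ScheduleController",
    "egf_experiment",
    "validate_well_mixed",
    "dissociation_waiting_times",
]

PACKING_RETRY = 2000


# ---------------------------------------------------------------------------
# presets

def desk_preset(**overrides) -> SimConfig:
    """Scaled-down configuration for desk-scale experiments.

    0.5 um box with copy numbers scaled with the membrane area, a raised
    timestep (the engine warns that per-step reaction probabilities exceed
    0.1) and fast adaptor binding so the membrane population saturates
    within the first simulated seconds.  Off-rates are large enough that
    assembly/disassembly dynamics are observable in seconds of simulated
    time; the preset preserves the qualitative regime (recruitment
    saturation before metrics are read off), not the original clock.
    """
    cfg = SimConfig(
        box_edge_um=0.5,
        n_clathrin=30,
        n_ap2=40,
        duration_s=8.0,
        frame_interval_s=0.05,
    )
    cfg = cfg.with_overrides(
        **{
            "kinetics.dt_s": 3e-4,
            "kinetics.k_clat_clat_on_uM_s": 5.0,
            "kinetics.k_clat_clat_off_s": 20.0,
            "kinetics.k_clat_ap2_on_uM_s": 20.0,
            "kinetics.k_clat_ap2_off_s": 0.5,
            "kinetics.d_ap2_trans_um2_s": 0.01,
            "kinetics.d_clat_mem_trans_um2_s": 0.01,
            "kinetics.d_clat_rot_s": 50.0,
            "kinetics.d_clat_mem_rot_s": 5.0,
        }
    )
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg


# ---------------------------------------------------------------------------
# initial conditions

def _sample_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    box_nm: float,
    min_dist: float,
    fixed: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Uniform positions in the box with hard-core rejection sampling."""
    from scipy.spatial import cKDTree

    out = np.zeros((0, 3))
    attempts = 0
    while len(out) < n:
        if attempts > PACKING_RETRY:
            raise RuntimeError(f"could not pack {n} molecules without overlap")
        attempts += 1
        cand = rng.uniform(0.0, box_nm, size=3)
        ref = out if fixed is None else np.vstack([out, fixed])
        if len(ref):
            if np.min(np.linalg.norm(ref - cand, axis=1)) < min_dist:
                continue
        out = np.vstack([out, cand])
    return out


def random_initial_state(config: SimConfig, seed: Optional[int] = None) -> SimState:
    """Clathrins uniform in the box with uniform random orientations,
    adaptors uniform on the membrane, no bonds."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = config.box()
    geom = config.geometry
    n = config.n_clathrin
    pos = (
        _sample_nonoverlapping(rng, n, box.edge_nm, 2 * geom.excluded_radius_nm)
        if n
        else np.zeros((0, 3))
    )
    quats = np.array([random_quat(rng) for _ in range(n)]).reshape(n, 4)
    ap2 = rng.uniform(0.0, box.edge_nm, size=(config.n_ap2, 2))
    state = SimState(
        box=box,
        geom=geom,
        kin=replace(config.kinetics),
        clat_pos=pos,
        clat_quat=quats,
        clat_mem=np.zeros(n, dtype=bool),
        ap2_pos=ap2,
        rng=rng,
    )
    state.refresh_rates()
    return state


def _honeycomb_patch(
    n: int, geom: SiteGeometryParams, center_xy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int, int]]]:
    """Connected flat hexagonal patch of n triskelia grown breadth-first.

    Returns (centers(n,3 with z=0), yaw angles(n,), bond list
    (i, site_i, j, site_j)).  Every neighbor pair at lattice distance is
    bonded, so rings are closed.
    """
    a = geom.bonded_center_distance_nm
    centers: list[np.ndarray] = [np.array([0.0, 0.0])]
    yaws: list[float] = [0.0]
    seen = {(0, 0)}

    def key(p: np.ndarray) -> tuple[int, int]:
        return (int(round(p[0] * 10)), int(round(p[1] * 10)))

    frontier = [0]
    while len(centers) < n and frontier:
        nxt = []
        for i in frontier:
            for ang in LEG_ANGLES + yaws[i]:
                p = centers[i] + a * np.array([np.cos(ang), np.sin(ang)])
                k = key(p)
                if k in seen:
                    continue
                seen.add(k)
                centers.append(p)
                yaws.append(np.pi / 3.0 if abs(yaws[i]) < 1e-9 else 0.0)
                nxt.append(len(centers) - 1)
                if len(centers) >= n:
                    break
            if len(centers) >= n:
                break
        frontier = nxt
    centers_arr = np.array(centers[:n])
    yaws_arr = np.array(yaws[:n])
    centers_arr += np.asarray(center_xy) - centers_arr.mean(axis=0)

    bonds: list[tuple[int, int, int, int]] = []
    for i in range(n):
        for si, ang in enumerate(LEG_ANGLES + yaws_arr[i]):
            target = centers_arr[i] + a * np.array([np.cos(ang), np.sin(ang)])
            d = np.linalg.norm(centers_arr - target, axis=1)
            j = int(np.argmin(d))
            if d[j] < 1e-6 and i < j:
                # partner leg points back from j toward i
                back_ang = ang + np.pi
                delta = np.angle(np.exp(1j * (back_ang - (LEG_ANGLES + yaws_arr[j]))))
                sj = int(np.argmin(np.abs(delta)))
                if abs(delta[sj]) > 1e-6:
                    raise RuntimeError("no matching partner leg in hexagonal patch")
                bonds.append((i, si, j, sj))
    out3 = np.zeros((n, 3))
    out3[:, :2] = centers_arr
    return out3, yaws_arr, bonds


def single_cluster_initial_state(
    config: SimConfig, n_in_cluster: int, seed: Optional[int] = None
) -> SimState:
    """One fully bonded flat hexagonal patch anchored at the box center;
    remaining clathrins random in the cytosol, remaining adaptors free."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = config.box()
    geom = config.geometry
    if n_in_cluster > config.n_clathrin:
        raise ValueError("cluster size exceeds the clathrin copy number")
    if n_in_cluster < 1:
        raise ValueError("cluster needs at least one member")

    centers, yaws, bonds = _honeycomb_patch(
        n_in_cluster, geom, np.array([box.edge_nm / 2, box.edge_nm / 2])
    )
    if np.any(centers[:, :2] < 0) or np.any(centers[:, :2] > box.edge_nm):
        raise RuntimeError("hexagonal patch does not fit in the box")
    centers[:, 2] = geom.membrane_anchor_z_nm

    n = config.n_clathrin
    n_rest = n - n_in_cluster
    rest = (
        _sample_nonoverlapping(
            rng, n_rest, box.edge_nm, 2 * geom.excluded_radius_nm, fixed=centers
        )
        if n_rest
        else np.zeros((0, 3))
    )
    pos = np.vstack([centers, rest])
    quats = np.vstack(
        [
            np.array([yaw_quat(phi) for phi in yaws]).reshape(-1, 4),
            np.array([random_quat(rng) for _ in range(n_rest)]).reshape(n_rest, 4),
        ]
    )
    mem = np.zeros(n, dtype=bool)
    mem[:n_in_cluster] = True

    n_anchor = min(n_in_cluster, config.n_ap2)
    ap2 = np.zeros((config.n_ap2, 2))
    ap2[:n_anchor] = pos[:n_anchor, :2]
    if config.n_ap2 > n_anchor:
        ap2[n_anchor:] = rng.uniform(0.0, box.edge_nm, size=(config.n_ap2 - n_anchor, 2))

    state = SimState(
        box=box,
        geom=geom,
        kin=replace(config.kinetics),
        clat_pos=pos,
        clat_quat=quats,
        clat_mem=mem,
        ap2_pos=ap2,
        rng=rng,
    )
    for i, si, j, sj in bonds:
        state.leg_bond[i, si] = (j, sj)
        state.leg_bond[j, sj] = (i, si)
    for k in range(n_anchor):
        state.clat_ap2[k] = k
        state.ap2_bond[k] = k
    state.invalidate()
    state.refresh_compartments()
    state.refresh_rates()
    return state


# ---------------------------------------------------------------------------
# parameter sweeps

SWEEP_VARIABLES = ("ap2_number", "k_clat_clat_fold", "d_clat_fold")


@dataclass
class SweepSpec:
    variable: str
    values: list
    base_config: SimConfig
    replicates: int = 4
    seeds: Optional[list[int]] = None
    n_seed_cluster: Optional[int] = None  # None -> random initial state

    def __post_init__(self) -> None:
        if self.variable not in SWEEP_VARIABLES:
            raise ValueError(f"variable must be one of {SWEEP_VARIABLES}")
        if any(v <= 0 for v in self.values) and self.variable != "ap2_number":
            raise ValueError("fold values must be positive")
        if self.seeds is None:
            self.seeds = list(range(len(self.values) * self.replicates))
        if len(self.seeds) != len(self.values) * self.replicates:
            raise ValueError("len(seeds) must equal len(values) * replicates")


def _apply_sweep_value(cfg: SimConfig, variable: str, value) -> SimConfig:
    if variable == "ap2_number":
        return cfg.with_overrides(n_ap2=int(value))
    if variable == "k_clat_clat_fold":
        return cfg.with_overrides(
            **{
                "kinetics.k_clat_clat_on_uM_s": cfg.kinetics.k_clat_clat_on_uM_s * value
            }
        )
    # d_clat_fold scales translational clathrin diffusion (3D and in-plane)
    return cfg.with_overrides(
        **{
            "kinetics.d_clat_trans_um2_s": cfg.kinetics.d_clat_trans_um2_s * value,
            "kinetics.d_clat_mem_trans_um2_s": cfg.kinetics.d_clat_mem_trans_um2_s * value,
        }
    )


def run_single(cfg: SimConfig, seed: int) -> tuple[MetricsReport, Trajectory]:
    state = random_initial_state(cfg, seed)
    traj = run(state, cfg.duration_s, cfg.frame_interval_s)
    stats = frames_to_stats(traj, cfg.min_cluster_size, cfg.hull_pad_nm)
    report = summarize(stats, cfg.duration_s, cfg.min_cluster_size)
    return report, traj


def run_sweep(spec: SweepSpec) -> dict:
    """Run every (value, replicate) pair and tabulate the modal metrics.

    Returns {'table': per-run DataFrame, 'groups': per-value mean/SD
    DataFrame, 'pvalues': {(value_a, value_b): p} for adjacent values}.
    """
    rows = []
    seed_iter = iter(spec.seeds)
    for value in spec.values:
        cfg = _apply_sweep_value(spec.base_config, spec.variable, value)
        for rep in range(spec.replicates):
            seed = next(seed_iter)
            report, _ = run_single(cfg, seed)
            rows.append(
                {
                    spec.variable: value,
                    "replicate": rep,
                    "seed": seed,
                    "config_hash": config_hash(cfg),
                    "tc_s": report.tc_s,
                    "modal_cluster_number": report.modal_cluster_number,
                    "mean_mean_cluster_size_um2": report.mean_mean_cluster_size_um2,
                    "mean_dwelling_time_s": report.mean_dwelling_time_s,
                }
            )
    table = pd.DataFrame(rows)
    metrics = [
        "modal_cluster_number",
        "mean_mean_cluster_size_um2",
        "mean_dwelling_time_s",
    ]
    groups = table.groupby(spec.variable)[metrics].agg(["mean", "std"])
    pvalues = {}
    from .analysis import compare_groups

    for va, vb in itertools.combinations(spec.values, 2):
        for metric in metrics:
            a = table.loc[table[spec.variable] == va, metric].to_numpy(dtype=float)
            b = table.loc[table[spec.variable] == vb, metric].to_numpy(dtype=float)
            try:
                _, p = compare_groups(a, b)
            except ValueError:
                p = float("nan")
            pvalues[(va, vb, metric)] = p
    return {"table": table, "groups": groups, "pvalues": pvalues}


# ---------------------------------------------------------------------------
# growth-factor stimulus schedule

EGF_COMBINATIONS = ("ap2_only", "ap2_plus_k", "ap2_plus_d", "ap2_k_d")


@dataclass
class EGFSchedule:
    """Piecewise-in-time parameter changes mimicking growth-factor stimulus.

    Adaptor count rises from ``ap2_start`` to ``ap2_peak`` over
    [0, t_switch] (linear ramp by default, step optional); depending on the
    combination the clathrin-clathrin on-rate is multiplied by ``k_fold``
    and the clathrin diffusion coefficient by ``d_fold`` as steps at t = 0.
    At ``t_switch`` every parameter reverts to baseline.
    """

    ap2_start: int = 100
    ap2_peak: int = 200
    k_fold: float = 50.0
    d_fold: float = 1.0 / 50.0
    t_switch_s: float = 1800.0
    t_end_s: float = 3600.0
    combination: str = "ap2_k_d"
    ap2_ramp: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.t_switch_s < self.t_end_s:
            raise ValueError("need 0 < t_switch_s < t_end_s")
        if self.combination not in EGF_COMBINATIONS:
            raise ValueError(f"combination must be one of {EGF_COMBINATIONS}")
        if self.ap2_ramp not in ("step", "linear"):
            raise ValueError("ap2_ramp must be 'step' or 'linear'")

    def params_at(self, t_s: float) -> tuple[int, float, float]:
        """(target adaptor count, k fold, d fold) active at time t."""
        if t_s >= self.t_switch_s:
            return self.ap2_start, 1.0, 1.0
        if self.ap2_ramp == "step":
            ap2 = self.ap2_peak
        else:
            frac = t_s / self.t_switch_s
            ap2 = int(round(self.ap2_start + (self.ap2_peak - self.ap2_start) * frac))
        k_fold = self.k_fold if self.combination in ("ap2_plus_k", "ap2_k_d") else 1.0
        d_fold = self.d_fold if self.combination in ("ap2_plus_d", "ap2_k_d") else 1.0
        return ap2, k_fold, d_fold


class ScheduleController:
    """Applies an :class:`EGFSchedule` to a running state before each step."""

    def __init__(self, schedule: EGFSchedule, base_kin):
        self.schedule = schedule
        self.base_k = base_kin.k_clat_clat_on_uM_s
        self.base_d = base_kin.d_clat_trans_um2_s
        self.base_d_mem = base_kin.d_clat_mem_trans_um2_s
        self._last = (None, None, None)

    def __call__(self, state: SimState) -> None:
        ap2_target, k_fold, d_fold = self.schedule.params_at(state.time_s)
        if (k_fold, d_fold) != self._last[1:]:
            state.kin.k_clat_clat_on_uM_s = self.base_k * k_fold
            state.kin.d_clat_trans_um2_s = self.base_d * d_fold
            state.kin.d_clat_mem_trans_um2_s = self.base_d_mem * d_fold
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state.refresh_rates()
        if ap2_target != self._last[0]:
            while state.n_ap2 < ap2_target:
                xy = state.rng.uniform(0.0, state.box.edge_nm, size=2)
                state.add_ap2(xy)
            while state.n_ap2 > ap2_target:
                free = np.flatnonzero(state.ap2_bond < 0)
                if len(free):
                    idx = int(state.rng.choice(free))
                else:
                    idx = int(state.rng.integers(state.n_ap2))
                state.remove_ap2(idx)
        self._last = (ap2_target, k_fold, d_fold)


def egf_experiment(
    config: SimConfig,
    schedule: EGFSchedule,
    n_seed_cluster: int,
    replicates: int = 3,
    seeds: Optional[list[int]] = None,
) -> dict:
    """Fold-change curves of cluster number and maximum cluster size.

    Starts each replicate from a single anchored cluster; curves are
    normalised to their t = 0 values and reported as mean +/- SD.
    """
    if seeds is None:
        seeds = list(range(replicates))
    if len(seeds) != replicates:
        raise ValueError("len(seeds) must equal replicates")
    count_curves, size_curves = [], []
    times = None
    for seed in seeds:
        cfg = config.with_overrides(n_ap2=schedule.ap2_start)
        state = single_cluster_initial_state(cfg, n_seed_cluster, seed)
        controller = ScheduleController(schedule, cfg.kinetics)
        traj = run(state, schedule.t_end_s, cfg.frame_interval_s, controller=controller)
        stats = frames_to_stats(traj, cfg.min_cluster_size, cfg.hull_pad_nm)
        times = stats.times_s
        n0 = max(stats.n_clusters[0], 1)
        a0 = stats.max_area_um2[0] if stats.max_area_um2[0] > 0 else 1.0
        count_curves.append(stats.n_clusters / n0)
        size_curves.append(stats.max_area_um2 / a0)
    count_arr = np.array(count_curves)
    size_arr = np.array(size_curves)
    return {
        "times_s": times,
        "count_fold_mean": count_arr.mean(axis=0),
        "count_fold_sd": count_arr.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(times),
        "size_fold_mean": size_arr.mean(axis=0),
        "size_fold_sd": size_arr.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(times),
        "count_fold_runs": count_arr,
        "size_fold_runs": size_arr,
        "seeds": seeds,
    }


# ---------------------------------------------------------------------------
# well-mixed validation harness (A + B <-> AB point particles)

def _mass_action_equilibrium(k_on_nm3_s, k_off_s, n_a, n_b, volume_nm3) -> float:
    """Bound-pair count solving k_on/V (nA-x)(nB-x) = k_off x."""
    if k_on_nm3_s == 0:
        return 0.0
    if k_off_s == 0:
        return float(min(n_a, n_b))
    c = k_on_nm3_s / volume_nm3
    # c x^2 - (c(nA+nB) + koff) x + c nA nB = 0
    A = c
    B = -(c * (n_a + n_b) + k_off_s)
    C = c * n_a * n_b
    disc = B * B - 4 * A * C
    return float((-B - np.sqrt(disc)) / (2 * A))


def validate_well_mixed(
    k_on_uM_s: float,
    k_off_s: float,
    n_a: int,
    n_b: int,
    box_edge_um: float,
    duration_s: float,
    seed: int,
    d_um2_s: float = 20.0,
    dt_s: float = 5e-5,
    sigma_nm: float = 10.0,
    burn_in_frac: float = 0.25,
    n_blocks: int = 20,
    start_bound: bool = False,
    record_unbind_times: bool = False,
) -> dict:
    """Point-particle A + B <-> AB in a reflecting box.

    Uses the same acceptance machinery as the full engine (Doi contact
    probability calibrated from ``k_on``; dissociation ``1 - exp(-k dt)``;
    one reaction per molecule per step, reacted molecules do not diffuse).
    Returns the time-averaged bound fraction with a block standard error
    and the mass-action equilibrium prediction.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    L = box_edge_um * 1e3
    V = L**3
    k_on = units.rate_uM_to_nm3(k_on_uM_s)
    d_nm2 = units.um2_s_to_nm2_s(d_um2_s)
    lam = calibrate_lambda_3d(k_on, sigma_nm, 2 * d_nm2) if k_on else 0.0
    p_on = -np.expm1(-lam * dt_s)
    p_off = dissociation_probability(k_off_s, dt_s)
    s_free = np.sqrt(2.0 * d_nm2 * dt_s)
    d_pair = combine_diffusion(np.array([d_um2_s, d_um2_s]), 1)
    s_pair = np.sqrt(2.0 * units.um2_s_to_nm2_s(d_pair) * dt_s)

    pos_a = rng.uniform(0, L, size=(n_a, 3))
    pos_b = rng.uniform(0, L, size=(n_b, 3))
    bond_a = np.full(n_a, -1, dtype=np.int64)  # partner B index
    bond_b = np.full(n_b, -1, dtype=np.int64)
    if start_bound:
        m = min(n_a, n_b)
        bond_a[:m] = np.arange(m)
        bond_b[:m] = np.arange(m)
        pos_b[:m] = pos_a[:m]

    n_steps = int(round(duration_s / dt_s))
    bound_trace = np.empty(n_steps)
    unbind_times = [] if record_unbind_times else None

    for k in range(n_steps):
        reacted_a = np.zeros(n_a, dtype=bool)
        reacted_b = np.zeros(n_b, dtype=bool)
        # dissociation first
        bound_idx = np.flatnonzero(bond_a >= 0)
        if len(bound_idx) and p_off > 0:
            breaks = bound_idx[rng.random(len(bound_idx)) < p_off]
            for i in breaks:
                j = bond_a[i]
                bond_a[i] = -1
                bond_b[j] = -1
                reacted_a[i] = True
                reacted_b[j] = True
                # place the freed partner at contact, random direction
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos_b[j] = np.clip(pos_a[i] + sigma_nm * u, 0, L)
                if unbind_times is not None:
                    unbind_times.append((k + 1) * dt_s)
        # association
        free_a = np.flatnonzero(bond_a < 0)
        free_b = np.flatnonzero(bond_b < 0)
        if len(free_a) and len(free_b) and p_on > 0:
            tree = cKDTree(pos_b[free_b])
            hits = tree.query_ball_point(pos_a[free_a], sigma_nm)
            cands = [
                (int(free_a[ia]), int(free_b[jb]))
                for ia, found in enumerate(hits)
                for jb in found
            ]
            if cands:
                for ci in rng.permutation(len(cands)):
                    i, j = cands[ci]
                    if reacted_a[i] or reacted_b[j] or bond_a[i] >= 0 or bond_b[j] >= 0:
                        continue
                    if rng.random() < p_on:
                        bond_a[i] = j
                        bond_b[j] = i
                        pos_b[j] = pos_a[i]
                        reacted_a[i] = True
                        reacted_b[j] = True
        # diffusion of non-reacted molecules/pairs
        bound_now = np.flatnonzero(bond_a >= 0)
        move_pairs = bound_now[~reacted_a[bound_now]]
        if len(move_pairs):
            disp = rng.normal(0, s_pair, size=(len(move_pairs), 3))
            newp = pos_a[move_pairs] + disp
            newp = np.where(newp < 0, -newp, newp)
            newp = np.where(newp > L, 2 * L - newp, newp)
            pos_a[move_pairs] = newp
            pos_b[bond_a[move_pairs]] = newp
        fa = np.flatnonzero((bond_a < 0) & ~reacted_a)
        if len(fa):
            newp = pos_a[fa] + rng.normal(0, s_free, size=(len(fa), 3))
            newp = np.where(newp < 0, -newp, newp)
            pos_a[fa] = np.where(newp > L, 2 * L - newp, newp)
        fb = np.flatnonzero((bond_b < 0) & ~reacted_b)
        if len(fb):
            newp = pos_b[fb] + rng.normal(0, s_free, size=(len(fb), 3))
            newp = np.where(newp < 0, -newp, newp)
            pos_b[fb] = np.where(newp > L, 2 * L - newp, newp)
        bound_trace[k] = np.count_nonzero(bond_a >= 0)

    limiting = min(n_a, n_b)
    burn = int(burn_in_frac * n_steps)
    tail = bound_trace[burn:] / limiting
    blocks = np.array_split(tail, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    se = float(block_means.std(ddof=1) / np.sqrt(len(blocks)))
    x_eq = _mass_action_equilibrium(k_on, k_off_s, n_a, n_b, V)
    out = {
        "bound_fraction_mean": float(tail.mean()),
        "bound_fraction_se": se,
        "bound_fraction_trace": bound_trace / limiting,
        "equilibrium_prediction": x_eq / limiting,
        "p_on_per_step": float(p_on),
        "lambda_s": float(lam),
    }
    if unbind_times is not None:
        out["unbind_times_s"] = np.array(unbind_times)
    return out


def dissociation_waiting_times(
    k_off_s: float, dt_s: float, n_bonds: int, seed: int, max_steps: int = 10**7
) -> np.ndarray:
    """Waiting times of independent bonds under the per-step break rule.

    Pure dissociation (no rebinding); uses the same per-step probability
    as the engine, so the samples are geometric with success probability
    ``1 - exp(-k dt)`` on the step grid.
    """
    rng = np.random.default_rng(seed)
    p = dissociation_probability(k_off_s, dt_s)
    if p <= 0:
        raise ValueError("k_off and dt must give a positive break probability")
    steps = rng.geometric(p, size=n_bonds)
    if np.any(steps > max_steps):
        raise RuntimeError("waiting time exceeded max_steps")
    return steps * dt_s
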