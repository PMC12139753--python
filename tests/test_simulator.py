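import numpy as np
import pytest
from scipy import stats as sps

from fclsim.model_core import (
    BoxGeometry,
    KineticParams,
    SiteGeometryParams,
    bound_partner_pose,
    yaw_quat,
)
from fclsim.simulator import (
    SimState,
    calibrate_lambda_3d,
    cluster_diffusion,
    combine_diffusion,
    dissociation_probability,
    dissociation_sweep,
    doi_rate_3d,
    run,
    step,
)
from helpers import make_dimer_state as _dimer_state, make_state


class TestDissociationProbability:
    def test_zero_rate(self):
        assert dissociation_probability(0.0, 3e-6) == 0.0

    def test_limit_to_one(self):
        assert dissociation_probability(1e12, 1.0) == pytest.approx(1.0)

    def test_closed_form(self):
        p = dissociation_probability(1.0, 3e-6)
        assert p == pytest.approx(1.0 - np.exp(-3e-6), rel=1e-12)
        assert p == pytest.approx(2.999996e-6, rel=1e-5)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            dissociation_probability(-1.0, 1e-6)
        with pytest.raises(ValueError):
            dissociation_probability(1.0, 0.0)


class TestClusterDiffusion:
    def test_single_component_identity(self):
        dt, dr = cluster_diffusion([(13.0, 0.03)])
        assert dt == pytest.approx(13.0)
        assert dr == pytest.approx(0.03)

    def test_13_identical_translational(self):
        dt, _ = cluster_diffusion([(13.0, 1.0)] * 13)
        assert dt == pytest.approx(1.0, rel=1e-12)

    def test_8_identical_rotational(self):
        d = 0.5
        _, dr = cluster_diffusion([(1.0, d)] * 8)
        assert dr == pytest.approx(d / 512.0, rel=1e-12)

    def test_random_inputs_match_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = rng.uniform(0.01, 20.0, size=rng.integers(1, 12))
            for n in (1, 3):
                expect = np.sum(d ** (-1.0 / n)) ** (-float(n))
                assert combine_diffusion(d, n) == pytest.approx(expect, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cluster_diffusion([])


class TestDoiCalibration:
    def test_round_trip(self):
        sigma, d = 10.0, 2e7
        for k_on in (1e7, 1e8, 5e8):
            lam = calibrate_lambda_3d(k_on, sigma, d)
            assert doi_rate_3d(lam, sigma, d) == pytest.approx(k_on, rel=1e-6)
        # below the shortcut threshold the reaction-limited bias is < 0.1%
        lam = calibrate_lambda_3d(1e5, sigma, d)
        assert doi_rate_3d(lam, sigma, d) == pytest.approx(1e5, rel=1e-3)

    def test_reaction_limited_regime(self):
        sigma, d = 10.0, 2e7
        k_on = 1e4  # far below the diffusion limit
        lam = calibrate_lambda_3d(k_on, sigma, d)
        v_sigma = 4.0 / 3.0 * np.pi * sigma**3
        assert lam == pytest.approx(k_on / v_sigma, rel=1e-3)

    def test_beyond_diffusion_limit_errors(self):
        with pytest.raises(ValueError):
            calibrate_lambda_3d(1e12, 10.0, 2e7)


class TestDissociationSweep:
    def test_zero_bonds_unchanged(self):
        state = make_state(np.array([[100.0, 100.0, 100.0]]))
        before = state.clat_pos.copy()
        reacted_c, _ = dissociation_sweep(state)
        assert not reacted_c.any()
        np.testing.assert_array_equal(state.clat_pos, before)

    def test_huge_rate_breaks_bond_and_marks_reacted(self):
        kin = KineticParams(k_clat_clat_off_s=1e9, k_clat_ap2_off_s=0.0, dt_s=1.0)
        state = _dimer_state(1, kin)
        reacted_c, _ = dissociation_sweep(state)
        assert state.leg_bond[0, 0, 0] == -1
        assert state.leg_bond[1, 0, 0] == -1
        assert reacted_c[0] and reacted_c[1]

    def test_break_frequency_matches_closed_form(self):
        # 500 independent bonds x 200 sweeps; bonds re-armed between sweeps
        k_off, dt = 10.0, 3e-6
        # raise dt so the expected count is testable at this trial budget
        k_off, dt = 100.0, 1e-4
        kin = KineticParams(
            k_clat_clat_off_s=k_off, k_clat_ap2_off_s=0.0, k_clat_clat_on_uM_s=0.0,
            k_clat_ap2_on_uM_s=0.0, dt_s=dt,
        )
        state = _dimer_state(500, kin)
        saved = state.leg_bond.copy()
        p = dissociation_probability(k_off, dt)
        n_sweeps, breaks = 200, 0
        for _ in range(n_sweeps):
            dissociation_sweep(state)
            n_bonds_after = np.count_nonzero(state.leg_bond[:, 0, 0] >= 0) // 2
            breaks += 500 - n_bonds_after
            state.leg_bond = saved.copy()
            state.invalidate()
        trials = 500 * n_sweeps
        expected = trials * p
        se = np.sqrt(trials * p * (1 - p))
        assert abs(breaks - expected) < 3 * se

    def test_waiting_times_exponential_ks(self):
        from fclsim.protocols import dissociation_waiting_times

        k_off, dt = 10.0, 1e-4
        t = dissociation_waiting_times(k_off, dt, 20000, seed=5)
        # KS against the exponential law at alpha = 0.01
        res = sps.kstest(t, "expon", args=(0, 1.0 / k_off))
        assert res.pvalue > 0.01


class TestDiffuseSweep:
    def test_zero_diffusion_static(self, quiet_kin):
        kin = KineticParams(
            **{
                **quiet_kin.__dict__,
                "d_clat_trans_um2_s": 0.0,
                "d_clat_rot_s": 0.0,
                "d_ap2_trans_um2_s": 0.0,
            }
        )
        state = make_state(
            np.array([[500.0, 500.0, 500.0]]), kin=kin, ap2_pos=np.array([[100.0, 100.0]])
        )
        p0, a0 = state.clat_pos.copy(), state.ap2_pos.copy()
        for _ in range(10):
            step(state)
        np.testing.assert_array_equal(state.clat_pos, p0)
        np.testing.assert_array_equal(state.ap2_pos, a0)

    def test_monomer_msd_matches_2Ddt(self, quiet_kin):
        d_um2_s = 13.0
        kin = KineticParams(
            **{**quiet_kin.__dict__, "d_clat_trans_um2_s": d_um2_s, "dt_s": 3e-6}
        )
        box = BoxGeometry(edge_nm=40000.0)
        state = make_state(np.array([[20000.0, 20000.0, 20000.0]]), box=box, kin=kin)
        n = 4000
        traj = run(state, n * kin.dt_s, kin.dt_s)
        pos = np.array([f.clat_pos[0] for f in traj.frames])
        disp = np.diff(pos, axis=0)
        msd_axis = np.mean(disp**2, axis=0)
        expect = 2.0 * d_um2_s * 1e6 * kin.dt_s
        se = expect * np.sqrt(2.0 / len(disp))
        for ax in range(3):
            assert abs(msd_axis[ax] - expect) < 3 * se

    def test_membrane_dimer_msd_uses_cluster_d(self, quiet_kin):
        kin = KineticParams(
            **{
                **quiet_kin.__dict__,
                "d_clat_mem_trans_um2_s": 0.5,
                "d_ap2_trans_um2_s": 0.5,
                "d_clat_mem_rot_s": 0.0,
                "dt_s": 3e-6,
            }
        )
        state = _dimer_state(1, kin, box_nm=40000.0, spacing=20000.0)
        d_unit = combine_diffusion(np.array([0.5, 0.5, 0.5, 0.5]), 1)
        n = 4000
        traj = run(state, n * kin.dt_s, kin.dt_s)
        cent = np.array([f.clat_pos.mean(axis=0) for f in traj.frames])
        disp = np.diff(cent, axis=0)
        msd_axis = np.mean(disp**2, axis=0)
        expect = 2.0 * d_unit * 1e6 * kin.dt_s
        se = expect * np.sqrt(2.0 / len(disp))
        for ax in range(2):
            assert abs(msd_axis[ax] - expect) < 3 * se
        assert msd_axis[2] == 0.0  # membrane units never move vertically

    def test_membrane_species_stay_at_plane(self, desk_config):
        from fclsim.protocols import random_initial_state

        state = random_initial_state(desk_config, seed=3)
        for _ in range(200):
            step(state)
        # adaptors live in 2D by construction; membrane clathrins at anchor height
        mem = state.clat_mem
        if mem.any():
            np.testing.assert_allclose(
                state.clat_pos[mem, 2],
                desk_config.geometry.membrane_anchor_z_nm,
                atol=1e-9,
            )


class TestStepAndRun:
    def test_empty_system_time_advances(self):
        state = make_state(np.zeros((0, 3)))
        t0 = state.time_s
        step(state)
        assert state.time_s == pytest.approx(t0 + state.kin.dt_s)

    def test_pure_diffusion_keeps_bonds(self, quiet_kin):
        state = _dimer_state(3, quiet_kin)
        bonds0 = state.leg_bond.copy()
        for _ in range(50):
            step(state)
        np.testing.assert_array_equal(state.leg_bond, bonds0)

    def test_determinism_same_seed(self, desk_config):
        from fclsim.protocols import random_initial_state

        t1 = run(random_initial_state(desk_config, seed=7), 0.05, 0.01)
        t2 = run(random_initial_state(desk_config, seed=7), 0.05, 0.01)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.clat_pos, f2.clat_pos)
            np.testing.assert_array_equal(f1.clat_quat, f2.clat_quat)
            np.testing.assert_array_equal(f1.leg_bond, f2.leg_bond)
            np.testing.assert_array_equal(f1.ap2_pos, f2.ap2_pos)

    def test_run_frame_counts(self):
        state = make_state(np.array([[500.0, 500.0, 500.0]]))
        traj = run(state, state.kin.dt_s, state.kin.dt_s)
        assert len(traj.frames) == 2  # t = 0 and one step
        state = make_state(np.array([[500.0, 500.0, 500.0]]))
        traj = run(state, 10 * state.kin.dt_s, 10 * state.kin.dt_s)
        assert len(traj.frames) == 2  # t = 0 and t = end

    def test_molecule_conservation(self, desk_config):
        from fclsim.protocols import random_initial_state

        state = random_initial_state(desk_config, seed=11)
        n_c, n_a = state.n_clathrin, state.n_ap2
        traj = run(state, 0.05, 0.01)
        for f in traj.frames:
            assert len(f.clat_pos) == n_c
            assert len(f.ap2_pos) == n_a

    def test_invariants_along_a_run(self, desk_config):
        """Bond geometry 5 nm, overlap freedom and containment per frame."""
        from fclsim.model_core import site_positions_many
        from fclsim.protocols import random_initial_state
        from fclsim.simulator import SimState

        state = random_initial_state(desk_config, seed=13)
        geom = desk_config.geometry
        L = state.box.edge_nm
        traj = run(state, 0.6, 0.03)
        for f in traj.frames:
            sites = site_positions_many(f.clat_pos, f.clat_quat, geom)
            for i in range(len(f.clat_pos)):
                for s in range(3):
                    j, sj = f.leg_bond[i, s]
                    if j >= 0 and (i, s) < (int(j), int(sj)):
                        d = np.linalg.norm(sites[i, s] - sites[j, sj])
                        assert d == pytest.approx(geom.bond_length_nm, abs=1e-6)
            # hard core: non-bonded pairs at >= 2 * excluded radius
            from scipy.spatial import distance_matrix

            if len(f.clat_pos) > 1:
                dm = distance_matrix(f.clat_pos, f.clat_pos)
                np.fill_diagonal(dm, np.inf)
                assert dm.min() >= 2 * geom.excluded_radius_nm - 1e-9
            assert np.all(f.clat_pos >= -1e-9) and np.all(f.clat_pos <= L + 1e-9)


class TestAssociationBasics:
    def test_no_candidates_no_change(self, quiet_kin):
        state = make_state(
            np.array([[100.0, 100.0, 500.0], [900.0, 900.0, 500.0]]), kin=quiet_kin
        )
        bonds0 = state.leg_bond.copy()
        step(state)
        np.testing.assert_array_equal(state.leg_bond, bonds0)

    def test_zero_on_rate_never_binds(self):
        kin = KineticParams(
            k_clat_clat_on_uM_s=0.0, k_clat_ap2_on_uM_s=0.0, dt_s=1e-4
        )
        state = make_state(
            np.array([[500.0, 500.0, 16.0]]),
            kin=kin,
            ap2_pos=np.array([[500.0, 500.0]]),
        )
        for _ in range(200):
            step(state)
        assert state.clat_ap2[0] == -1

    def test_recruitment_binds_and_anchors(self):
        kin = KineticParams(
            k_clat_clat_on_uM_s=0.0,
            k_clat_ap2_on_uM_s=50.0,
            k_clat_ap2_off_s=0.0,
            k_clat_clat_off_s=0.0,
            d_clat_trans_um2_s=1.0,
            dt_s=1e-4,
        )
        geom = SiteGeometryParams()
        state = make_state(
            np.array([[500.0, 500.0, geom.membrane_anchor_z_nm + 2.0]]),
            kin=kin,
            clat_quat=np.array([yaw_quat(0.0)]),
            ap2_pos=np.array([[500.0, 500.0]]),
        )
        bound = False
        for _ in range(500):
            step(state)
            if state.clat_ap2[0] >= 0:
                bound = True
                break
        assert bound
        assert state.clat_mem[0]
        assert state.clat_pos[0, 2] == pytest.approx(geom.membrane_anchor_z_nm)
        np.testing.assert_allclose(state.ap2_pos[0], state.clat_pos[0, :2], atol=1e-9)
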