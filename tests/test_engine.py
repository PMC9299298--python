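"""Per-step update loop: mobility partition, free-diffusion law,
obstruction/confinement, binding dynamics and determinism."""

import math

import numpy as np
import pytest

from cadclust import (CadherinMonomer, KineticParams, PeriodicDomain,
                      RunSchedule, SystemState, advance, init_state, run, step)
from cadclust.engine import diffusion_move, mobile_units, rotation_move
from cadclust.fixtures import square_box_with_gap, three_monomer_state, triangle_corral


def M(i, plane, x, y, theta_deg=0.0, **kw):
    return CadherinMonomer(id=i, plane=plane, center=np.array([x, y], dtype=float),
                           theta=math.radians(theta_deg), **kw)


class TestMobileUnits:
    def test_partition_covers_all_without_overlap(self, dom, params):
        st = three_monomer_state(dom, params)
        units, immobile = mobile_units(st)
        ids = sorted([i for u in units for i in u.member_ids] + immobile)
        assert ids == list(range(st.n_monomers))

    def test_cis_bond_immobilises_whole_trans_dimer(self, dom, params):
        st = three_monomer_state(dom, params)  # 0-1 trans, 0-2 cis
        units, immobile = mobile_units(st)
        assert sorted(immobile) == [0, 1, 2]
        assert units == []

    def test_free_dimer_is_one_unit(self, dom, params):
        ms = [M(0, 0, 1, 1, 0, trans_partner=1), M(1, 1, 1, 1, 90, trans_partner=0)]
        st = SystemState.from_monomers(ms, dom, params)
        units, immobile = mobile_units(st)
        assert len(units) == 1 and units[0].kind == "trans_dimer"
        assert immobile == []


class TestDiffusionMove:
    def test_zero_diffusivity_keeps_position(self, dom):
        p = KineticParams(D=0.0)
        st = SystemState.from_monomers([M(0, 0, 5, 5)], dom, p)
        units, _ = mobile_units(st)
        diffusion_move(units[0], st, np.random.default_rng(0))
        assert st.pos[0] == pytest.approx((5.0, 5.0))

    def test_step_length_is_sqrt_4_D_dt(self, dom, inert_params):
        st = SystemState.from_monomers([M(0, 0, 500, 500)], dom, inert_params)
        units, _ = mobile_units(st)
        assert diffusion_move(units[0], st, np.random.default_rng(0))
        assert np.linalg.norm(st.unwrapped[0]) == pytest.approx(2.0)

    def test_dimer_moves_rigidly(self, dom, inert_params):
        ms = [M(0, 0, 5, 5, 0, trans_partner=1), M(1, 1, 5, 5, 90, trans_partner=0)]
        st = SystemState.from_monomers(ms, dom, inert_params)
        units, _ = mobile_units(st)
        diffusion_move(units[0], st, np.random.default_rng(0))
        assert np.array_equal(st.pos[0], st.pos[1])

    def test_rejected_against_enclosing_triangle(self):
        st = triangle_corral(radius=1.8)  # every direction blocked within 2 nm
        units, _ = mobile_units(st)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert diffusion_move(units[0], st, rng) is False
        assert st.pos[0] == pytest.approx((500.0, 500.0))


class TestRotationMove:
    def test_rotation_magnitude(self, dom, inert_params):
        st = SystemState.from_monomers([M(0, 0, 5, 5, 0)], dom, inert_params)
        units, _ = mobile_units(st)
        rotation_move(units[0], st, np.random.default_rng(1))
        assert abs(math.degrees(st.theta[0] if st.theta[0] < math.pi
                                else st.theta[0] - 2 * math.pi)) == pytest.approx(10.0)

    def test_dimer_preserves_packing_offset(self, dom, inert_params):
        ms = [M(0, 0, 5, 5, 0, trans_partner=1), M(1, 1, 5, 5, 90, trans_partner=0)]
        st = SystemState.from_monomers(ms, dom, inert_params)
        units, _ = mobile_units(st)
        rotation_move(units[0], st, np.random.default_rng(1))
        diff = (st.theta[1] - st.theta[0]) % (2 * math.pi)
        assert math.degrees(diff) == pytest.approx(90.0)

    def test_cis_bonded_monomer_does_not_rotate(self, dom, params):
        st = three_monomer_state(dom, params)
        theta_before = st.theta.copy()
        for u in mobile_units(st)[0]:
            rotation_move(u, st, np.random.default_rng(1))
        assert np.array_equal(st.theta, theta_before)


class TestStepKernel:
    def test_inert_state_invariant_except_time(self, dom):
        p = KineticParams(D=0.0, D_rot=0.0, kass_trans=0.0, kass_cis=0.0,
                          kass_cad_actin=0.0, kdis_trans=0.0, kdis_cis=0.0,
                          kdis_cad_actin=0.0)
        st = init_state(dom, p.replace(cad_density=50.0), 3)
        pos = st.pos.copy()
        theta = st.theta.copy()
        step(st, seed=9)
        assert np.array_equal(st.pos, pos)
        assert np.array_equal(st.theta, theta)
        assert st.time == pytest.approx(p.dt)

    def test_certain_association_bonds_eligible_pair_in_one_step(self, dom):
        # p_ass -> 1 and the pair is coaxial afterwards
        p = KineticParams(D=0.0, D_rot=0.0, kass_trans=1e12, kdis_trans=0.0,
                          kass_cis=0.0, kdis_cis=0.0, kass_cad_actin=0.0,
                          kdis_cad_actin=0.0)
        ms = [M(0, 0, 500.0, 500.0, 0), M(1, 1, 501.0, 500.0, 85)]
        st = SystemState.from_monomers(ms, dom, p)
        step(st, seed=4)
        assert st.trans[0] == 1 and st.trans[1] == 0
        assert np.allclose(st.pos[0], st.pos[1], atol=1e-9)
        st.audit(check_geometry=True)

    def test_certain_cis_association_packs_chain(self, dom):
        p = KineticParams(D=0.0, D_rot=0.0, kass_cis=1e12, kdis_cis=0.0,
                          kass_trans=0.0, kdis_trans=0.0, kass_cad_actin=0.0,
                          kdis_cad_actin=0.0)
        ms = [M(0, 0, 500.0, 500.0, 0), M(1, 0, 506.0, 500.0, 10)]
        st = SystemState.from_monomers(ms, dom, p)
        step(st, seed=4)
        assert st.cis_donor[0] == 1 and st.cis_acceptor[1] == 0
        gap = np.linalg.norm(st.pos[1] - st.pos[0])
        assert gap == pytest.approx(2 * p.r_cad, abs=1e-9)
        assert st.theta[1] == pytest.approx(st.theta[0])

    def test_fixed_seed_reproduces_trajectory(self, dom):
        p = KineticParams(cad_density=100.0, actin_conc=60.0)
        a = init_state(dom, p, 11)
        b = init_state(dom, p, 11)
        advance(a, 200, seed=5)
        advance(b, 200, seed=5)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.trans, b.trans)
        assert np.array_equal(a.fil_anchor, b.fil_anchor)

    def test_bond_bookkeeping_balances(self, dom):
        p = KineticParams(cad_density=200.0, actin_conc=60.0)
        st = init_state(dom, p, 2)
        counts = advance(st, 2000, seed=6)
        assert counts[0] - counts[1] == st.n_trans_bonds()
        assert counts[2] - counts[3] == st.n_cis_bonds()
        assert counts[4] - counts[5] == st.n_actin_bonds()
        st.audit()

    def test_structural_invariants_hold_during_clustering(self, dom):
        p = KineticParams(cad_density=300.0, actin_conc=60.0, actin_lifetime=0.005)
        st = init_state(dom, p, 8)
        for k in range(5):
            advance(st, 400, seed=100 + k)
            st.audit()

    def test_isolated_pair_mean_bond_lifetime(self, dom):
        # permanent-contact pair: rebinding is immediate, so bonded time /
        # break events estimates the mean bond duration ~ 1/k_dis
        k_dis = 1e3
        p = KineticParams(D=0.0, D_rot=0.0, kass_trans=1e12, kdis_trans=k_dis,
                          kass_cis=0.0, kdis_cis=0.0, kass_cad_actin=0.0,
                          kdis_cad_actin=0.0)
        ms = [M(0, 0, 500.0, 500.0, 0), M(1, 1, 500.0, 500.0, 90)]
        st = SystemState.from_monomers(ms, dom, p)
        counts = advance(st, 1_200_000, seed=13)
        n_breaks = counts[1]
        assert n_breaks > 10_000
        mean_lifetime = counts[6] * p.dt / n_breaks
        assert mean_lifetime == pytest.approx(1.0 / k_dis, rel=0.05)


class TestCisEquilibrium:
    def test_bound_fraction_matches_two_state_oracle(self, dom):
        """An isolated, permanently eligible donor-acceptor pair with only
        cis kinetics reaches the occupancy of an independent two-state
        Markov oracle driven by the same per-step probabilities."""
        kass, kdis = 5e3, 2e3
        p = KineticParams(D=0.0, D_rot=0.0, kass_cis=kass, kdis_cis=kdis,
                          kass_trans=0.0, kdis_trans=0.0, kass_cad_actin=0.0,
                          kdis_cad_actin=0.0)
        ms = [M(0, 0, 500.0, 500.0, 0), M(1, 0, 505.0, 500.0, 0)]
        st = SystemState.from_monomers(ms, dom, p)
        n_samples, stride = 4000, 10
        bound = 0
        events = 1
        prev = False
        for k in range(n_samples):
            advance(st, stride, seed=10_000 + k)
            b = st.cis_donor[0] >= 0
            bound += b
            events += b != prev
            prev = b
        frac_engine = bound / n_samples

        from cadclust.kinetics import association_probability, dissociation_probability
        p_on = association_probability(kass, p.dt)
        p_off = dissociation_probability(kdis, p.dt)
        rng = np.random.default_rng(77)
        state = False
        o_bound = 0
        o_events = 1
        for k in range(n_samples * stride):
            if state:
                if rng.uniform() < p_off:
                    state = False
                    o_events += 1
            elif rng.uniform() < p_on:
                state = True
                o_events += 1
            if (k + 1) % stride == 0:
                o_bound += state
        frac_oracle = o_bound / n_samples
        # SE from the effective number of independent occupancy spells
        se = math.sqrt(frac_oracle * (1 - frac_oracle)) * (
            1 / math.sqrt(events) + 1 / math.sqrt(o_events)
        )
        assert abs(frac_engine - frac_oracle) < 3 * se


class TestFreeDiffusionLaw:
    def test_msd_matches_4_D_t(self, dom, inert_params):
        # 10^3 monomers x 10^3 steps of the fixed-step walk
        p = inert_params.replace(cad_density=500.0, D_rot=0.0)
        st = init_state(dom, p, 21)
        n_steps = 1000
        traj = np.empty((n_steps // 10, st.n_monomers, 2))
        advance(st, n_steps, seed=3, traj_every=10, traj_out=traj)
        # traj rows hold cumulative displacement; ensemble MSD from the origin
        for row, n in [(9, 100), (49, 500), (99, 1000)]:
            sq = (traj[row] ** 2).sum(axis=1)
            expected = 4 * p.D * n * p.dt  # = n * step^2
            se = sq.std(ddof=1) / math.sqrt(sq.size)
            assert abs(sq.mean() - expected) < 3 * se


class TestConfinement:
    def test_never_escapes_closed_triangle(self):
        st = triangle_corral(radius=60.0)
        advance(st, 100_000, seed=17)
        d = np.linalg.norm(st.unwrapped[0])
        assert d < 60.0  # still within the corral's circumradius

    def test_escapes_with_obstruction_disabled(self):
        st = triangle_corral(radius=60.0)
        advance(st, 100_000, seed=17, obstruction=False)
        assert np.linalg.norm(st.unwrapped[0]) > 60.0

    def test_escape_time_grows_as_mesh_shrinks(self):
        # square boxes with one gap: smaller box -> more wall encounters per
        # unit area explored, but a longer search for the same-size gap
        def mean_escape_steps(side, n_walkers=12, cap=120_000):
            times = []
            for w in range(n_walkers):
                st = square_box_with_gap(side=side, gap=10.0)
                escaped = cap
                for block in range(cap // 4000):
                    advance(st, 4000, seed=1000 + 31 * w + block)
                    if np.linalg.norm(st.unwrapped[0]) > side:  # left the box
                        escaped = (block + 1) * 4000
                        break
                times.append(escaped)
            return np.mean(times)

        small = mean_escape_steps(60.0)
        large = mean_escape_steps(150.0)
        assert small < large


class TestRun:
    def test_zero_duration_gives_initial_snapshot_only(self, dom):
        p = KineticParams(cad_density=20.0)
        res = run(dom, p, RunSchedule(0.0, 1.0, 0.5, seed=2))
        assert len(res.snapshots) == 1
        assert res.traj.shape[0] == 1

    def test_snapshot_count_scales_with_interval(self, dom):
        p = KineticParams(cad_density=20.0)
        res1 = run(dom, p, RunSchedule(0.02, 0.01, 0.001, seed=2))
        res2 = run(dom, p, RunSchedule(0.02, 0.005, 0.001, seed=2))
        assert len(res2.snapshots) - 1 == 2 * (len(res1.snapshots) - 1)

    def test_trajectory_rows_are_absolute_unwrapped_positions(self, dom):
        p = KineticParams(cad_density=20.0, kass_cis=0.0, kass_trans=0.0,
                          kass_cad_actin=0.0)
        res = run(dom, p, RunSchedule(0.01, 0.01, 0.001, seed=2))
        # cumulative displacement from row 0 equals the state's unwrapped sum
        d = res.traj[-1] - res.traj[0]
        assert np.allclose(d, res.final_state.unwrapped)

    def test_same_seed_same_outputs(self, dom):
        p = KineticParams(cad_density=50.0)
        r1 = run(dom, p, RunSchedule(0.02, 0.01, 0.001, seed=5))
        r2 = run(dom, p, RunSchedule(0.02, 0.01, 0.001, seed=5))
        assert np.array_equal(r1.traj, r2.traj)
        assert r1.events == r2.events
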