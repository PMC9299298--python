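"""Measurement suite: cluster detection and statistics, the 2D cis
dissociation constant, MSD estimation and cluster lifetime tracking."""

import math

import numpy as np
import pytest

from cadclust import (CadherinMonomer, KineticParams, PeriodicDomain,
                      SystemState, estimate_kd_cis, find_clusters, fraction_cis,
                      fraction_trans, max_cluster_size, mean_cluster_size, msd,
                      msd_loglog_slope, nnd, size_cv, track_lifetimes)
from cadclust.analysis import ClusterSnapshot, mean_lifetime
from conftest import union_find_partition


def _state_with_bonds(n, dom, params, trans_pairs=(), cis_pairs=(), planes=None):
    st = SystemState.empty(dom, params, n)
    rng = np.random.default_rng(0)
    st.pos[:] = rng.uniform(0, dom.width, (n, 2))
    if planes is None:
        st.plane[n // 2:] = 1
    else:
        st.plane[:] = planes
    for a, b in trans_pairs:
        st.trans[a] = b
        st.trans[b] = a
    for a, b in cis_pairs:
        st.cis_donor[a] = b
        st.cis_acceptor[b] = a
    return st


class TestFindClusters:
    def test_no_bonds_gives_singletons(self, dom, params):
        st = _state_with_bonds(10, dom, params)
        snap = find_clusters(st)
        assert sorted(snap.sizes) == [1] * 10

    def test_cis_chain_is_one_cluster(self, dom, params):
        st = _state_with_bonds(5, dom, params, cis_pairs=[(0, 1), (1, 2)],
                               planes=np.zeros(5, dtype=np.int64))
        snap = find_clusters(st)
        assert sorted(snap.sizes) == [1, 1, 3]

    def test_trans_bond_links_planes(self, dom, params):
        st = _state_with_bonds(4, dom, params, trans_pairs=[(0, 2)])
        snap = find_clusters(st)
        assert sorted(snap.sizes) == [1, 1, 2]

    def test_matches_union_find_oracle_on_random_bond_graphs(self, dom, params):
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = 200
            st = SystemState.empty(dom, params, n)
            st.pos[:] = rng.uniform(0, dom.width, (n, 2))
            st.plane[n // 2:] = 1
            edges = []
            # random trans pairing across planes
            lower = rng.permutation(np.arange(n // 2))
            upper = rng.permutation(np.arange(n // 2, n))
            for a, b in zip(lower[: n // 4], upper[: n // 4]):
                st.trans[a] = b
                st.trans[b] = a
                edges.append((int(a), int(b)))
            # random cis chains within each plane
            for plane_ids in (lower, upper):
                perm = rng.permutation(plane_ids)
                for a, b in zip(perm[:-1:3], perm[1::3]):
                    if st.cis_donor[a] < 0 and st.cis_acceptor[b] < 0 and a != b:
                        st.cis_donor[a] = b
                        st.cis_acceptor[b] = a
                        edges.append((int(a), int(b)))
            ours = sorted([list(c) for c in find_clusters(st).clusters])
            assert ours == union_find_partition(n, edges)


class TestClusterStats:
    def test_max_and_mean_sizes(self, dom, params):
        st = _state_with_bonds(
            15, dom, params,
            cis_pairs=[(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6),  # size 7
                       (8, 9), (9, 10),  # size 3
                       (11, 12), (12, 13), (13, 14)],  # size 5... wait size 4
            planes=np.zeros(15, dtype=np.int64),
        )
        snap = find_clusters(st)
        assert max_cluster_size(snap) == 7
        # qualifying clusters (>= 5 members): the size-7 chain only
        assert mean_cluster_size(snap, min_size=5) == pytest.approx(7.0)

    def test_mean_absent_when_no_qualifying_cluster(self, dom, params):
        st = _state_with_bonds(4, dom, params)
        assert math.isnan(mean_cluster_size(find_clusters(st)))

    def test_empty_state_max_is_zero(self, dom, params):
        st = SystemState.empty(dom, params, 0)
        assert max_cluster_size(find_clusters(st)) == 0

    def test_fractions(self, dom, params):
        st = _state_with_bonds(4, dom, params, trans_pairs=[(0, 2)])
        assert fraction_trans(st) == pytest.approx(0.5)
        assert fraction_cis(st) == 0.0
        st2 = _state_with_bonds(4, dom, params, cis_pairs=[(0, 1)],
                                planes=np.zeros(4, dtype=np.int64))
        assert fraction_cis(st2) == pytest.approx(0.5)

    def test_fraction_trans_equals_twice_bond_count_over_n(self, dom, params):
        st = _state_with_bonds(10, dom, params, trans_pairs=[(0, 5), (1, 6)])
        assert fraction_trans(st) == pytest.approx(2 * 2 / 10)


class TestKdEstimator:
    def test_absent_without_cis_bonds(self, dom, params):
        st = _state_with_bonds(10, dom, params)
        assert math.isnan(estimate_kd_cis([st]))

    def test_every_donor_bound_gives_zero(self, dom, params):
        n = 6
        st = _state_with_bonds(n, dom, params,
                               cis_pairs=[(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)],
                               planes=np.zeros(n, dtype=np.int64))
        assert estimate_kd_cis([st]) == 0.0

    @pytest.mark.parametrize("p_on, p_off", [(1e-4, 1e-2), (3e-4, 1e-2), (1e-4, 3e-2)])
    def test_recovers_zero_dimensional_oracle_constant(self, dom, params, p_on, p_off):
        # well-mixed oracle: every free donor-acceptor pair binds with p_on,
        # every bond breaks with p_off; detailed balance gives
        # nd*na/nb -> p_off/p_on (counts), i.e. KD = (p_off/p_on)/area
        rng = np.random.default_rng(42)
        n = 120
        bonds = set()
        samples = []
        free_d = list(range(n))
        free_a = list(range(n))
        for t in range(4000):
            # break
            for bond in list(bonds):
                if rng.uniform() < p_off:
                    bonds.discard(bond)
                    free_d.append(bond[0])
                    free_a.append(bond[1])
            # form (binomial over free pairs, random matching)
            k = rng.binomial(len(free_d) * len(free_a), p_on)
            for _ in range(k):
                if not free_d or not free_a:
                    break
                d = free_d.pop(rng.integers(len(free_d)))
                a = free_a.pop(rng.integers(len(free_a)))
                if d == a:  # a monomer cannot cis-bind itself
                    free_d.append(d)
                    free_a.append(a)
                    continue
                bonds.add((d, a))
            if t >= 2000 and t % 50 == 0:
                samples.append((len(free_d), len(free_a), len(bonds)))
        # rebuild each sampled occupancy as a state and run the estimator
        states = []
        area = dom.area_um2
        vals = []
        for nd, na, nb in samples:
            st = SystemState.empty(dom, params, n)
            st.plane[:] = 0
            for k in range(nb):  # ring wiring: donor k -> acceptor k+1
                st.cis_donor[k] = (k + 1) % n
                st.cis_acceptor[(k + 1) % n] = k
            states.append(st)
            if nb:
                vals.append((nd / area) * (na / area) / (nb / area))
        est = estimate_kd_cis(states)
        expected = (p_off / p_on) / area
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        assert est == pytest.approx(float(np.mean(vals)))
        assert abs(est - expected) < 3 * se + 0.05 * expected


class TestMsd:
    def test_stationary_particles_have_zero_msd(self):
        traj = np.zeros((50, 8, 2))
        times = np.arange(50) * 0.01
        curve = msd(traj, times)
        assert np.allclose(curve.msd[np.isfinite(curve.msd)], 0.0)

    def test_recovers_diffusivity_of_synthetic_walk(self):
        # fixed-step random walk: MSD = 4 D t exactly in expectation
        rng = np.random.default_rng(8)
        n, steps, L = 1000, 1000, 2.0
        ang = rng.uniform(0, 2 * math.pi, (steps, n))
        traj = np.zeros((steps + 1, n, 2))
        traj[1:] = np.cumsum(
            np.stack([L * np.cos(ang), L * np.sin(ang)], axis=-1), axis=0
        )
        dt = 1e-5
        times = np.arange(steps + 1) * dt
        curve = msd(traj, times)
        D = 1e5  # L^2/(4 dt)
        sel = np.isfinite(curve.msd)
        fitted = np.polyfit(np.log(curve.lags[sel]), np.log(curve.msd[sel]), 1)
        assert fitted[0] == pytest.approx(1.0, abs=0.05)
        # diffusivity from the short-lag decade: MSD(t) = 4 D t
        short = sel & (curve.lags <= 10 * curve.lags[0])
        D_est = float(np.mean(curve.msd[short] / (4 * curve.lags[short])))
        assert D_est == pytest.approx(D, rel=0.02)

    def test_confined_particle_plateaus(self):
        # reflecting box oracle: MSD saturates, long-lag slope < 0.5
        rng = np.random.default_rng(9)
        n, steps, L, box = 200, 4000, 2.0, 30.0
        pos = np.full((n, 2), box / 2)
        traj = np.zeros((steps + 1, n, 2))
        traj[0] = pos
        for t in range(steps):
            ang = rng.uniform(0, 2 * math.pi, n)
            prop = pos + np.stack([L * np.cos(ang), L * np.sin(ang)], axis=-1)
            prop = np.abs(prop)  # reflect at 0
            prop = box - np.abs(box - prop)  # reflect at box
            pos = prop
            traj[t + 1] = pos
        times = np.arange(steps + 1) * 1e-5
        curve = msd(traj, times)
        slope = msd_loglog_slope(curve, (curve.lags[-1] / 10, curve.lags[-1]))
        assert slope < 0.5

    def test_lag_beyond_trajectory_reported_absent(self):
        traj = np.zeros((10, 3, 2))
        times = np.arange(10) * 0.1
        curve = msd(traj, times, lags=[5, 20])
        assert math.isnan(curve.msd[1])
        assert curve.n_contributing[1] == 0

    def test_nonuniform_sampling_rejected(self):
        traj = np.zeros((4, 2, 2))
        with pytest.raises(ValueError):
            msd(traj, np.array([0.0, 0.1, 0.3, 0.35]))


def _snap(time, clusters, centroids=None):
    k = len(clusters)
    cents = np.zeros((k, 2)) if centroids is None else np.asarray(centroids, float)
    return ClusterSnapshot(time=time,
                           clusters=[np.array(sorted(c), dtype=int) for c in clusters],
                           centroids=cents)


class TestTrackLifetimes:
    def test_persistent_pair_lifetime(self):
        # a bond pair existing for exactly 10 snapshots at 0.1 s spacing,
        # then dissolved: lifetime 1.0 s
        snaps = [_snap(0.1 * t, [[0, 1]]) for t in range(10)]
        snaps.append(_snap(1.0, [[0], [1]]))
        # singletons are not components of size >= 2; rebuild cluster lists
        snaps[-1] = _snap(1.0, [])
        tracks = track_lifetimes(snaps)
        assert len(tracks) == 1
        assert tracks[0].lifetime == pytest.approx(1.0)
        assert not tracks[0].censored

    def test_open_track_is_right_censored(self):
        snaps = [_snap(0.1 * t, [[0, 1, 2]]) for t in range(5)]
        tracks = track_lifetimes(snaps)
        assert tracks[0].censored
        assert tracks[0].death is None
        assert math.isnan(mean_lifetime(tracks))

    def test_split_follows_lowest_min_id_half(self):
        snaps = [
            _snap(0.0, [[0, 1, 2, 3]]),
            _snap(0.1, [[0, 1], [2, 3]]),
            _snap(0.2, [[0, 1], [2, 3]]),
        ]
        tracks = track_lifetimes(snaps)
        assert len(tracks) == 2
        t0 = tracks[0]
        assert t0.birth == 0.0
        assert t0.sizes == [4, 2, 2]  # followed the {0,1} half
        assert tracks[1].birth == pytest.approx(0.1)

    def test_merge_continues_larger_overlap(self):
        snaps = [
            _snap(0.0, [[0, 1, 2], [5, 6]]),
            _snap(0.1, [[0, 1, 2, 5, 6]]),
        ]
        tracks = track_lifetimes(snaps)
        big = [t for t in tracks if t.birth == 0.0 and t.sizes[0] == 3][0]
        small = [t for t in tracks if t.sizes[0] == 2][0]
        assert big.sizes == [3, 5]  # the triple continues into the merge
        assert small.death == pytest.approx(0.1)

    def test_frozen_snapshots_yield_immortal_tracks(self, dom, params):
        st = _state_with_bonds(8, dom, params, cis_pairs=[(0, 1), (2, 3), (3, 4)],
                               planes=np.zeros(8, dtype=np.int64))
        base = find_clusters(st)
        snaps = []
        for t in range(6):
            s = ClusterSnapshot(time=float(t), clusters=base.clusters,
                                centroids=base.centroids)
            snaps.append(s)
        tracks = track_lifetimes(snaps)
        assert len(tracks) == 2  # the two bonded components
        assert all(t.censored for t in tracks)

    def test_nonuniform_spacing_rejected(self):
        snaps = [_snap(0.0, [[0, 1]]), _snap(0.1, [[0, 1]]), _snap(0.3, [[0, 1]])]
        with pytest.raises(ValueError):
            track_lifetimes(snaps)


class TestPatterning:
    def test_nnd_two_clusters(self, dom):
        snap = _snap(0.0, [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]],
                     centroids=[[100.0, 100.0], [200.0, 100.0]])
        assert nnd(snap, dom) == pytest.approx(100.0)

    def test_nnd_uses_minimal_image(self, dom):
        snap = _snap(0.0, [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]],
                     centroids=[[10.0, 0.0], [990.0, 0.0]])
        assert nnd(snap, dom) == pytest.approx(20.0)

    def test_nnd_absent_below_two_qualifying(self, dom):
        snap = _snap(0.0, [[0, 1, 2, 3, 4], [5, 6]],
                     centroids=[[0, 0], [50, 50]])
        assert math.isnan(nnd(snap, dom))

    def test_size_cv_zero_for_equal_sizes(self, dom):
        snap = _snap(0.0, [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]])
        assert size_cv(snap) == 0.0

    def test_size_cv_value(self, dom):
        snap = _snap(0.0, [list(range(0, 5)), list(range(5, 12)), [20]])
        sizes = np.array([5, 7])
        expected = sizes.std() / sizes.mean()
        assert size_cv(snap) == pytest.approx(expected)

    def test_grid_nnd_exceeds_random_nnd(self, dom):
        rng = np.random.default_rng(4)
        k = 16
        side = int(math.sqrt(k))
        grid_cents = [
            [(i + 0.5) * dom.width / side, (j + 0.5) * dom.height / side]
            for i in range(side) for j in range(side)
        ]
        grid_snap = _snap(0.0, [[5 * c + m for m in range(5)] for c in range(k)],
                          centroids=grid_cents)
        vals = []
        for _ in range(20):
            rand_cents = rng.uniform(0, dom.width, (k, 2))
            rand_snap = _snap(0.0, [[5 * c + m for m in range(5)] for c in range(k)],
                              centroids=rand_cents)
            vals.append(nnd(rand_snap, dom))
        assert nnd(grid_snap, dom) > np.mean(vals)
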