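import itertools

import numpy as np
import pytest

from amideshell import synthetic as syn
from amideshell.hbond import (
    HBondCriteria,
    dist_angle_histogram,
    find_water_bridges,
    group_acceptors,
    group_donors,
    hbond_count_series,
    hbond_state_distribution,
    is_hbonded,
    rank_waters,
    running_integral,
    water_molecules,
)
from conftest import make_water_box_frame


class TestIsHbonded:
    def setup_method(self):
        self.acceptor = np.zeros(3)

    def _triple(self, r, dev_deg):
        """Donor-H-acceptor with H at distance r, deviation dev from linear."""
        h = np.array([r, 0.0, 0.0])
        th = np.radians(dev_deg)
        d = h + 0.9572 * np.array([np.cos(th), np.sin(th), 0.0])
        return d, h

    def test_typical_bond_geometry(self):
        d, h = self._triple(1.8, 10.0)
        assert is_hbonded(d, h, self.acceptor)

    def test_inclusive_boundary(self):
        d, h = self._triple(2.5, 45.0)
        assert is_hbonded(d, h, self.acceptor)

    def test_distance_exceeded(self):
        d, h = self._triple(2.6, 0.0)
        assert not is_hbonded(d, h, self.acceptor)

    def test_angle_exceeded(self):
        d, h = self._triple(1.8, 46.0)
        assert not is_hbonded(d, h, self.acceptor)

    def test_coincident_h_and_acceptor(self):
        with pytest.raises(ValueError, match="coincide"):
            is_hbonded(np.array([1.0, 0, 0]), np.zeros(3), np.zeros(3))

    def test_minimum_image_applied(self):
        box = np.array([10.0, 10.0, 10.0])
        # H at 8.2 along x is 1.8 A from the acceptor through the +x boundary;
        # the donor sits on the opposite side so D-H...A is linear
        h = np.array([8.2, 0.0, 0.0])
        d = np.array([7.2428, 0.0, 0.0])
        assert is_hbonded(d, h, self.acceptor, box=box)
        with np.testing.assert_raises(AssertionError):
            # without the box the pair is 8.2 A apart: no bond
            assert is_hbonded(d, h, self.acceptor)

    def test_criteria_monotonicity(self):
        d, h = self._triple(2.3, 30.0)
        loose = HBondCriteria(r_max=3.0, ang_max=60.0)
        tight = HBondCriteria(r_max=2.5, ang_max=45.0)
        assert is_hbonded(d, h, self.acceptor, tight) <= is_hbonded(d, h, self.acceptor, loose)


class TestCountSeries:
    def test_one_water_schedule(self):
        hs = syn.HydrationSchedule([(0.0, 500.0, 1.0, 0.0)])
        traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=1)
        series = hbond_count_series(traj, "C2=O2")
        mean, _ = series.window_stats()
        assert mean == pytest.approx(1.0, abs=0.1)

    def test_window_means_ordered(self, three_window_traj):
        series = hbond_count_series(three_window_traj, "C2=O2")
        m1, _ = series.window_stats(0, 2000)
        m2, _ = series.window_stats(2000, 4000)
        m3, _ = series.window_stats(4000, 6000)
        assert m1 < m2 < m3
        assert m1 == pytest.approx(1.0, abs=0.1)
        assert m2 == pytest.approx(1.5, abs=0.1)
        assert m3 == pytest.approx(2.0, abs=0.1)

    def test_no_waters_zero_series(self, peptide_fixture):
        from amideshell.trajectory_io import Topology, Trajectory

        top, pos = peptide_fixture
        top2 = Topology(labels=top.labels, elements=top.elements, masses=top.masses,
                        bonds=top.bonds, groups={**top.groups, "water": ()})
        traj = Trajectory(top2, pos[None], dt=0.5)
        series = hbond_count_series(traj, "C2=O2")
        assert series.counts.tolist() == [0]

    def test_identity_count_consistency(self, three_window_traj):
        series = hbond_count_series(three_window_traj, "C2=O2")
        for c, ids in zip(series.counts[::500], series.identities[::500]):
            assert c == len(ids)

    def test_exchange_changes_identity(self):
        hs = syn.HydrationSchedule([(0.0, 2000.0, 1.0, 0.005)])
        traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=3)
        series = hbond_count_series(traj, "C2=O2")
        assert len(set(series.identities)) > 1

    def test_empty_window_raises(self, three_window_traj):
        series = hbond_count_series(three_window_traj, "C2=O2")
        with pytest.raises(ValueError, match="empty"):
            series.window_stats(1e6, 2e6)

    def test_loosening_criteria_never_decreases(self, three_window_traj):
        tight = hbond_count_series(three_window_traj, "C2=O2", HBondCriteria(2.5, 45.0))
        loose = hbond_count_series(three_window_traj, "C2=O2", HBondCriteria(3.0, 60.0))
        assert np.all(loose.counts >= tight.counts)


class TestStateDistribution:
    def test_direct_count(self):
        from amideshell.hbond import HBondSeries

        s = HBondSeries(np.array([1, 1, 2, 2]), [frozenset({0})] * 2 + [frozenset({0, 1})] * 2,
                        dt=0.5, group="g")
        assert hbond_state_distribution(s) == {1: 0.5, 2: 0.5}

    def test_point_mass(self):
        from amideshell.hbond import HBondSeries

        s = HBondSeries(np.full(7, 2), [frozenset({0, 1})] * 7, dt=0.5, group="g")
        assert hbond_state_distribution(s) == {2: 1.0}

    def test_mixed_window_bimodal_and_mean_conserved(self, three_window_traj):
        series = hbond_count_series(three_window_traj, "C2=O2")
        dist = hbond_state_distribution(series)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert {1, 2} <= set(dist)
        mean_dist = sum(k * p for k, p in dist.items())
        assert mean_dist == pytest.approx(series.counts.mean())


@pytest.fixture(scope="module")
def hist():
    hs = syn.HydrationSchedule([(0.0, 1000.0, 1.0, 0.0)], mean_r=1.9, mean_theta=10.0,
                               jitter_r=0.05, jitter_theta=2.0)
    traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=2, n_background=0)
    return dist_angle_histogram(traj, "C2=O2", r_range=(0.0, 10.0))


class TestDistAngleHistogram:

    def test_modal_bin_matches_generator(self, hist):
        i, j = np.unravel_index(np.argmax(hist.grid), hist.grid.shape)
        assert hist.r_centers[i] == pytest.approx(1.9, abs=0.1)
        assert hist.theta_centers[j] == pytest.approx(10.0, abs=3.0)

    def test_marginals_are_projected_sums(self, hist):
        np.testing.assert_allclose(hist.g_r, hist.grid.sum(axis=1) * hist.dtheta)
        np.testing.assert_allclose(hist.g_theta, hist.grid.sum(axis=0) * hist.dr)

    def test_grid_nonnegative(self, hist):
        assert np.all(hist.grid >= 0)

    def test_empty_water_set_zero_grid(self, peptide_fixture):
        from amideshell.trajectory_io import Topology, Trajectory

        top, pos = peptide_fixture
        top2 = Topology(labels=top.labels, elements=top.elements, masses=top.masses,
                        bonds=top.bonds, groups={**top.groups, "water": ()})
        traj = Trajectory(top2, pos[None], dt=0.5)
        h = dist_angle_histogram(traj, "C2=O2")
        np.testing.assert_allclose(h.grid, 0.0)

    def test_bimodal_recovery(self):
        hs1 = syn.HydrationSchedule([(0.0, 500.0, 1.0, 0.0)], mean_r=1.7, jitter_r=0.03)
        hs2 = syn.HydrationSchedule([(0.0, 500.0, 1.0, 0.0)], mean_r=2.3, jitter_r=0.03)
        t1 = syn.gen_hydration_trajectory(hs1, dt=0.5, seed=4)
        t2 = syn.gen_hydration_trajectory(hs2, dt=0.5, seed=5)
        h1 = dist_angle_histogram(t1, "C2=O2")
        h2 = dist_angle_histogram(t2, "C2=O2")
        combined = h1.grid + h2.grid
        g_r = combined.sum(axis=1)
        r_at = h1.r_centers
        peak1 = r_at[np.argmax(g_r * (r_at < 2.0))]
        peak2 = r_at[np.argmax(g_r * (r_at >= 2.0))]
        assert peak1 == pytest.approx(1.7, abs=0.1)
        assert peak2 == pytest.approx(2.3, abs=0.1)


@pytest.fixture(scope="module")
def single_water_hist():
    hs = syn.HydrationSchedule([(0.0, 1000.0, 1.0, 0.0)], mean_r=1.8, jitter_r=0.03)
    traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=6, n_background=0)
    return dist_angle_histogram(traj, "C2=O2", r_range=(0.0, 10.0))


class TestRunningIntegral:

    def test_step_at_water_distance(self, single_water_hist):
        assert running_integral(single_water_hist, 1.6) == pytest.approx(0.0, abs=0.01)
        assert running_integral(single_water_hist, 2.1) == pytest.approx(1.0, abs=0.02)

    def test_below_first_bin_zero(self, single_water_hist):
        assert running_integral(single_water_hist, 0.0) == 0.0

    def test_two_water_cutoff(self):
        hs = syn.HydrationSchedule([(0.0, 1000.0, 2.0, 0.0)])
        traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=7, n_background=0)
        h = dist_angle_histogram(traj, "C2=O2", r_range=(0.0, 10.0))
        assert running_integral(h, 2.5, "hbond") == pytest.approx(2.0, abs=0.05)

    def test_monotone_nondecreasing(self, single_water_hist):
        rs = np.linspace(0.1, 9.9, 40)
        vals = [running_integral(single_water_hist, r) for r in rs]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_infinity_equals_mean_total(self):
        hs = syn.HydrationSchedule([(0.0, 500.0, 1.0, 0.0)])
        traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=8, n_background=3)
        h = dist_angle_histogram(traj, "C2=O2", r_range=(0.0, 20.0))
        total = running_integral(h, 20.0, "all")
        assert total == pytest.approx(4.0, abs=0.01)  # 1 bound + 3 background


class TestRankWaters:
    def _frame_with_waters_at(self, dists):
        hs = syn.HydrationSchedule([(0.0, 10.0, 0.0, 0.0)])
        traj = syn.gen_hydration_trajectory(hs, dt=0.5, seed=9,
                                            n_background=len(dists))
        pos = traj.positions[0].copy()
        top = traj.topology
        o2 = pos[2]
        waters = water_molecules(top)
        for k, d in enumerate(dists):
            base = waters[k, 0]
            direction = np.array([np.cos(k), np.sin(k), 0.1 * k])
            direction /= np.linalg.norm(direction)
            shift = o2 + d * direction - pos[base]
            pos[base:base + 3] += shift
        from amideshell.trajectory_io import Frame

        return Frame(pos, topology=top), waters

    def test_rank_order(self):
        frame, waters = self._frame_with_waters_at([1.8, 2.5, 3.7, 4.1])
        ranking = rank_waters(frame, "C2=O2", n=4)
        assert [rw.oxygen for rw in ranking] == list(waters[:4, 0])
        assert not ranking.short
        oo = [rw.oo_distance for rw in ranking]
        assert oo == sorted(oo)

    def test_rank_identity_swap(self):
        f1, waters = self._frame_with_waters_at([1.8, 3.0])
        f2, _ = self._frame_with_waters_at([3.0, 1.8])
        r1 = rank_waters(f1, "C2=O2", n=2)
        r2 = rank_waters(f2, "C2=O2", n=2)
        assert r1[0].oxygen != r2[0].oxygen

    def test_tie_breaks_on_atom_index(self):
        frame, waters = self._frame_with_waters_at([2.0, 2.0])
        ranking = rank_waters(frame, "C2=O2", n=2)
        assert ranking[0].oxygen < ranking[1].oxygen

    def test_short_flag(self):
        frame, _ = self._frame_with_waters_at([2.0])
        ranking = rank_waters(frame, "C2=O2", n=4)
        assert ranking.short
        assert len(ranking) == 1


class TestWaterBridges:
    def test_three_water_bridge(self, water_chain_frame):
        bridges = find_water_bridges(water_chain_frame, "C2=O2", "C3=O3")
        assert len(bridges) == 1
        assert bridges[0].order == 3

    def test_no_bridge_empty(self, water_chain_frame):
        # N2-D2 donor points away from every water
        bridges = find_water_bridges(water_chain_frame, "N2-D2", "C3=O3")
        assert bridges == []

    def test_order_cap(self, water_chain_frame):
        bridges = find_water_bridges(water_chain_frame, "C2=O2", "C3=O3", max_order=2)
        assert bridges == []


def brute_force_bond_mask(frame, group, criteria):
    """Exhaustive all-pairs H-bond enumeration (oracle)."""
    top = frame.topology
    waters = water_molecules(top)
    acceptors = group_acceptors(top, group)
    donors = group_donors(top, group)
    pos = frame.positions
    out = []
    for o, h1, h2 in waters:
        bonded = False
        for a in acceptors:
            for h in (h1, h2):
                if is_hbonded(pos[o], pos[h], pos[a], criteria, frame.box):
                    bonded = True
        for d, h in donors:
            if is_hbonded(pos[d], pos[h], pos[o], criteria, frame.box):
                bonded = True
        out.append(bonded)
    return np.array(out)


def brute_force_bridges(frame, group_a, group_b, criteria, max_order=7):
    """Exhaustive simple-path search over the H-bond graph (oracle)."""
    top = frame.topology
    waters = water_molecules(top)
    nw = len(waters)
    pos = frame.positions
    a_mask = brute_force_bond_mask(frame, group_a, criteria)
    b_mask = brute_force_bond_mask(frame, group_b, criteria)
    ww = np.zeros((nw, nw), dtype=bool)
    for i, j in itertools.combinations(range(nw), 2):
        for don, acc in ((i, j), (j, i)):
            for h in waters[don, 1:3]:
                try:
                    if is_hbonded(pos[waters[don, 0]], pos[h], pos[waters[acc, 0]],
                                  criteria, frame.box):
                        ww[i, j] = ww[j, i] = True
                except ValueError:
                    pass
    paths = []

    def extend(path):
        last = path[-1]
        if b_mask[last]:
            paths.append(tuple(path))
        if len(path) >= max_order:
            return
        for nxt in range(nw):
            if ww[last, nxt] and nxt not in path:
                extend(path + [nxt])

    for start in np.nonzero(a_mask)[0]:
        extend([int(start)])
    if not paths:
        return set()
    shortest = min(len(p) for p in paths)
    return {p for p in paths if len(p) == shortest}


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_bond_mask_matches_production(self, seed):
        from amideshell.hbond import _water_group_bond_mask

        frame = make_water_box_frame(n_waters=15, seed=seed)
        top = frame.topology
        crit = HBondCriteria()
        waters = water_molecules(top)
        prod = _water_group_bond_mask(
            frame.positions, frame.box, waters,
            group_acceptors(top, "C2=O2"), group_donors(top, "C2=O2"), crit
        )
        oracle = brute_force_bond_mask(frame, "C2=O2", crit)
        np.testing.assert_array_equal(prod, oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_bridges_match_exhaustive_search(self, seed):
        frame = make_water_box_frame(n_waters=12, seed=seed, spread=4.0)
        crit = HBondCriteria(r_max=3.0, ang_max=60.0)  # denser graph
        waters = water_molecules(frame.topology)
        oxy_to_local = {int(o): k for k, (o, _, _) in enumerate(waters)}
        prod = find_water_bridges(frame, "C2=O2", "C3=O3", crit)
        prod_paths = {tuple(oxy_to_local[o] for o in b.path) for b in prod}
        oracle = brute_force_bridges(frame, "C2=O2", "C3=O3", crit)
        assert prod_paths == oracle

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_periodic_box_bond_mask(self, seed):
        from amideshell.hbond import _water_group_bond_mask

        box = np.array([12.0, 12.0, 12.0])
        frame = make_water_box_frame(n_waters=10, seed=seed, box=box, spread=8.0)
        top = frame.topology
        crit = HBondCriteria()
        waters = water_molecules(top)
        prod = _water_group_bond_mask(
            frame.positions, frame.box, waters,
            group_acceptors(top, "C2=O2"), group_donors(top, "C2=O2"), crit
        )
        oracle = brute_force_bond_mask(frame, "C2=O2", crit)
        np.testing.assert_array_equal(prod, oracle)
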