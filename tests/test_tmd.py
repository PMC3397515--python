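"""Elastic network, RMSD restraint energetics, and Langevin TMD dynamics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from radamotor import (
    FilamentSpec, LegParams, Structure, TMDRestraint, build_elastic_network,
    make_filament, network_energy_forces, rmsd, rmsd0_linear_schedule,
    run_cycle, run_tmd_leg, superpose, tmd_energy_forces,
)


def ca_structure(coords):
    n = len(coords)
    return Structure(np.arange(1, n + 1), ["ALA"] * n, ["CA"] * n, coords)


class TestElasticNetwork:
    def test_two_atoms_one_pair(self):
        s = ca_structure(np.array([[0.0, 0, 0], [3.0, 0, 0]]) + 1.0)
        net = build_elastic_network(s, cutoff=5.0)
        assert len(net.pairs) == 1
        assert net.rest_lengths[0] == pytest.approx(3.0)

    def test_linear_chain_nearest_neighbours_only(self):
        n = 8
        s = ca_structure(np.column_stack([3.8 * np.arange(n),
                                          np.zeros(n), np.zeros(n)]))
        net = build_elastic_network(s, cutoff=4.0)
        assert len(net.pairs) == n - 1

    def test_pair_count_matches_brute_force(self):
        s = make_filament(FilamentSpec(20, 3.8, 100.0, 2.3))
        net = build_elastic_network(s, cutoff=10.0)
        d = np.linalg.norm(s.coords[:, None] - s.coords[None], axis=-1)
        brute = int(np.sum(np.triu(d <= 10.0, k=1)))
        assert len(net.pairs) == brute
        np.testing.assert_allclose(
            net.rest_lengths, d[net.pairs[:, 0], net.pairs[:, 1]])

    def test_disconnected_atom_warns(self):
        s = ca_structure(np.array([[0.0, 0, 0], [3.0, 0, 0], [100.0, 0, 0]]))
        with pytest.warns(UserWarning, match="disconnected"):
            build_elastic_network(s, cutoff=5.0)

    def test_energy_invariant_under_rigid_motion(self, rng):
        s = make_filament(FilamentSpec(10, 3.8, 100.0, 2.3))
        net = build_elastic_network(s, cutoff=8.0)
        x = s.coords + rng.normal(0, 0.3, s.coords.shape)
        e1, _ = network_energy_forces(x, net)
        r = Rotation.random(rng=rng).as_matrix()
        e2, _ = network_energy_forces(x @ r.T + np.array([7.0, -2.0, 1.0]), net)
        assert e2 == pytest.approx(e1, abs=1e-9)

    def test_forces_sum_to_zero(self, rng):
        s = make_filament(FilamentSpec(10, 3.8, 100.0, 2.3))
        net = build_elastic_network(s, cutoff=8.0)
        _, f = network_energy_forces(s.coords + rng.normal(0, 0.5, s.coords.shape), net)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        sched = rmsd0_linear_schedule(8.0, 2.0)
        assert sched(0.0) == 8.0
        assert sched(1.0) == 4.0
        assert sched(2.0) == 0.0
        assert sched(3.0) == 0.0  # clamped

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rmsd0_linear_schedule(-1.0, 1.0)
        with pytest.raises(ValueError):
            rmsd0_linear_schedule(1.0, 0.0)


class TestRestraintEnergy:
    def test_zero_at_matched_rmsd(self, rng):
        tgt = ca_structure(rng.normal(0, 3, (8, 3)))
        restraint = TMDRestraint(K=200.0, target=tgt,
                                 schedule=lambda t: 0.0, duration=1.0)
        e, f = tmd_energy_forces(tgt.coords.copy(), restraint, 0.5)
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_closed_form_unit_energy(self):
        """K=200, N=100, RMSD−RMSD0 = 1 Å ⇒ U = K/(2N) = 1.0 kcal/mol."""
        rng = np.random.default_rng(0)
        tgt = ca_structure(rng.normal(0, 5, (100, 3)))
        restraint = TMDRestraint(K=200.0, target=tgt,
                                 schedule=lambda t: 1.0, duration=1.0)
        # mobile = target: RMSD = 0, RMSD0 = 1 → Δ = 1
        e, _ = tmd_energy_forces(tgt.coords.copy(), restraint, 0.0)
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_energy_nonnegative_and_zero_iff_matched(self, rng):
        tgt = ca_structure(rng.normal(0, 3, (10, 3)))
        restraint = TMDRestraint(K=200.0, target=tgt,
                                 schedule=lambda t: 0.5, duration=1.0)
        for _ in range(10):
            x = tgt.coords + rng.normal(0, 1.0, tgt.coords.shape)
            e, _ = tmd_energy_forces(x, restraint, 0.1)
            assert e >= 0.0
            matched = rmsd(x, tgt.coords) == pytest.approx(0.5, abs=1e-12)
            assert (e == pytest.approx(0.0, abs=1e-12)) == matched

    def test_time_outside_schedule_rejected(self, rng):
        tgt = ca_structure(rng.normal(0, 3, (5, 3)))
        restraint = TMDRestraint(K=200.0, target=tgt,
                                 schedule=lambda t: 0.0, duration=1.0)
        with pytest.raises(ValueError, match="outside"):
            tmd_energy_forces(tgt.coords, restraint, 2.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_forces_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        tgt = ca_structure(rng.normal(0, 3, (8, 3)))
        restraint = TMDRestraint(K=200.0, target=tgt,
                                 schedule=lambda t: 0.5, duration=1.0)
        x = tgt.coords + rng.normal(0, 1.0, (8, 3))
        _, forces = tmd_energy_forces(x, restraint, 0.0)
        h = 1e-5
        for i in range(8):
            for k in range(3):
                p, m = x.copy(), x.copy()
                p[i, k] += h
                m[i, k] -= h
                ep, _ = tmd_energy_forces(p, restraint, 0.0)
                em, _ = tmd_energy_forces(m, restraint, 0.0)
                fd = -(ep - em) / (2 * h)
                assert forces[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def toy_pair():
    """10-residue helix A and its distorted partner B."""
    a = make_filament(FilamentSpec(10, 3.8, 100.0, 2.3))
    b = make_filament(FilamentSpec(10, 3.8, -100.0, 2.3))
    return a, b


class TestRunTmdLeg:
    def test_fixed_point_at_zero_temperature(self):
        a, _ = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        restraint = TMDRestraint(K=200.0, target=a, schedule=lambda t: 0.0,
                                 duration=1.0)
        params = LegParams(steps=1000, output_stride=100, seed=0, temperature=0.0)
        traj, _ = run_tmd_leg(a, net, restraint, params)
        assert np.abs(traj.frames[-1] - a.coords).max() < 1e-3

    def test_two_state_convergence(self):
        a, b = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        r0 = superpose(a, b).rmsd
        assert r0 > 1.0
        leg_ns = 3000 * 0.01 / 1000.0
        restraint = TMDRestraint(K=200.0, target=b,
                                 schedule=rmsd0_linear_schedule(r0, 0.75 * leg_ns),
                                 duration=leg_ns)
        params = LegParams(steps=3000, output_stride=100, seed=1)

        def rest_schedule(t, a0=np.linalg.norm(
                a.coords[net.pairs[:, 0]] - a.coords[net.pairs[:, 1]], axis=1),
                b0=np.linalg.norm(
                b.coords[net.pairs[:, 0]] - b.coords[net.pairs[:, 1]], axis=1)):
            frac = min(1.0, t / (0.75 * leg_ns))
            return (1 - frac) * a0 + frac * b0

        traj, _ = run_tmd_leg(a, net, restraint, params, rest_schedule=rest_schedule)
        assert superpose(traj.frames[-1], b.coords).rmsd <= 0.5

    def test_deterministic_for_fixed_seed(self):
        a, b = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        restraint = TMDRestraint(K=200.0, target=b,
                                 schedule=rmsd0_linear_schedule(5.0, 0.02),
                                 duration=0.02)
        params = LegParams(steps=500, output_stride=50, seed=42)
        t1, p1 = run_tmd_leg(a, net, restraint, params)
        t2, p2 = run_tmd_leg(a, net, restraint, params)
        np.testing.assert_array_equal(t1.frames, t2.frames)
        np.testing.assert_array_equal(p1.potential, p2.potential)

    def test_energy_non_increasing_at_zero_temperature(self):
        a, _ = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        rng = np.random.default_rng(3)
        start = a.coords + rng.normal(0, 0.8, a.coords.shape)
        restraint = TMDRestraint(K=200.0, target=a, schedule=lambda t: 0.0,
                                 duration=1.0)
        params = LegParams(steps=2000, output_stride=20, seed=0, temperature=0.0)
        _, prof = run_tmd_leg(start, net, restraint, params)
        total = prof.potential + prof.restraint
        # underdamped modes trade kinetic and potential energy, so check the
        # decaying envelope first, then strict decay once settled
        blocks = [total[i:i + 20].max() for i in range(0, 100, 20)]
        assert all(b2 < b1 for b1, b2 in zip(blocks, blocks[1:]))
        settled = total[60:]  # after transients (~12 ps)
        assert np.all(np.diff(settled) <= 1e-4)

    def test_blow_up_aborts_with_diagnostic(self):
        a, b = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        restraint = TMDRestraint(K=200.0, target=b, schedule=lambda t: 0.0,
                                 duration=10.0)
        params = LegParams(dt=50.0, steps=200, output_stride=10, seed=0)  # unstable dt
        with pytest.raises(RuntimeError, match="blow-up"):
            run_tmd_leg(a, net, restraint, params)

    def test_leg_end_rmsd_monotone_in_force_constant(self):
        a, b = toy_pair()
        net = build_elastic_network(a, cutoff=10.0)
        finals = []
        for K in (20.0, 200.0, 2000.0):
            leg_ns = 2000 * 0.01 / 1000.0
            restraint = TMDRestraint(K=K, target=b,
                                     schedule=rmsd0_linear_schedule(
                                         superpose(a, b).rmsd, 0.75 * leg_ns),
                                     duration=leg_ns)
            traj, _ = run_tmd_leg(a, net, restraint,
                                  LegParams(steps=2000, output_stride=200, seed=5))
            finals.append(superpose(traj.frames[-1], b.coords).rmsd)
        assert finals[0] > finals[1] > finals[2]


class TestRunCycle:
    def test_identical_states_stay_put(self):
        a, _ = toy_pair()
        lp = LegParams(steps=300, output_stride=30, seed=0, temperature=0.0)
        traj, prof, summ = run_cycle([a, a, a, a], leg_params=lp, seed=0)
        assert prof.potential[0] == 0.0
        for s in summ:
            assert s["end_rmsd_to_target"] < 0.05
            assert s["barrier_height"] < 0.5

    def test_cycle_closure_and_zero_reference(self, quartet):
        lp = LegParams(steps=3000, output_stride=25, seed=1)
        traj, prof, summ = run_cycle(list(quartet), leg_params=lp, seed=1)
        ca = quartet[0].role_indices(("CA",))
        closure = superpose(traj.frames[-1][ca], quartet[0].coords[ca]).rmsd
        assert closure <= 0.5
        assert prof.potential[0] == 0.0
        assert [s["is_global_max"] for s in summ].count(True) == 1

    def test_incongruent_states_rejected(self):
        a, _ = toy_pair()
        c = make_filament(FilamentSpec(12, 3.8, 100.0, 2.3))
        with pytest.raises(ValueError, match="congruent"):
            run_cycle([a, a, c, a])
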