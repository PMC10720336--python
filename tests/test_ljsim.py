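"""LJ simulator: neighbor-list exactness, force/virial correctness,
pressure identities, miss counting, and integrator properties."""

import numpy as np
import pytest

from verletdiag.core import CutoffScheme, ScheduleConfig, REDUCED_UNITS
from verletdiag.ljsim import (
    BarostatConfig,
    LJPotential,
    NeighborList,
    SimState,
    ThermostatConfig,
    brute_force_pairs,
    build_neighbor_list,
    count_missed,
    forces_energy_virial,
    instantaneous_pressure,
    run,
)
from verletdiag.synthetic import gen_freeflight_gas

POT = LJPotential(epsilon=1.0, sigma=1.0, r_c=2.5)


def two_particle_state(distance, box=10.0):
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + distance, 1.0, 1.0]])
    return SimState(
        positions=pos, velocities=np.zeros((2, 3)), box=np.full(3, box), masses=1.0
    )


class TestNeighborList:
    def test_pair_inside_cutoff_found(self):
        state = two_particle_state(0.9 * 2.5)
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        assert len(nlist.pairs) == 1

    def test_pair_outside_cutoff_absent(self):
        state = two_particle_state(1.1 * 2.5)
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        assert len(nlist.pairs) == 0

    def test_minimum_image_across_boundary(self):
        state = SimState(
            positions=np.array([[0.1, 5.0, 5.0], [9.9, 5.0, 5.0]]),
            velocities=np.zeros((2, 3)),
            box=np.full(3, 10.0),
            masses=1.0,
        )
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        assert len(nlist.pairs) == 1  # separation 0.2 through the boundary

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([7.0, 8.0, 9.0])
        state = SimState(
            positions=rng.random((400, 3)) * box,
            velocities=np.zeros((400, 3)),
            box=box,
            masses=1.0,
        )
        cut = CutoffScheme(r_c=2.5, r_l=3.0)
        fast = build_neighbor_list(state, cut).pairs
        oracle = brute_force_pairs(state, 3.0)
        assert np.array_equal(fast, oracle)

    def test_box_too_small_is_an_error(self):
        state = two_particle_state(1.0, box=4.0)
        with pytest.raises(ValueError, match="minimum-image"):
            build_neighbor_list(state, CutoffScheme(r_c=2.0, r_l=2.5))


class TestForcesEnergyVirial:
    def test_lj_minimum_has_zero_force(self):
        state = two_particle_state(2.0 ** (1.0 / 6.0))
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        forces, energy, _ = forces_energy_virial(state, POT, nlist)
        assert np.abs(forces).max() < 1e-12
        assert energy == pytest.approx(-1.0 + POT.shift)

    def test_beyond_cutoff_contributes_nothing(self):
        state = two_particle_state(2.6)
        nlist = NeighborList(pairs=np.array([[0, 1]]), built_at_step=0, r_l=3.0)
        forces, energy, virial = forces_energy_virial(state, POT, nlist)
        assert np.all(forces == 0.0) and energy == 0.0 and np.all(virial == 0.0)

    def test_forces_are_energy_gradient(self):
        # central-difference oracle on a random dense configuration
        rng = np.random.default_rng(7)
        box = np.full(3, 6.0)
        state = SimState(
            positions=rng.random((60, 3)) * box,
            velocities=np.zeros((60, 3)),
            box=box,
            masses=1.0,
        )
        cut = CutoffScheme(r_c=2.5, r_l=2.9)
        nlist = build_neighbor_list(state, cut)
        forces, _, _ = forces_energy_virial(state, POT, nlist)
        h = 1e-5
        num = np.zeros_like(forces)
        for i in range(6):  # spot-check a subset of particles
            for c in range(3):
                for sgn, dst in ((+1, 0), (-1, 1)):
                    st = state.copy()
                    st.positions[i, c] += sgn * h
                    e = forces_energy_virial(st, POT, nlist)[1]
                    num[i, c] += e if dst == 0 else -e
        num /= 2.0 * h
        scale = np.abs(forces[:6]).max()
        assert np.abs(-num[:6] - forces[:6]).max() / scale < 1e-6

    def test_single_pair_virial_closed_form(self):
        d = 1.5
        state = two_particle_state(d)
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        _, _, virial = forces_energy_virial(state, POT, nlist)
        sr6 = d**-6
        w = 24.0 * (2.0 * sr6**2 - sr6) / d**2  # f_vec = w * d_vec
        assert virial[0, 0] == pytest.approx(w * d * d, rel=1e-12)
        assert virial[1, 1] == 0.0 and virial[2, 2] == 0.0


class TestInstantaneousPressure:
    def test_ideal_gas_law(self):
        state = gen_freeflight_gas(
            rho=0.5, temperature=1.0, mass=1.0, box=8.0, seed=3, units=REDUCED_UNITS
        )
        ps = instantaneous_pressure(state, np.zeros((3, 3)), REDUCED_UNITS)
        # for an ideal gas the virial vanishes and P = 2 E_kin / (3V) holds
        assert ps.scalar == pytest.approx(
            2.0 * state.kinetic_energy() / (3.0 * state.volume)
        )
        # and at N ~ 250 the sample is close to rho kB T
        assert ps.scalar == pytest.approx(0.5 * 1.0, rel=0.15)

    def test_at_rest_without_interactions_pressure_vanishes(self):
        state = two_particle_state(5.0, box=12.0)
        ps = instantaneous_pressure(state, np.zeros((3, 3)), REDUCED_UNITS)
        assert ps.scalar == 0.0

    def test_parallel_and_normal_components(self):
        state = two_particle_state(5.0, box=12.0)
        tensor = np.diag([1.0, 3.0, 5.0])
        ps = instantaneous_pressure(state, tensor * state.volume, REDUCED_UNITS)
        assert ps.parallel == pytest.approx(2.0)
        assert ps.normal == pytest.approx(5.0)

    def test_listed_pairs_match_all_pairs_evaluation(self, equilibrated_lj_small):
        state = equilibrated_lj_small
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        n = state.n
        i, j = np.triu_indices(n, k=1)
        allpairs = NeighborList(
            pairs=np.column_stack([i, j]), built_at_step=0, r_l=np.inf
        )
        f1, e1, v1 = forces_energy_virial(state, POT, nlist)
        f2, e2, v2 = forces_energy_virial(state, POT, allpairs)
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert np.allclose(f1, f2, atol=1e-10)
        assert np.allclose(v1, v2, atol=1e-10)


class TestCountMissed:
    def test_fresh_list_misses_nothing(self, equilibrated_lj_small):
        state = equilibrated_lj_small
        nlist = build_neighbor_list(state, CutoffScheme(r_c=2.5, r_l=2.5))
        nu, ne = count_missed(state, 2.5, nlist, set())
        assert nu == 0 and ne == 0

    def test_displacement_bound_guarantees_no_misses(self):
        # buffer wider than any pair can close in one lifetime
        state = gen_freeflight_gas(
            rho=0.4, temperature=1.0, mass=1.0, box=14.0, seed=5, units=REDUCED_UNITS
        )
        nst, dt = 10, 0.005
        v_max = np.linalg.norm(state.velocities, axis=1).max()
        r_l = 2.5 + 2.0 * v_max * nst * dt
        res = run(
            state,
            None,
            CutoffScheme(r_c=2.5, r_l=r_l),
            ScheduleConfig(dt=dt, nstlist=nst),
            3 * nst,
            units=REDUCED_UNITS,
            count_misses=True,
        )
        assert res.miss_events.sum() == 0

    def test_every_step_rebuilds_never_miss(self):
        state = gen_freeflight_gas(
            rho=0.4, temperature=1.0, mass=1.0, box=11.0, seed=6, units=REDUCED_UNITS
        )
        res = run(
            state,
            None,
            CutoffScheme(r_c=2.5, r_l=2.5),
            ScheduleConfig(dt=0.01, nstlist=1),
            30,
            units=REDUCED_UNITS,
            count_misses=True,
        )
        assert res.miss_events.sum() == 0

    def test_stale_list_with_zero_buffer_misses(self):
        state = gen_freeflight_gas(
            rho=0.4, temperature=1.0, mass=1.0, box=11.0, seed=7, units=REDUCED_UNITS
        )
        res = run(
            state,
            None,
            CutoffScheme(r_c=2.5, r_l=2.5),
            ScheduleConfig(dt=0.01, nstlist=20),
            100,
            units=REDUCED_UNITS,
            count_misses=True,
        )
        assert res.miss_events.sum() > 0
        assert np.all(res.miss_unique <= res.miss_events)


class TestRun:
    def test_momentum_conserved_in_nve(self, equilibrated_lj_small):
        state = equilibrated_lj_small
        res = run(
            state,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            ScheduleConfig(dt=0.004, nstlist=10),
            200,
            units=REDUCED_UNITS,
        )
        p0 = (state.velocities * state.masses[:, None]).sum(axis=0)
        p1 = (res.state.velocities * res.state.masses[:, None]).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-9

    def test_nve_energy_stable_with_complete_lists(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.5),
            ScheduleConfig(dt=0.002, nstlist=1),
            1500,
            units=REDUCED_UNITS,
        )
        drift = abs(res.e_total[-1] - res.e_total[0]) / res.state.n
        assert drift < 5e-4

    def test_zero_buffer_stale_lists_drift_and_miss(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.5),
            ScheduleConfig(dt=0.002, nstlist=40),
            1600,
            units=REDUCED_UNITS,
            count_misses=True,
        )
        assert res.miss_events.sum() > 0
        drift = (res.e_total[-1] - res.e_total[0]) / res.state.n
        # missed attractive pairs re-enter the list at rebuilds with u < 0,
        # so the total energy drifts measurably (downward for attractive LJ)
        assert abs(drift) > 1e-3
        assert drift < 0

    def test_degenerate_dual_list_is_bit_identical(self, equilibrated_lj_small):
        sched = ScheduleConfig(dt=0.004, nstlist=20)
        single = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            sched,
            100,
            units=REDUCED_UNITS,
        )
        dual = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(
                r_c=2.5, r_l=2.8, dual=True, r_inner=2.8, nstlist_inner=5
            ),
            sched,
            100,
            units=REDUCED_UNITS,
        )
        assert np.array_equal(single.state.positions, dual.state.positions)
        assert np.array_equal(single.p_scalar, dual.p_scalar)

    def test_dual_list_prunes_and_runs(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=3.0, dual=True, r_inner=2.6, nstlist_inner=5),
            ScheduleConfig(dt=0.004, nstlist=20),
            60,
            units=REDUCED_UNITS,
        )
        assert np.isfinite(res.p_scalar).all()

    def test_incompatible_inner_interval_rejected(self, equilibrated_lj_small):
        with pytest.raises(ValueError):
            run(
                equilibrated_lj_small,
                POT,
                CutoffScheme(
                    r_c=2.5, r_l=3.0, dual=True, r_inner=2.6, nstlist_inner=7
                ),
                ScheduleConfig(dt=0.004, nstlist=20),
                10,
                units=REDUCED_UNITS,
            )

    def test_divergence_reports_step(self, equilibrated_lj_small):
        with pytest.raises(RuntimeError, match="step"):
            run(
                equilibrated_lj_small,
                POT,
                CutoffScheme(r_c=2.5, r_l=2.8),
                ScheduleConfig(dt=5.0, nstlist=1),  # absurd time step
                50,
                units=REDUCED_UNITS,
            )

    def test_thermostat_holds_temperature(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            ScheduleConfig(dt=0.004, nstlist=10, nsttcouple=10),
            300,
            thermostat=ThermostatConfig(target=1.0),
            units=REDUCED_UNITS,
        )
        assert res.state.temperature(REDUCED_UNITS) == pytest.approx(1.0, rel=0.05)

    def test_isotropic_barostat_relaxes_pressure(self, equilibrated_lj_small):
        # dense fluid at P ~ 2.4 coupled to target 1: the box must expand
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            ScheduleConfig(dt=0.004, nstlist=10, nstpcouple=10, nsttcouple=10),
            400,
            thermostat=ThermostatConfig(target=1.0),
            barostat=BarostatConfig(
                mode="isotropic", tau_p=2.0, target=1.0, compressibility=0.05
            ),
            units=REDUCED_UNITS,
        )
        assert res.box[-1].prod() > res.box[0].prod()
        # isotropic coupling keeps the box cubic
        assert np.ptp(res.box[-1]) < 1e-12

    def test_semiisotropic_barostat_couples_xy_jointly(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            ScheduleConfig(dt=0.004, nstlist=10, nstpcouple=10),
            100,
            barostat=BarostatConfig(
                mode="semi-isotropic", tau_p=2.0, target=1.0, compressibility=0.05
            ),
            units=REDUCED_UNITS,
        )
        assert res.box[-1][0] == pytest.approx(res.box[-1][1], rel=1e-14)
        assert res.box[-1][2] != pytest.approx(res.box[-1][0], rel=1e-6)

    def test_pressure_series_export(self, equilibrated_lj_small):
        res = run(
            equilibrated_lj_small,
            POT,
            CutoffScheme(r_c=2.5, r_l=2.8),
            ScheduleConfig(dt=0.004, nstlist=10),
            50,
            units=REDUCED_UNITS,
        )
        series = res.pressure_series()
        assert series.has_tensor and len(series) == 51
        assert series.nstlist == 10
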