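"""Missed-interaction model: closed form vs sampling oracles, monotonicity,
rigid-molecule extension, and the r_l recommendation engine."""

import math

import numpy as np
import pytest

from verletdiag.core import CutoffScheme, ScheduleConfig
from verletdiag.missmodel import (
    GasModel,
    RigidGasModel,
    crossing_probability_endpoint,
    drift_rate,
    martini_water_gas,
    n_missed_point,
    n_missed_rigid,
    recommend_rl,
    relative_velocity_sigma,
    tip3p_like_rigid,
)

MARTINI = martini_water_gas()  # rho=7.08 nm^-3, m=72 amu, T=310 K
MARTINI_CUT = CutoffScheme(r_c=1.1, r_l=1.28)
MARTINI_SCHED = ScheduleConfig(dt=0.02, nstlist=25)


def sampling_oracle(r, r_c, sigma, n, rng):
    """Brute-force estimate of P(|r_vec + d| < r_c) for Gaussian d."""
    d = rng.normal(scale=sigma, size=(n, 3))
    d[:, 2] += r  # place the pair along z
    p = np.mean(np.einsum("ij,ij->i", d, d) < r_c**2)
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return p, se


class TestCrossingProbability:
    @pytest.mark.parametrize(
        "r,r_c,t",
        [
            (1.30, 1.1, 0.5),  # Martini-like bead, dense sampling region
            (1.35, 1.1, 0.5),
            (1.30, 1.2, 0.3),
            (1.50, 1.1, 0.8),
        ],
    )
    def test_matches_sampling_oracle(self, r, r_c, t, rng):
        gas = GasModel(rho=7.08, mass=72.0, temperature=310.0)
        cut = CutoffScheme(r_c=r_c, r_l=min(r - 0.01, r_c + 0.1) if r - 0.01 > r_c else r_c)
        p = crossing_probability_endpoint(r, cut, t, gas)
        sigma = t * relative_velocity_sigma(310.0, 72.0, 72.0)
        p_mc, se = sampling_oracle(r, r_c, sigma, 1_000_000, rng)
        assert p == pytest.approx(p_mc, abs=4 * se)

    def test_no_displacement_means_no_crossing(self):
        p = crossing_probability_endpoint(1.30, MARTINI_CUT, 0.0, MARTINI)
        assert p == 0.0

    def test_huge_cutoff_sphere_captures_everything(self):
        # underlying displacement law: a sphere much larger than both the
        # pair distance and the displacement scale captures probability 1
        from verletdiag.missmodel import _gaussian_sphere_prob

        assert _gaussian_sphere_prob(1.3, r_c=1e3, sigma=0.2) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_inside_buffer_is_a_domain_error(self):
        with pytest.raises(ValueError):
            crossing_probability_endpoint(1.2, MARTINI_CUT, 0.5, MARTINI)


class TestNMissedPoint:
    def test_endpoint_regression_value(self):
        # frozen from this implementation's verified oracle run
        est = n_missed_point(MARTINI_CUT, MARTINI_SCHED, MARTINI, "endpoint")
        assert est.n_missed == pytest.approx(0.6861051442869, rel=1e-9)
        assert est.stderr == 0.0

    def test_path_mc_regression_value(self):
        est = n_missed_point(
            MARTINI_CUT, MARTINI_SCHED, MARTINI, "path-MC", n_samples=200_000, seed=1
        )
        assert est.n_missed == pytest.approx(0.5746452835072, rel=1e-9)

    def test_estimators_cross_validate(self):
        # endpoint closed form and path sampling describe the same physics
        e1 = n_missed_point(MARTINI_CUT, MARTINI_SCHED, MARTINI, "endpoint")
        e2 = n_missed_point(
            MARTINI_CUT, MARTINI_SCHED, MARTINI, "path-MC", n_samples=1_000_000, seed=3
        )
        assert e1.n_missed > 0 and e2.n_missed > 0
        assert abs(e1.n_missed - e2.n_missed) / e2.n_missed < 0.25

    def test_unreachable_buffer_gives_zero(self):
        cut = CutoffScheme(r_c=1.1, r_l=3.0)
        est = n_missed_point(cut, MARTINI_SCHED, MARTINI, "endpoint")
        assert est.n_missed < 1e-12

    def test_no_stale_steps_no_misses(self):
        sched = ScheduleConfig(dt=0.02, nstlist=1)
        est = n_missed_point(MARTINI_CUT, sched, MARTINI, "path-MC", seed=0)
        assert est.n_missed == 0.0 and est.per_step == 0.0

    def test_monotone_in_buffer_interval_temperature_density(self):
        base = n_missed_point(MARTINI_CUT, MARTINI_SCHED, MARTINI).n_missed
        wider = n_missed_point(
            CutoffScheme(r_c=1.1, r_l=1.4), MARTINI_SCHED, MARTINI
        ).n_missed
        longer = n_missed_point(
            MARTINI_CUT, ScheduleConfig(dt=0.02, nstlist=50), MARTINI
        ).n_missed
        hotter = n_missed_point(
            MARTINI_CUT, MARTINI_SCHED, GasModel(7.08, 72.0, 360.0)
        ).n_missed
        denser = n_missed_point(
            MARTINI_CUT, MARTINI_SCHED, GasModel(9.0, 72.0, 310.0)
        ).n_missed
        assert wider < base < longer
        assert base < hotter
        assert base < denser

    def test_per_step_bounds_unique_misses(self):
        est = n_missed_point(
            MARTINI_CUT, MARTINI_SCHED, MARTINI, "path-MC", n_samples=50_000, seed=9
        )
        assert est.per_step >= est.n_missed > 0

    def test_fixed_seed_is_bit_reproducible(self):
        a = n_missed_point(MARTINI_CUT, MARTINI_SCHED, MARTINI, "path-MC", seed=42)
        b = n_missed_point(MARTINI_CUT, MARTINI_SCHED, MARTINI, "path-MC", seed=42)
        assert a.n_missed == b.n_missed and a.per_step == b.per_step

    def test_bad_gas_rejected(self):
        with pytest.raises(ValueError):
            GasModel(rho=-1.0, mass=72.0, temperature=310.0)
        with pytest.raises(ValueError):
            GasModel(rho=7.0, mass=0.0, temperature=310.0)


class TestNMissedRigid:
    def test_point_limit_reproduces_point_model(self):
        # all site offsets zero: the rigid body degenerates to a point mass
        rigid = RigidGasModel(
            rho=7.08,
            temperature=310.0,
            site_offsets={"W": np.zeros((1, 3))},
            site_masses={"W": 72.0},
        )
        sched = ScheduleConfig(dt=0.02, nstlist=10)
        cut = CutoffScheme(r_c=1.1, r_l=1.2)
        er = n_missed_rigid(cut, sched, rigid, ("W", "W"), n_samples=40_000, seed=11)
        ep = n_missed_point(
            cut, sched, GasModel(7.08, 72.0, 310.0), "path-MC",
            n_samples=200_000, seed=12,
        )
        assert er.n_missed == pytest.approx(
            ep.n_missed, abs=3 * math.hypot(er.stderr, ep.stderr)
        )

    def test_frozen_molecules_miss_nothing(self):
        rigid = tip3p_like_rigid(temperature=0.0)
        est = n_missed_rigid(
            CutoffScheme(r_c=1.2, r_l=1.25),
            ScheduleConfig(dt=0.002, nstlist=20),
            rigid,
            ("H", "H"),
            n_samples=1000,
            seed=0,
        )
        assert est.n_missed == 0.0

    def test_fast_hydrogens_dominate_misses(self):
        # peripheral light sites sweep the widest arcs, so at equal cutoffs
        # H-H pairs are missed more often than O-H, and O-H more than O-O
        rigid = tip3p_like_rigid()
        cut = CutoffScheme(r_c=1.2, r_l=1.24)
        sched = ScheduleConfig(dt=0.002, nstlist=20)
        ests = {
            pair: n_missed_rigid(cut, sched, rigid, pair, n_samples=30_000, seed=21)
            for pair in [("H", "H"), ("O", "H"), ("O", "O")]
        }
        n_hh = ests[("H", "H")]
        n_oh = ests[("O", "H")]
        n_oo = ests[("O", "O")]
        assert n_hh.n_missed > n_oh.n_missed > n_oo.n_missed

    def test_zero_inertia_with_off_axis_mass_rejected(self):
        with pytest.raises(ValueError):
            RigidGasModel(
                rho=30.0,
                temperature=300.0,
                site_offsets={"A": np.array([[0.1, 0.0, 0.0]])},
                site_masses={"A": 1.0},
                inertia=np.array([0.0, 0.0, 0.0]),
            )

    def test_unknown_site_type_rejected(self):
        rigid = tip3p_like_rigid()
        with pytest.raises(ValueError):
            n_missed_rigid(
                CutoffScheme(r_c=1.2, r_l=1.25),
                ScheduleConfig(dt=0.002, nstlist=5),
                rigid,
                ("O", "X"),
            )


class TestRecommendRl:
    def test_infinite_tolerance_returns_rc(self):
        rl = recommend_rl(MARTINI_SCHED, MARTINI, 1.1, tolerance=math.inf)
        assert rl == 1.1

    def test_longer_lifetime_needs_larger_buffer(self):
        rl_25 = recommend_rl(MARTINI_SCHED, MARTINI, 1.1, 1e-4)
        rl_50 = recommend_rl(ScheduleConfig(dt=0.02, nstlist=50), MARTINI, 1.1, 1e-4)
        assert rl_50 > rl_25 > 1.1

    def test_bisection_postcondition(self):
        tol = 1e-4
        rl = recommend_rl(MARTINI_SCHED, MARTINI, 1.1, tol)
        at = n_missed_point(CutoffScheme(1.1, rl), MARTINI_SCHED, MARTINI).n_missed
        below = n_missed_point(
            CutoffScheme(1.1, rl - 0.01), MARTINI_SCHED, MARTINI
        ).n_missed
        assert at <= tol < below

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            recommend_rl(MARTINI_SCHED, MARTINI, 1.1, 0.0)


class TestDriftRate:
    def test_unreachable_buffer_drifts_nothing(self):
        d = drift_rate(
            CutoffScheme(r_c=1.1, r_l=3.0), MARTINI_SCHED, MARTINI,
            epsilon=5.0, sigma=0.47, n_samples=20_000, seed=3,
        )
        assert d == 0.0

    def test_drift_decreases_with_buffer(self):
        rls = [1.15, 1.25, 1.35, 1.45]
        drifts = [
            drift_rate(
                CutoffScheme(r_c=1.1, r_l=rl), MARTINI_SCHED, MARTINI,
                epsilon=5.0, sigma=0.47, n_samples=60_000, seed=4,
            )
            for rl in rls
        ]
        assert drifts[0] > 0
        assert all(a > b for a, b in zip(drifts, drifts[1:]))

    def test_martini_default_scenario_is_positive(self):
        d = drift_rate(
            MARTINI_CUT, MARTINI_SCHED, MARTINI,
            epsilon=5.0, sigma=0.47, n_samples=40_000, seed=5,
        )
        assert d > 0
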