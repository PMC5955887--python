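"""Reaction-diffusion model: diffusive rates, capture probability, scans."""

import numpy as np
import pytest

import dimerkin as dk
from dimerkin.msm import stationary_distribution
from dimerkin.rxndiff import (
    RDParams,
    capture_probability,
    component_rates,
    concentration_scan,
    convert_rate,
    estimate_diffusion,
    estimate_passage_fractions,
    estimate_r0,
    k_plus1,
    lifetimes,
)


class TestDiffusionEstimate:
    def test_recovers_generator_truth(self, free_world, free_trajs):
        # window well below L/2: the radial coordinate diffuses freely there
        D, se = estimate_diffusion(free_trajs, d_window=(4.0, 6.0), max_lag=3)
        D_rel = 2 * free_world.diffusion_translation
        assert D == pytest.approx(D_rel, rel=0.05)

    def test_frozen_trajectory_zero(self):
        tr = dk.CVTrajectory(t=np.arange(100.0), d=np.full(100, 5.0),
                             alpha1=np.zeros(100), alpha2=np.zeros(100), dt=0.01)
        D, _ = estimate_diffusion([tr], d_window=(4, 7), max_lag=4)
        assert D == pytest.approx(0.0, abs=1e-12)

    def test_time_resolution_invariance(self, free_world):
        """Halving the recording step leaves the estimate unchanged within error."""
        coarse = dk.simulate_unbiased(free_world, 4, 100_000, dt=1e-3, stride=10)
        fine = dk.simulate_unbiased(free_world, 4, 200_000, dt=5e-4, stride=10)
        Dc, _ = estimate_diffusion(coarse, d_window=(4, 7), max_lag=5)
        Df, _ = estimate_diffusion(fine, d_window=(4, 7), max_lag=5)
        assert Df == pytest.approx(Dc, rel=0.1)

    def test_empty_window_errors(self):
        tr = dk.CVTrajectory(t=np.arange(10.0), d=np.full(10, 1.0),
                             alpha1=np.zeros(10), alpha2=np.zeros(10), dt=0.01)
        with pytest.raises(ValueError):
            estimate_diffusion([tr], d_window=(4, 7), max_lag=3)


class TestEncounterDistance:
    def test_single_state(self):
        assert estimate_r0([1.0], [6.2], [0]) == pytest.approx(6.2)

    def test_uniform_two_states(self):
        assert estimate_r0([0.3, 0.2, 0.2], [1.0, 5.0, 7.0], [1, 2]) == pytest.approx(6.0)

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            estimate_r0([1.0], [6.2], [])


class TestKPlus1:
    def test_worked_example(self):
        lam_um = (np.pi * 100) ** -0.5
        expect = 4 * np.pi * 0.1 / np.log(lam_um * 1e3 / 6.2) * 1e-6
        assert k_plus1(100, 0.1, 6.2) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_c_and_linear_in_D(self):
        assert k_plus1(400, 0.1, 6.2) > k_plus1(100, 0.1, 6.2)
        assert k_plus1(100, 0.2, 6.2) == pytest.approx(2 * k_plus1(100, 0.1, 6.2))

    def test_too_dense_errors(self):
        with pytest.raises(ValueError, match="mean free path"):
            k_plus1(1e7, 0.1, 6.2)


class TestCaptureProbability:
    def test_fesc_zero_gives_fass(self):
        assert capture_probability(0.7, 0.0, 100, 6.2, 7.0) == pytest.approx(0.7)

    def test_fass_one_gives_one(self):
        assert capture_probability(1.0, 0.0, 100, 6.2, 7.0) == pytest.approx(1.0)

    def test_large_mean_free_path_limit(self):
        # λ→∞: p_ass→0 so γ→f_ass
        g = capture_probability(0.6, 0.4, 1e12, 6.2, 7.0)
        assert g == pytest.approx(0.6, rel=1e-2)

    def test_geometry_and_fraction_validation(self):
        with pytest.raises(ValueError):
            capture_probability(0.5, 0.5, 6.5, 6.2, 7.0)  # λ < r1
        with pytest.raises(ValueError):
            capture_probability(1.5, 0.0, 100, 6.2, 7.0)


class TestPassageFractions:
    def test_hand_built_excursions(self):
        # one association (d dips below 2 after crossing r0) and one escape
        d = np.array([8, 7, 6.0, 5, 4, 1.5, 5, 6.0, 6.5, 7.2, 8])
        tr = dk.CVTrajectory(t=np.arange(len(d), dtype=float), d=d,
                             alpha1=np.zeros(len(d)), alpha2=np.zeros(len(d)), dt=1.0)
        f_ass, f_esc = estimate_passage_fractions(
            [tr], r0=6.2, r1=7.0, is_associated=lambda d, a1, a2: np.asarray(d) < 2.0
        )
        assert f_ass == pytest.approx(0.5)
        assert f_esc == pytest.approx(0.5)


class TestComponentRates:
    def _Tcg(self):
        return np.array([
            [0.94, 0.02, 0.02, 0.01, 0.01],
            [0.05, 0.95, 0, 0, 0],
            [0.05, 0, 0.95, 0, 0],
            [0.08, 0, 0, 0.92, 0],
            [0.10, 0, 0, 0, 0.90],
        ])

    def test_two_state_closed_forms(self):
        p, q, tau = 0.1, 0.2, 0.05
        T = np.array([[1 - p, p], [q, 1 - q]])
        r_lin = component_rates(T, tau, ["C00"], time_scale=1.0)
        assert r_lin.k_enter[0] == pytest.approx(p / tau)
        assert r_lin.k_exit[0] == pytest.approx(q / tau)
        r_log = component_rates(T, tau, ["C00"], time_scale=1.0, method="matrix_log")
        # exact generator of a 2-state chain: K = -ln(1-p-q)/(p+q) * [[-p, p], [q, -q]]
        factor = -np.log(1 - p - q) / (p + q)
        assert r_log.k_enter[0] == pytest.approx(factor * p / tau, rel=1e-10)
        assert r_log.k_exit[0] == pytest.approx(factor * q / tau, rel=1e-10)

    def test_identity_matrix_zero_rates(self):
        r = component_rates(np.eye(3), 0.05, ["A", "B"], time_scale=1.0)
        assert np.all(r.k_enter == 0) and np.all(r.k_exit == 0)

    def test_time_scale_applied_exactly_once(self):
        T = self._Tcg()
        r1 = component_rates(T, 0.05, ["a", "b", "c", "d"], time_scale=1.0)
        r4 = component_rates(T, 0.05, ["a", "b", "c", "d"], time_scale=4.0)
        assert np.allclose(r4.k_exit * 4, r1.k_exit)
        t1 = lifetimes(r1)["T_off_us"].to_numpy()
        t4 = lifetimes(r4)["T_off_us"].to_numpy()
        assert np.allclose(t4, 4 * t1)


class TestConcentrationScan:
    def _rates(self, time_scale=1.0):
        return component_rates(
            np.array([
                [0.94, 0.02, 0.02, 0.01, 0.01],
                [0.05, 0.95, 0, 0, 0],
                [0.05, 0, 0.95, 0, 0],
                [0.08, 0, 0, 0.92, 0],
                [0.10, 0, 0, 0, 0.90],
            ]),
            0.05, ["C0pi", "Cpi0", "Cpipi", "C00"], time_scale=time_scale,
        )

    def test_zero_entry_rates_zero_fractions(self):
        rates = component_rates(np.eye(3), 0.05, ["A", "B"], time_scale=1.0)
        res = concentration_scan(rates, RDParams(c_grid=np.array([1.0, 100.0])))
        assert np.all(res.table["fraction"].fillna(0) == 0)

    def test_bound_fraction_monotone_in_c(self):
        res = concentration_scan(self._rates(), RDParams(c_grid=np.logspace(-1, 3, 17)))
        tot = res.table[res.table.valid].groupby("c")["fraction"].sum()
        assert np.all(np.diff(tot.to_numpy()) >= -1e-12)

    def test_equilibrium_consistent_with_reduced_matrix(self):
        """Conditional on being bound, the component fractions equal the
        stationary ratios of the reduced transfer matrix at any c."""
        rates = self._rates()
        res = concentration_scan(rates, RDParams(c_grid=np.array([50.0])))
        t = res.table[res.table.valid]
        fr = t.set_index("component")["fraction"]
        pi_cg = stationary_distribution(np.array([
            [0.94, 0.02, 0.02, 0.01, 0.01],
            [0.05, 0.95, 0, 0, 0],
            [0.05, 0, 0.95, 0, 0],
            [0.08, 0, 0, 0.92, 0],
            [0.10, 0, 0, 0, 0.90],
        ]))
        expect = pi_cg[1:] / pi_cg[1:].sum()
        got = (fr / fr.sum()).loc[["C0pi", "Cpi0", "Cpipi", "C00"]].to_numpy()
        assert np.allclose(got, expect, atol=1e-12)

    def test_k_on_vanishes_at_low_c_and_saturates(self):
        """Effective association is diffusion-limited (→0) at low density and
        reaction-limited (saturating at the entry rate) at high density."""
        # slow chemical step so the crossover happens inside the dilute regime
        T = np.eye(5)
        T[0, 1:] = [5e-7, 5e-7, 2.5e-7, 2.5e-7]
        T[0, 0] = 1 - T[0, 1:].sum()
        for i, p in enumerate([2e-3, 2e-3, 4e-3, 5e-3], start=1):
            T[i, 0] = p
            T[i, i] = 1 - p
        rates = component_rates(T, 0.05, ["C0pi", "Cpi0", "Cpipi", "C00"],
                                time_scale=1.0)
        res = concentration_scan(rates, RDParams(c_grid=np.logspace(-5, 3.5, 40)))
        t = res.table[(res.table.component == "C0pi") & res.table.valid]
        k_eff = t["k_on_eff"].to_numpy()
        assert k_eff[0] < 1e-6 * k_eff[-1]
        # low-c regime still strongly growing, high-c regime nearly flat
        assert k_eff[len(k_eff) // 2] / k_eff[len(k_eff) // 2 - 4] > 5
        assert k_eff[-1] / k_eff[-5] < 1.2

    def test_too_dense_points_flagged(self):
        res = concentration_scan(self._rates(), RDParams(c_grid=np.array([1.0, 1e6])))
        flags = res.table.groupby("c")["valid"].all()
        assert flags[1.0] and not flags[1e6]


class TestUnits:
    def test_rate_round_trips_exact(self):
        assert convert_rate(3e-4, "per_us", "per_ms") == 0.3
        assert convert_rate(0.3, "per_ms", "per_s") == 300.0
        assert convert_rate(convert_rate(1.23, "per_us", "per_s"), "per_s", "per_us") == 1.23

    def test_lifetime_inverse(self):
        r = dk.ComponentRates(labels=["C0pi"], k_enter=np.array([0.1]),
                              k_exit=np.array([1 / 210.0]), lag_us=0.05, time_scale=4.0)
        assert lifetimes(r)["T_off_us"].iloc[0] == pytest.approx(210.0)
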