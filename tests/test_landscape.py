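import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from unfoldkit.constants import kbt_joule
from unfoldkit.errors import ConfigError, FitError, InsufficientDataError
from unfoldkit.landscape import (
    alpha0_from_intercept,
    barrier_height,
    bootstrap_landscape,
    delta_x_from_slope,
    fit_fmp_vs_lnv,
    fit_fu_vs_lnr,
    mc_landscape_search,
    most_probable_force,
    propagate_uncertainties,
    protein_spring_constant,
)
from unfoldkit.simulate import SimulationConfig, simulate_curve

SPEEDS = (400.0, 800.0, 1600.0, 3200.0, 6400.0, 12800.0)


def bell_line(delta_x_nm, alpha0, temperature):
    """Slope and intercept (N) of the Bell-Evans FU-vs-ln r line."""
    kbt = kbt_joule(temperature)
    dx = delta_x_nm * 1e-9
    slope = kbt / dx
    intercept = slope * math.log(dx / (alpha0 * kbt))
    return slope, intercept


def sample_bell_forces(rng, n, loading_rate, delta_x_nm, alpha0, temperature):
    """Rupture forces (pN) at constant loading rate via the inverse CDF."""
    kbt = kbt_joule(temperature)
    dx = delta_x_nm * 1e-9
    u = rng.uniform(size=n)
    arg = 1.0 - (loading_rate * dx / (alpha0 * kbt)) * np.log(u)
    return (kbt / dx) * np.log(arg) * 1e12


class TestMostProbableForce:
    def test_gaussian_sample(self):
        rng = np.random.default_rng(1)
        forces = rng.normal(200.0, 25.0, 10_000)
        assert most_probable_force(forces) == pytest.approx(200.0, abs=2.0)

    def test_degenerate_sample(self):
        assert most_probable_force(np.full(150, 150.0)) == 150.0

    def test_too_few_forces(self):
        with pytest.raises(InsufficientDataError):
            most_probable_force(np.arange(10.0))


class TestFmpVsLnv:
    def test_closed_form_round_trip(self):
        # Fmp generated exactly from the Bell-Evans relation with r = k*v
        dx_nm, alpha0, k, temp = 0.15, 0.34, 0.06, 296.15
        kbt = kbt_joule(temp)
        dx = dx_nm * 1e-9
        pairs = []
        for v in SPEEDS:
            fmp = (kbt / dx) * math.log(k * (v * 1e-9) * dx / (alpha0 * kbt))
            pairs.append((v, fmp * 1e12))
        est = fit_fmp_vs_lnv(pairs, temp, effective_k=k)
        assert est.delta_x == pytest.approx(dx_nm, rel=1e-6)
        assert est.alpha0 == pytest.approx(alpha0, rel=1e-6)
        assert est.delta_g == pytest.approx(math.log(1e7 / alpha0), rel=1e-6)

    def test_alpha0_requires_stiffness(self):
        pairs = [(v, 100.0 + 25.0 * math.log(v)) for v in SPEEDS]
        est = fit_fmp_vs_lnv(pairs, 296.15)
        assert est.alpha0 is None and est.delta_g is None
        assert est.delta_x > 0

    def test_two_speeds_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_fmp_vs_lnv([(400.0, 100.0), (800.0, 120.0)], 296.15)

    def test_flat_line_rejected(self):
        with pytest.raises(FitError):
            fit_fmp_vs_lnv([(v, 150.0) for v in SPEEDS], 296.15)


def _table(fu_pN, rate_Ns, speeds):
    return pd.DataFrame({
        "fu_pN": fu_pN, "loading_rate_Ns": rate_Ns, "speed_nms": speeds,
        "included": True,
    })


class TestFuVsLnr:
    def test_exact_line_recovery(self):
        # line built from the 23 C parameters: S = kBT/0.15 nm = 27.26 pN
        slope, intercept = bell_line(0.15, 0.34, 296.15)
        rates = np.logspace(-9, -7, 12)
        fu = (slope * np.log(rates) + intercept) * 1e12
        speeds = np.repeat((400.0, 1600.0, 6400.0), 4)
        est = fit_fu_vs_lnr(_table(fu, rates, speeds), 296.15)
        assert est.slope == pytest.approx(slope, rel=1e-9)
        assert est.slope * 1e12 == pytest.approx(27.26, abs=0.01)
        assert est.intercept * 1e12 == pytest.approx(692.4, abs=0.5)
        assert est.delta_x == pytest.approx(0.15, rel=1e-9)
        assert est.alpha0 == pytest.approx(0.34, rel=1e-9)

    def test_bell_sampled_events_recover_slope(self):
        # stochastic rupture forces at each speed's loading rate (r = k*v)
        rng = np.random.default_rng(23)
        dx_nm, alpha0, temp = 0.15, 0.34, 296.15
        fu, rates, speeds = [], [], []
        for v in SPEEDS:
            r = 0.06 * v * 1e-9
            f = sample_bell_forces(rng, 400, r, dx_nm, alpha0, temp)
            fu.extend(f)
            rates.extend([r] * f.size)
            speeds.extend([v] * f.size)
        est = fit_fu_vs_lnr(_table(np.array(fu), np.array(rates), np.array(speeds)), temp)
        assert est.slope * 1e12 == pytest.approx(27.26, rel=0.10)

    def test_single_speed_rejected(self):
        table = _table(np.linspace(100, 200, 30), np.logspace(-9, -8, 30),
                       np.full(30, 1600.0))
        with pytest.raises(InsufficientDataError):
            fit_fu_vs_lnr(table, 296.15)

    def test_constant_rate_rejected(self):
        table = _table(np.linspace(100, 200, 30), np.full(30, 1e-8),
                       np.repeat((400.0, 1600.0, 6400.0), 10))
        with pytest.raises(FitError):
            fit_fu_vs_lnr(table, 296.15)


class TestParameterFormulas:
    def test_delta_x_from_slope_printed_row(self):
        assert delta_x_from_slope(27.26e-12, 296.15) == pytest.approx(0.150, abs=0.001)

    def test_delta_x_identity_and_scaling(self):
        s = kbt_joule(296.15) / 1e-9
        assert delta_x_from_slope(s, 296.15) == pytest.approx(1.0, rel=1e-12)
        assert delta_x_from_slope(2 * s, 296.15) == pytest.approx(0.5, rel=1e-12)
        with pytest.raises(ValueError):
            delta_x_from_slope(0.0, 296.15)

    def test_alpha0_printed_row(self):
        assert alpha0_from_intercept(692.4e-12, 27.26e-12) == pytest.approx(0.34, abs=0.005)

    def test_alpha0_zero_intercept(self):
        assert alpha0_from_intercept(0.0, 2.0) == pytest.approx(0.5, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dx=st.floats(0.05, 2.0), a0=st.floats(1e-6, 1e3), temp=st.floats(273.0, 320.0))
    def test_round_trip_identities(self, dx, a0, temp):
        slope, intercept = bell_line(dx, a0, temp)
        assert delta_x_from_slope(slope, temp) == pytest.approx(dx, rel=1e-9)
        assert alpha0_from_intercept(intercept, slope) == pytest.approx(a0, rel=1e-9)

    def test_barrier_height_printed_rows(self):
        assert barrier_height(1.17) == pytest.approx(15.96, abs=0.01)
        assert barrier_height(0.34) == pytest.approx(17.20, abs=0.01)
        assert barrier_height(1e7) == 0.0
        with pytest.raises(ValueError):
            barrier_height(2e7)

    def test_spring_constant_printed_row(self):
        assert protein_spring_constant(15.98, 0.13, 291.15) == pytest.approx(7.60, abs=0.01)
        assert protein_spring_constant(0.0, 0.13, 291.15) == 0.0
        d1 = protein_spring_constant(15.98, 0.13, 291.15)
        d2 = protein_spring_constant(15.98, 0.26, 291.15)
        assert d2 == pytest.approx(d1 / 4.0, rel=1e-12)


class TestUncertainties:
    def test_zero_covariance_gives_zero_stderrs(self):
        sds = propagate_uncertainties(27.26e-12, 692.4e-12, np.zeros((2, 2)), 296.15)
        assert all(v == 0.0 for v in sds.values())

    def test_jacobian_matches_finite_differences(self):
        s, c, temp, a = 27.26e-12, 692.4e-12, 296.15, 1e7
        cov = np.array([[1e-26, 2e-25], [2e-25, 1e-23]])

        def params(slope, intercept):
            dx = delta_x_from_slope(slope, temp)
            a0 = alpha0_from_intercept(intercept, slope)
            dg = barrier_height(a0, a)
            return np.array([dx, a0, dg, protein_spring_constant(dg, dx, temp)])

        h_s, h_c = s * 1e-7, c * 1e-7
        j_s = (params(s + h_s, c) - params(s - h_s, c)) / (2 * h_s)
        j_c = (params(s, c + h_c) - params(s, c - h_c)) / (2 * h_c)
        jac = np.column_stack([j_s, j_c])
        expected = np.sqrt(np.einsum("ij,jk,ik->i", jac, cov, jac))
        sds = propagate_uncertainties(s, c, cov, temp, a)
        got = np.array([sds["delta_x"], sds["alpha0"], sds["delta_g"], sds["spring_d"]])
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_bootstrap_agrees_with_delta_method(self):
        rng = np.random.default_rng(31)
        fu, rates, speeds = [], [], []
        for v in SPEEDS:
            r = 0.06 * v * 1e-9
            f = sample_bell_forces(rng, 150, r, 0.15, 0.34, 296.15)
            fu.extend(f)
            rates.extend([r] * f.size)
            speeds.extend([v] * f.size)
        table = _table(np.array(fu), np.array(rates), np.array(speeds))
        est = fit_fu_vs_lnr(table, 296.15)
        boot = bootstrap_landscape(table, 296.15, n_boot=300, seed=5)
        assert boot["delta_x"] == pytest.approx(est.delta_x_stderr, rel=0.30)


class TestMcLandscapeSearch:
    BASE = SimulationConfig(n_domains=5, piezo_range=250.0, force_noise_sd=0.0,
                            detachment_force_mean="never")

    def _observed(self, n_curves=100):
        observed = {}
        for v in (400.0, 6400.0):
            cfg = SimulationConfig(n_domains=5, piezo_range=250.0, force_noise_sd=0.0,
                                   detachment_force_mean="never", pulling_speed=v)
            children = np.random.SeedSequence(123).spawn(n_curves)
            forces = []
            for child in children:
                _, truth = simulate_curve(cfg, np.random.default_rng(child), record=False)
                forces.extend(e.force for e in truth.events)
            observed[v] = np.array(forces)
        return observed

    def test_recovers_generating_grid_point(self):
        observed = self._observed()
        best, surface = mc_landscape_search(
            observed, [0.10, 0.17, 0.28], [0.15, 0.67, 3.0], self.BASE,
            seed=42, n_sim=40,
        )
        assert best == (0.17, 0.67)
        assert len(surface) == 9
        assert surface["objective"].min() == surface.set_index(["delta_x", "alpha0"]).loc[best, "objective"]

    def test_single_point_grid(self):
        observed = {400.0: np.array([100.0, 120.0]), 800.0: np.array([110.0, 130.0])}
        best, surface = mc_landscape_search(observed, [0.2], [1.0], self.BASE, seed=1, n_sim=2)
        assert best == (0.2, 1.0) and len(surface) == 1

    def test_invalid_grids_rejected(self):
        observed = {400.0: np.array([100.0]), 800.0: np.array([110.0])}
        with pytest.raises(ConfigError):
            mc_landscape_search(observed, [], [1.0], self.BASE, seed=1)
        with pytest.raises(ConfigError):
            mc_landscape_search(observed, [0.2], [-1.0], self.BASE, seed=1)

    def test_needs_two_speeds(self):
        with pytest.raises(InsufficientDataError):
            mc_landscape_search({400.0: np.array([100.0])}, [0.2], [1.0], self.BASE, seed=1)
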