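"""Karplus forward model, ensemble averaging, chi-squared, and VCD."""

import math

import numpy as np
import pytest

from ramaibi import (
    AngleGrid,
    GaussianComponent,
    GaussianRamaModel,
    JCouplingObservation,
    KarplusParameters,
    OscillatorModelConfig,
    VCDProfile,
    average_coupling,
    chi2_j,
    chi2_vcd,
    coupling_uncertainty,
    ensemble_average,
    evaluate_model,
    histogram_from_angles,
    jcoupling_report,
    karplus_value,
    vcd_profile,
)
from ramaibi.observables import conformer_rotational_strengths, total_uncertainty

HNHA = KarplusParameters("3J(HN,HA)", A=7.09, B=-1.42, C=1.55, theta0=-60.0,
                         depends_on="phi", s_A=0.11, s_B=0.09, s_C=0.06)
ONEJ = KarplusParameters("1J(N,CA)", A=-0.98, B=1.70, C=9.51, theta0=0.0,
                         depends_on="psi")


def single_gaussian_dist(grid, center=(-65.0, 150.0), sigma=20.0):
    model = GaussianRamaModel(
        components=(GaussianComponent("pPII", 1.0, center, (sigma, sigma)),)
    )
    return evaluate_model(model, grid)


class TestKarplus:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (60.0, 7.09 - 1.42 + 1.55),      # theta + theta0 = 0, cos = 1
            (-120.0, 7.09 + 1.42 + 1.55),    # cos = -1
            (150.0, 1.55),                   # cos = 0
        ],
    )
    def test_extremal_angles(self, theta, expected):
        assert karplus_value(theta, HNHA) == pytest.approx(expected, abs=1e-12)

    def test_periodicity(self):
        t = np.linspace(-180, 180, 37)
        assert np.allclose(karplus_value(t, HNHA), karplus_value(t + 360.0, HNHA),
                           atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            karplus_value(float("nan"), HNHA)


class TestEnsembleAverage:
    def test_constant_observable(self, coarse_grid):
        d = single_gaussian_dist(coarse_grid)
        assert ensemble_average(d, lambda phi, psi: np.full_like(phi, 4.0)) == \
            pytest.approx(4.0, abs=1e-12)

    def test_delta_distribution_sifts(self, default_grid):
        d = histogram_from_angles([(-60.0, 150.0)], default_grid)
        i, j = default_grid.indices_of(-60.0, 150.0)
        phi_c = default_grid.centers_phi[i]
        got = average_coupling(d, HNHA)
        assert got == pytest.approx(karplus_value(phi_c, HNHA), abs=1e-12)

    def test_linearity_and_monotonicity(self, coarse_grid):
        d = single_gaussian_dist(coarse_grid)
        q1 = lambda phi, psi: np.cos(np.deg2rad(phi))
        q2 = lambda phi, psi: np.cos(np.deg2rad(phi)) + 0.5
        a1, a2 = ensemble_average(d, q1), ensemble_average(d, q2)
        assert a2 == pytest.approx(a1 + 0.5, abs=1e-12)
        assert a1 <= a2

    def test_non_finite_on_occupied_bin_rejected(self, coarse_grid):
        d = single_gaussian_dist(coarse_grid)
        with pytest.raises(ValueError, match="non-finite"):
            ensemble_average(d, lambda phi, psi: np.full_like(phi, np.nan))

    def test_matches_fine_grid_quadrature_oracle(self, default_grid):
        """2-deg ensemble average of a smooth periodic integrand agrees
        with independent 0.25-deg midpoint quadrature to 1e-4 Hz."""
        center, sigma = (-65.0, 150.0), 20.0
        d = single_gaussian_dist(default_grid, center, sigma)
        got = average_coupling(d, HNHA)

        x = np.arange(-180.0 + 0.125, 180.0, 0.25)
        dens = np.zeros_like(x)
        for shift in (-360.0, 0.0, 360.0):
            dens += np.exp(-0.5 * ((x - center[0] - shift) / sigma) ** 2)
        dens /= dens.sum()
        c = np.cos(np.deg2rad(x + HNHA.theta0))
        oracle = float(np.sum(dens * (HNHA.A * c * c + HNHA.B * c + HNHA.C)))
        assert got == pytest.approx(oracle, abs=1e-4)


class TestCouplingUncertainty:
    def test_zero_parameter_errors_reduce_to_s_j(self, coarse_grid):
        params = KarplusParameters("x", 1.0, 1.0, 1.0, 0.0, "phi",
                                   s_A=0.0, s_B=0.0, s_C=0.0)
        obs = JCouplingObservation("x", 5.0, 0.4)
        d = single_gaussian_dist(coarse_grid)
        assert coupling_uncertainty(d, params, obs) == pytest.approx(0.4, abs=1e-12)

    def test_delta_at_quarter_period(self, default_grid):
        # cos(theta + theta0) = 0 leaves only s_C and s_J in quadrature
        phi_c = -151.0  # a bin center; with theta0 = -60 gives cos(-211 deg)
        params = KarplusParameters("x", 2.0, 1.0, 0.5, -phi_c - 90.0, "phi",
                                   s_A=0.2, s_B=0.3, s_C=0.4)
        obs = JCouplingObservation("x", 5.0, 0.3)
        d = histogram_from_angles([(phi_c, 0.0)], default_grid)
        expected = math.sqrt(0.4**2 + 0.3**2)
        assert coupling_uncertainty(d, params, obs) == pytest.approx(expected, abs=1e-12)

    def test_missing_uncertainties_instruct_s_j(self, coarse_grid):
        d = single_gaussian_dist(coarse_grid)
        obs = JCouplingObservation("1J(N,CA)", 10.5, 0.5)
        with pytest.raises(ValueError, match="s_J alone"):
            coupling_uncertainty(d, ONEJ, obs)
        assert total_uncertainty(d, ONEJ, obs) == 0.5

    def test_never_below_experimental_error(self, coarse_grid):
        d = single_gaussian_dist(coarse_grid)
        obs = JCouplingObservation("3J(HN,HA)", 6.0, 0.25)
        assert coupling_uncertainty(d, HNHA, obs) >= 0.25

    def test_matches_fine_grid_quadrature_oracle(self, default_grid):
        center, sigma = (-65.0, 150.0), 20.0
        d = single_gaussian_dist(default_grid, center, sigma)
        obs = JCouplingObservation("3J(HN,HA)", 6.0, 0.3)
        got = coupling_uncertainty(d, HNHA, obs)
        x = np.arange(-180.0 + 0.125, 180.0, 0.25)
        dens = np.zeros_like(x)
        for shift in (-360.0, 0.0, 360.0):
            dens += np.exp(-0.5 * ((x - center[0] - shift) / sigma) ** 2)
        dens /= dens.sum()
        c = np.cos(np.deg2rad(x + HNHA.theta0))
        sbar = np.sqrt((HNHA.s_A * c * c) ** 2 + (HNHA.s_B * c) ** 2
                       + HNHA.s_C**2 + 0.3**2)
        assert got == pytest.approx(float(np.sum(dens * sbar)), abs=1e-6)


class TestChi2J:
    def test_perfect_agreement_is_zero(self):
        assert chi2_j([1.0, 2.0], [1.0, 2.0], [0.1, 0.2]) == 0.0

    def test_one_sigma_deviation_is_one(self):
        assert chi2_j([5.3], [5.0], [0.3]) == pytest.approx(1.0, abs=1e-12)

    def test_direct_summation_oracle(self):
        dev = [0.1, -0.2, 0.35, 0.0, -0.5]
        s = [0.2, 0.25, 0.3, 0.4, 0.5]
        exp = [6.0, 5.0, 4.0, 11.0, 2.0]
        calc = [e + d for e, d in zip(exp, dev)]
        oracle = sum((d / si) ** 2 for d, si in zip(dev, s)) / 5
        assert chi2_j(calc, exp, s) == pytest.approx(oracle, abs=1e-14)

    def test_permutation_invariance_and_scaling(self):
        rng = np.random.default_rng(2)
        calc, exp, s = rng.normal(5, 1, 8), rng.normal(5, 1, 8), rng.uniform(0.1, 0.5, 8)
        base = chi2_j(calc, exp, s)
        perm = rng.permutation(8)
        assert chi2_j(calc[perm], exp[perm], s[perm]) == pytest.approx(base, abs=1e-12)
        assert chi2_j(calc, exp, 2 * s) == pytest.approx(base / 4, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            chi2_j([], [], [])


class TestVCD:
    def test_single_conformer_couplet_is_conservative(self, default_grid):
        d = histogram_from_angles([(-60.0, 150.0)], default_grid)
        cfg = OscillatorModelConfig()
        nu_p, nu_m, r_p, r_m = conformer_rotational_strengths(-59.0, 151.0, cfg)
        assert abs(r_p + r_m) < 1e-12
        # integrated signal vanishes within convolution error
        prof = vcd_profile(d, cfg)
        integral = np.trapezoid(prof.delta_epsilon, prof.wavenumbers)
        scale = np.trapezoid(np.abs(prof.delta_epsilon), prof.wavenumbers)
        assert abs(integral) < 1e-6 * max(scale, 1e-30) + 1e-12

    def test_linearity_over_conformer_mixture(self, default_grid):
        cfg = OscillatorModelConfig()
        a = histogram_from_angles([(-60.0, 150.0)], default_grid)
        b = histogram_from_angles([(70.0, -40.0)], default_grid)
        mix = histogram_from_angles([(-60.0, 150.0)] * 3 + [(70.0, -40.0)],
                                    default_grid)
        expected = 0.75 * vcd_profile(a, cfg).delta_epsilon \
            + 0.25 * vcd_profile(b, cfg).delta_epsilon
        assert np.abs(vcd_profile(mix, cfg).delta_epsilon - expected).max() < 1e-12

    def test_degenerate_geometry_gives_zero_couplet(self, default_grid):
        # parallel dipoles: orientation angle 0 -> sin = 0 -> no signal
        d = histogram_from_angles([(-75.0, 75.0)], default_grid)  # phi+psi = 0
        prof = vcd_profile(d, OscillatorModelConfig())
        assert np.abs(prof.delta_epsilon).max() < 1e-14

    def test_inversion_symmetric_ensemble_is_silent(self, default_grid):
        from ramaibi.fixtures import GLYCINE_LIKE_COMPONENTS

        model = GaussianRamaModel(components=GLYCINE_LIKE_COMPONENTS)
        d = evaluate_model(model, default_grid)
        cfg = OscillatorModelConfig()
        prof = vcd_profile(d, cfg)
        # couplet-scale envelope: same model with unsigned strengths
        phi, psi = default_grid.mesh()
        occ = d.p > 0
        nu_p, nu_m, r_p, r_m = conformer_rotational_strengths(phi[occ], psi[occ], cfg)
        env = (d.p[occ] * np.abs(r_p)) @ np.exp(
            -0.5 * ((cfg.wavenumbers[None, :] - nu_p[:, None]) / cfg.half_width) ** 2
        )
        assert np.abs(prof.delta_epsilon).max() <= 1e-10 * env.max()


class TestChi2VCD:
    def test_identical_profiles_score_zero(self):
        nu = np.arange(1600.0, 1700.0, 5.0)
        de = np.sin(nu / 30.0)
        exp = VCDProfile(nu, de, s_k=np.full_like(nu, 0.01))
        calc = VCDProfile(nu, de.copy())
        assert chi2_vcd(calc, exp) == 0.0

    def test_single_point_one_sigma(self):
        exp = VCDProfile(np.array([1650.0]), np.array([0.2]), s_k=np.array([0.05]))
        calc = VCDProfile(np.array([1650.0]), np.array([0.25]))
        assert chi2_vcd(calc, exp) == pytest.approx(1.0, abs=1e-12)

    def test_ten_point_summation_oracle(self):
        rng = np.random.default_rng(4)
        nu = np.linspace(1600, 1690, 10)
        e, c = rng.normal(0, 0.1, 10), rng.normal(0, 0.1, 10)
        s = rng.uniform(0.01, 0.05, 10)
        oracle = float(np.mean(((c - e) / s) ** 2))
        assert chi2_vcd(VCDProfile(nu, c), VCDProfile(nu, e, s_k=s)) == \
            pytest.approx(oracle, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = VCDProfile(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        b = VCDProfile(np.array([1.0, 3.0]), np.array([0.0, 0.0]),
                       s_k=np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match="grid"):
            chi2_vcd(a, b)


def test_report_flags_unmatched_coupling_names(coarse_grid):
    d = single_gaussian_dist(coarse_grid)
    obs = [JCouplingObservation("3J(nope)", 5.0, 0.3)]
    with pytest.raises(ValueError, match="3J"):
        jcoupling_report(d, [HNHA], obs)


def test_report_aggregates_full_and_phi_subsets(coarse_grid):
    d = single_gaussian_dist(coarse_grid)
    obs = [JCouplingObservation("3J(HN,HA)", 6.0, 0.3),
           JCouplingObservation("1J(N,CA)", 10.8, 0.5)]
    rep = jcoupling_report(d, [HNHA, ONEJ], obs)
    assert set(rep.table.coupling_name) == {"3J(HN,HA)", "1J(N,CA)"}
    assert rep.chi2_j >= 0
    # phi subset excludes the psi-dependent 1J coupling
    row = rep.table[rep.table.coupling_name == "3J(HN,HA)"].iloc[0]
    assert rep.chi2_jphi == pytest.approx(
        ((row.J_calc - row.J_exp) / row.s_i) ** 2, abs=1e-12
    )
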