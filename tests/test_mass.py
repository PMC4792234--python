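"""SEC calibration, Guinier analysis, Vc and I(0)-ratio mass estimators."""

import numpy as np
import pytest

from micalkin import (
    ScatteringProfile,
    SECCalibration,
    coordinate_rg,
    correlation_volume,
    guinier_fit,
    mass_from_i0_ratio,
    mass_from_vc,
    percent_mass_deviation,
    sec_predict_mass,
    toy_profile,
    uniform_ball,
)
from micalkin.mass import GuinierError

SPHERE_RG_30 = np.sqrt(3.0 / 5.0) * 30.0  # 23.2379 Å


def gaussian_profile(i0=7.0, rg=30.0, qmax=0.3, n=300):
    q = np.linspace(1e-3, qmax, n)
    return ScatteringProfile(q=q, intensity=i0 * np.exp(-(q**2) * rg**2 / 3.0))


def sphere_form_factor(radius=30.0, qmax=0.12, n=400):
    q = np.linspace(1e-3, qmax, n)
    x = q * radius
    f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return ScatteringProfile(q=q, intensity=f**2)


class TestSECCalibration:
    def test_exact_log_line_recovers_standards(self):
        """Standards sitting exactly on a log-line predict themselves."""
        vo = 8.0
        slope, intercept = -2.0, 7.0
        ves = np.array([10.0, 12.0, 14.0, 16.0, 18.0])
        masses = 10.0 ** (intercept + slope * ves / vo)
        cal = SECCalibration(standards=tuple(zip(ves, masses)), void_volume=vo)
        assert cal.slope == pytest.approx(slope, rel=1e-10)
        for ve, m in zip(ves, masses):
            assert cal.predict_mass(ve).mass == pytest.approx(m, rel=1e-9)

    def test_zero_slope_constant_prediction(self):
        cal = SECCalibration(standards=((10.0, 5e4), (14.0, 5e4)), void_volume=8.0)
        assert cal.slope == pytest.approx(0.0, abs=1e-12)
        assert cal.predict_mass(12.0).mass == pytest.approx(5e4, rel=1e-9)

    def test_noisy_standards_within_5pct(self):
        """1% Ve noise on a 5-standard set: prediction within 5% of truth.

        Cross-checked against a closed-form least-squares line computed
        directly from the normal equations.
        """
        rng = np.random.default_rng(17)
        vo, slope, intercept = 8.0, -2.5, 8.0
        ves_true = np.linspace(10, 18, 5)
        masses = 10.0 ** (intercept + slope * ves_true / vo)
        ves = ves_true * (1 + 0.01 * rng.standard_normal(5))
        cal = SECCalibration(standards=tuple(zip(ves, masses)), void_volume=vo)
        # closed-form regression oracle
        x = ves / vo
        y = np.log10(masses)
        sl = (np.mean(x * y) - x.mean() * y.mean()) / (np.mean(x**2) - x.mean() ** 2)
        ic = y.mean() - sl * x.mean()
        assert cal.slope == pytest.approx(sl, rel=1e-10)
        assert cal.intercept == pytest.approx(ic, rel=1e-10)
        ve_query = 13.0
        m_true = 10.0 ** (intercept + slope * ve_query / vo)
        assert cal.predict_mass(ve_query).mass == pytest.approx(m_true, rel=0.05)

    def test_extrapolation_warns(self):
        cal = SECCalibration(standards=((10.0, 1e5), (12.0, 1e4)), void_volume=8.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            sec_predict_mass(cal, 20.0)

    def test_file_io_and_validation(self, tmp_path):
        path = tmp_path / "standards.txt"
        path.write_text("# Ve_mL mass_Da\n10.0 669000\n12.0 158000\n14.0 44000\n")
        cal = SECCalibration.from_file(path, void_volume=8.0)
        assert len(cal.standards) == 3
        with pytest.raises(ValueError):
            SECCalibration(standards=((10.0, 1e5),), void_volume=8.0)
        with pytest.raises(ValueError):
            SECCalibration(standards=((10.0, 1e5), (12.0, 1e4)), void_volume=0.0)


class TestGuinier:
    def test_exact_gaussian(self):
        """A pure Guinier profile returns I0 and Rg to 1e-6."""
        g = guinier_fit(gaussian_profile())
        assert g.i0 == pytest.approx(7.0, rel=1e-6)
        assert g.rg == pytest.approx(30.0, rel=1e-6)
        assert g.r_squared > 0.999999

    def test_sphere_form_factor_rg(self):
        """Uniform sphere of R=30 Å: Rg within 2% of sqrt(3/5)*30."""
        g = guinier_fit(sphere_form_factor())
        assert g.rg == pytest.approx(SPHERE_RG_30, rel=0.02)
        assert max(g.q_max * g.rg, 0) <= 1.3 + 1e-9

    def test_flat_profile_raises(self):
        q = np.linspace(1e-3, 0.3, 100)
        prof = ScatteringProfile(q=q, intensity=np.ones_like(q))
        with pytest.raises(GuinierError, match="decay"):
            guinier_fit(prof)

    def test_too_few_points_raises(self):
        q = np.linspace(1e-3, 0.3, 4)
        prof = ScatteringProfile(q=q, intensity=np.exp(-q**2))
        with pytest.raises(GuinierError):
            guinier_fit(prof)


class TestCorrelationVolume:
    def test_scale_invariance(self):
        prof = gaussian_profile()
        g = guinier_fit(prof)
        vc1 = correlation_volume(prof, i0=g.i0, rg=g.rg)
        scaled = prof.scaled(37.0)
        gs = guinier_fit(scaled)
        vc2 = correlation_volume(scaled, i0=gs.i0, rg=gs.rg)
        assert vc2 == pytest.approx(vc1, rel=1e-9)

    def test_gaussian_closed_form(self):
        """∫q·I dq for a Gaussian has a closed form; Vc matches to 0.5%."""
        i0, rg = 7.0, 30.0
        prof = gaussian_profile(i0, rg, qmax=0.3, n=2000)
        qu = 0.3
        integral = (3.0 * i0 / (2.0 * rg**2)) * (1.0 - np.exp(-(qu**2) * rg**2 / 3.0))
        vc = correlation_volume(prof, i0=i0, rg=rg, q_upper=qu)
        assert vc == pytest.approx(i0 / integral, rel=0.005)

    def test_grid_refinement_converges(self):
        i0, rg = 5.0, 25.0
        coarse = correlation_volume(gaussian_profile(i0, rg, n=500), i0=i0, rg=rg)
        fine = correlation_volume(gaussian_profile(i0, rg, n=1000), i0=i0, rg=rg)
        assert abs(fine - coarse) / fine < 1e-3

    def test_q_upper_beyond_range_raises(self):
        prof = gaussian_profile()
        with pytest.raises(ValueError, match="q_upper"):
            correlation_volume(prof, i0=7.0, rg=30.0, q_upper=1.0)


class TestMassEstimators:
    def test_mass_from_vc_arithmetic(self):
        est = mass_from_vc(250.0, 31.0)
        assert est.mass == pytest.approx((250.0**2 / 31.0) / 1.231, rel=1e-12)
        assert mass_from_vc(500.0, 31.0).mass == pytest.approx(4 * est.mass, rel=1e-12)
        assert mass_from_vc(250.0, 1e9).mass < 1e-3
        with pytest.raises(ValueError):
            mass_from_vc(-1.0, 31.0)

    def test_i0_ratio_identity_and_scaling(self):
        assert mass_from_i0_ratio(10, 2, 10, 2, 132000).mass == pytest.approx(132000)
        assert mass_from_i0_ratio(5, 2, 10, 2, 132000).mass == pytest.approx(66000)
        with pytest.raises(ValueError):
            mass_from_i0_ratio(10, 0, 10, 2, 132000)

    def test_i0_ratio_forward_simulation(self):
        """Ideal I0 ∝ mass·conc recovers a 68425 Da particle exactly."""
        k = 3.7e-3  # arbitrary instrument constant
        mass_s, conc_s = 132000.0, 4.0
        mass_x, conc_x = 68425.0, 7.0
        est = mass_from_i0_ratio(k * mass_x * conc_x, conc_x,
                                 k * mass_s * conc_s, conc_s, mass_s)
        assert est.mass == pytest.approx(mass_x, rel=1e-12)

    def test_percent_deviation_published_rows(self):
        from micalkin.kinetics import round_half_away

        assert round_half_away(percent_mass_deviation(61455, 68425), 1) == -10.2
        assert round_half_away(percent_mass_deviation(55000, 68425), 1) == -19.6
        assert percent_mass_deviation(68425, 68425) == 0.0
        with pytest.raises(ValueError):
            percent_mass_deviation(1.0, 0.0)


class TestToyProfile:
    def test_single_point(self):
        q = np.linspace(0.01, 0.3, 50)
        prof = toy_profile(np.array([[1.0, 2.0, 3.0]]), q)
        assert np.allclose(prof.intensity, 1.0)
        assert coordinate_rg(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_closed_form(self):
        """I(q) = 2(1 + sin(qd)/(qd)) for two unit points; Rg = d/2."""
        d = 20.0
        pts = np.array([[0, 0, 0], [0, 0, d]], dtype=float)
        q = np.linspace(0.01, 0.5, 100)
        prof = toy_profile(pts, q, bin_width=0.001)
        expected = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        assert np.allclose(prof.intensity, expected, rtol=1e-4)
        assert coordinate_rg(pts) == pytest.approx(d / 2.0, rel=1e-12)

    def test_uniform_ball_rg_and_guinier(self):
        """1e4-point ball of R=30: coordinate Rg within 1% of 23.24 Å and
        Guinier Rg of its Debye profile within 2% of the coordinate value."""
        pts = uniform_ball(10_000, 30.0, seed=123)
        rg_coord = coordinate_rg(pts)
        assert rg_coord == pytest.approx(SPHERE_RG_30, rel=0.01)
        q = np.linspace(5e-3, 0.1, 60)
        prof = toy_profile(pts, q)
        g = guinier_fit(prof)
        assert g.rg == pytest.approx(rg_coord, rel=0.02)
        assert g.i0 == pytest.approx(1e8, rel=0.02)  # N² forward scattering

    def test_round_trip_random_clouds(self):
        """Guinier Rg tracks coordinate Rg within 3% for random blobs."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            pts = rng.standard_normal((800, 3)) * rng.uniform(5, 15)
            rg_c = coordinate_rg(pts)
            q = np.linspace(0.2 / rg_c / 10, 1.2 / rg_c, 80)
            g = guinier_fit(toy_profile(pts, q, bin_width=0.1))
            assert g.rg == pytest.approx(rg_c, rel=0.03)

    def test_empty_points_raises(self):
        with pytest.raises(ValueError):
            toy_profile(np.empty((0, 3)), np.array([0.1]))
        with pytest.raises(ValueError):
            coordinate_rg(np.empty((0, 3)))


class TestProfileIO:
    def test_text_roundtrip(self, tmp_path):
        prof = gaussian_profile(n=50)
        prof.sigma = 0.01 * prof.intensity
        path = tmp_path / "profile.dat"
        prof.to_text(path)
        back = ScatteringProfile.from_text(path, concentration=4.0)
        assert np.allclose(back.q, prof.q)
        assert np.allclose(back.intensity, prof.intensity)
        assert np.allclose(back.sigma, prof.sigma)
        assert back.concentration == 4.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ScatteringProfile(q=np.array([0.0, 0.1]), intensity=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ScatteringProfile(q=np.array([0.2, 0.1]), intensity=np.array([1.0, 1.0]))
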