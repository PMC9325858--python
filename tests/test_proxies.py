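"""Proxy chain: Mg/Ca thermometry, seawater d18O, density, salinity, errors."""

import numpy as np
import pytest

from coralmound import eos80
from coralmound.proxies import (
    GLOBAL_DENSITY,
    REGIONAL_DENSITY,
    ForamSample,
    MgCaCalibration,
    PaleotempEquation,
    SalinityRegression,
    bwt_from_mgca,
    d18osw_from_calcite,
    density_from_d18oc,
    propagate_uncertainty,
    reconstruct_downcore,
    salinity_from_d18osw,
    salinity_route_eos,
    screen_contamination,
)


class TestBwtFromMgca:
    def test_preexponential_maps_to_zero(self):
        assert bwt_from_mgca(1.24) == pytest.approx(0.0)

    def test_core_average_value(self):
        # ln(2.7/1.24)/0.069
        assert bwt_from_mgca(2.7) == pytest.approx(11.28, abs=0.01)

    def test_round_trip_exact(self):
        cal = MgCaCalibration()
        for t in (0.0, 5.5, 12.0):
            assert bwt_from_mgca(cal.a * np.exp(cal.b * t), cal) == pytest.approx(t)

    def test_strictly_increasing(self):
        mg = np.linspace(1.0, 3.5, 50)
        t = bwt_from_mgca(mg)
        assert np.all(np.diff(t) > 0)

    def test_nonpositive_mgca_rejected(self):
        with pytest.raises(ValueError):
            bwt_from_mgca(0.0)


class TestD18oswFromCalcite:
    def test_study_average_point(self):
        # downcore-average inputs give about -0.55 permil seawater d18O
        assert d18osw_from_calcite(0.4, 10.1) == pytest.approx(-0.55, abs=0.01)

    def test_constructed_zero(self):
        eq = PaleotempEquation()
        t = 8.0
        d18o_c = eq.k0 + eq.k1 * t + eq.k2 * t**2 - eq.scale_offset
        assert d18osw_from_calcite(d18o_c, t) == pytest.approx(0.0, abs=1e-12)

    def test_temperature_sensitivity(self):
        # d(d18O_SW)/dT = -(k1 + 2 k2 T) = +0.223 permil/degC at T = 10
        h = 1e-6
        sens = (d18osw_from_calcite(0.4, 10 + h) - d18osw_from_calcite(0.4, 10 - h)) / (2 * h)
        assert sens == pytest.approx(0.223, abs=1e-3)


class TestSalinityFromD18osw:
    def test_printed_endpoints(self):
        assert salinity_from_d18osw(0.63) == pytest.approx(36.43, abs=0.01)
        assert salinity_from_d18osw(-1.55) == pytest.approx(27.87, abs=0.01)

    def test_intercept_maps_to_zero(self):
        assert salinity_from_d18osw(-8.6493) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing(self):
        d = np.linspace(-2, 1, 20)
        assert np.all(np.diff(salinity_from_d18osw(d)) > 0)


class TestDensityFromD18oc:
    def test_regional_intercept_and_unit_point(self):
        assert density_from_d18oc(0.0) == pytest.approx(25.64)
        assert density_from_d18oc(1.0) == pytest.approx(27.28)

    def test_global_intercept(self):
        assert density_from_d18oc(0.0, GLOBAL_DENSITY) == pytest.approx(25.7)

    def test_increasing_over_observed_range(self):
        # vertex of the regional quadratic sits at -3.4 permil, far outside
        # the observed -0.3 .. 1.6 permil, so the relation is monotone there
        d = np.linspace(-0.3, 1.6, 40)
        assert np.all(np.diff(density_from_d18oc(d)) > 0)


class TestSalinityRouteEos:
    def test_round_trip(self):
        target = eos80.sigma_theta(35, 8, 100)
        assert salinity_route_eos(8, target, 100) == pytest.approx(35.0, abs=1e-5)

    def test_check_value(self):
        assert salinity_route_eos(5, 27.67547, 0) == pytest.approx(35.0, abs=1e-4)

    def test_unattainable_density_raises(self):
        with pytest.raises(eos80.DensityUnattainableError):
            salinity_route_eos(5, -1.0, 0)


class TestContaminationScreen:
    def test_independent_noise_passes(self):
        rng = np.random.default_rng(10)
        samples = [
            ForamSample(depth=i, mgca=m, d18o_c=0.4, alca=a, feca=f)
            for i, (m, a, f) in enumerate(zip(
                rng.uniform(2.3, 3.3, 50), rng.normal(0.3, 0.05, 50),
                rng.normal(4.0, 0.5, 50)))
        ]
        report = screen_contamination(samples)
        assert report["pass"]
        assert report["r2"]["feca"] < 0.4

    def test_proportional_feca_fails(self):
        samples = [
            ForamSample(depth=i, mgca=m, d18o_c=0.4, alca=0.3, feca=2 * m)
            for i, m in enumerate(np.linspace(2.0, 3.0, 10))
        ]
        report = screen_contamination(samples)
        assert report["r2"]["feca"] == pytest.approx(1.0)
        assert not report["pass"]

    def test_constant_feca_passes(self):
        samples = [
            ForamSample(depth=i, mgca=m, d18o_c=0.4, alca=0.3, feca=4.0)
            for i, m in enumerate(np.linspace(2.0, 3.0, 10))
        ]
        report = screen_contamination(samples)
        assert report["r2"]["feca"] == 0.0
        assert report["pass"]

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            screen_contamination([ForamSample(depth=0, mgca=2.7, d18o_c=0.4)])


class TestPropagateUncertainty:
    def test_bwt_2sd_matches_stated_value(self):
        s = ForamSample(depth=0, mgca=2.7, d18o_c=0.4)
        for method in ("delta", "mc"):
            sd2 = propagate_uncertainty(s, method=method, seed=4)
            assert sd2["bwt"] == pytest.approx(1.1, abs=0.1)

    def test_zero_input_sds_give_zero_output_sds(self):
        s = ForamSample(depth=0, mgca=2.7, d18o_c=0.4,
                        sd2_mgca=1e-15, sd2_d18o=1e-15)
        cal = MgCaCalibration(sd2_a=1e-15, sd2_b=1e-15)
        from dataclasses import replace
        dc = replace(REGIONAL_DENSITY, sd2_c0=0.0, sd2_c1=0.0, sd2_c2=0.0)
        sd2 = propagate_uncertainty(s, calibration=cal, density_calibration=dc)
        for key, v in sd2.items():
            assert v == pytest.approx(0.0, abs=1e-10), key

    def test_delta_method_linearity_in_input_sds(self):
        s1 = ForamSample(depth=0, mgca=2.7, d18o_c=0.4)
        s2 = ForamSample(depth=0, mgca=2.7, d18o_c=0.4,
                         sd2_mgca=0.2, sd2_d18o=0.12)
        cal2 = MgCaCalibration(sd2_a=0.08, sd2_b=0.01)
        from dataclasses import replace
        dc2 = replace(REGIONAL_DENSITY, sd2_c0=0.52, sd2_c1=0.06, sd2_c2=0.04)
        a = propagate_uncertainty(s1, method="delta")
        b = propagate_uncertainty(s2, calibration=cal2, density_calibration=dc2,
                                  method="delta")
        for key in ("bwt", "d18o_sw", "sigma_theta_regional", "sal_route_a"):
            assert b[key] / a[key] == pytest.approx(2.0, rel=1e-9)

    def test_delta_and_mc_agree(self):
        s = ForamSample(depth=0, mgca=2.7, d18o_c=0.4)
        delta = propagate_uncertainty(s, method="delta")
        mc = propagate_uncertainty(s, method="mc", n=20000, seed=5)
        for key in delta:
            assert mc[key] == pytest.approx(delta[key], rel=0.10), key

    def test_small_mc_n_rejected(self):
        s = ForamSample(depth=0, mgca=2.7, d18o_c=0.4)
        with pytest.raises(ValueError):
            propagate_uncertainty(s, method="mc", n=50)


class TestReconstructDowncore:
    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            reconstruct_downcore([])

    def test_noise_free_single_sample_exact_chain(self):
        cal = MgCaCalibration()
        eq = PaleotempEquation()
        reg = SalinityRegression()
        t_true, s_true = 8.3, 35.0
        d18o_sw = reg.slope * s_true + reg.intercept
        d18o_c = (d18o_sw - eq.scale_offset) + eq.k0 + eq.k1 * t_true + eq.k2 * t_true**2
        mgca = cal.a * np.exp(cal.b * t_true)
        sample = ForamSample(depth=0, mgca=mgca, d18o_c=d18o_c)
        row = reconstruct_downcore([sample])[0]
        assert row.bwt == pytest.approx(t_true, abs=1e-12)
        assert row.d18o_sw == pytest.approx(d18o_sw, abs=1e-12)
        assert row.sal_route_a == pytest.approx(s_true, abs=1e-9)
        assert row.sigma_theta_regional == pytest.approx(
            density_from_d18oc(d18o_c))

    def test_flags_below_calibration_range(self):
        row = reconstruct_downcore([ForamSample(depth=0, mgca=1.0, d18o_c=0.4)])[0]
        assert "below_calibration_range" in row.qc_flags

    def test_batch_never_aborts_on_unattainable_density(self):
        # very negative d18O_C -> density below fresh water, route B missing
        rows = reconstruct_downcore([
            ForamSample(depth=0, mgca=2.7, d18o_c=-15.0),
            ForamSample(depth=1, mgca=2.7, d18o_c=0.4),
        ])
        assert rows[0].sal_route_b is None
        assert "density_unattainable" in rows[0].qc_flags
        assert rows[1].sal_route_b is not None
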