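"""Tests for kinetics, polarization accounting, geometry and statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phipkit as pk


class TestHydrogenationKinetics:
    def test_zero_bubbling_time_gives_zero(self):
        p = pk.KineticsParams(pc0=50, p0=0.3, r=0.2, k1=0.5, tb=0.0)
        assert pk.hydrogenated_concentration(p) == 0.0

    def test_slow_decay_limit_is_saturating_growth(self):
        # r -> 0: [PC_H] -> pc0·p0·(1 - e^{-k1·tb})
        p = pk.KineticsParams(pc0=50, p0=0.3, r=1e-9, k1=0.5, tb=4.0)
        expected = 50 * 0.3 * (1 - math.exp(-0.5 * 4.0))
        assert pk.hydrogenated_concentration(p) == pytest.approx(expected,
                                                                 rel=1e-6)

    def test_maximum_at_analytic_bubbling_time(self):
        r, k1 = 0.12, 0.55
        tb_star = pk.optimal_bubbling_time(r, k1)
        assert tb_star == pytest.approx(math.log(k1 / r) / (k1 - r))
        f = lambda tb: pk.hydrogenated_concentration(
            pk.KineticsParams(pc0=50, p0=0.3, r=r, k1=k1, tb=tb))
        eps = 1e-5
        assert f(tb_star) >= f(tb_star - eps)
        assert f(tb_star) >= f(tb_star + eps)

    def test_continuous_across_equal_rates(self):
        # the closed form approaches the analytic r = k1 limit linearly in
        # |r - k1|, with no jump at the branch switch
        k1, tb = 0.5, 4.0
        exact = pk.hydrogenated_concentration(
            pk.KineticsParams(pc0=50, p0=0.3, r=k1, k1=k1, tb=tb))
        assert exact == pytest.approx(50 * 0.3 * k1 * tb * math.exp(-k1 * tb),
                                      rel=1e-12)
        for delta, tol in ((1e-5, 2e-5), (1e-8, 1e-6)):
            near = pk.hydrogenated_concentration(
                pk.KineticsParams(pc0=50, p0=0.3, r=k1 * (1 - delta),
                                  k1=k1, tb=tb))
            assert near == pytest.approx(exact, rel=tol)


class TestThermalPolarization:
    def test_high_field_spectrometer_value(self):
        # 9.4 T, 300 K: the canonical ~3.2e-5 thermal 1H polarization
        assert pk.thermal_polarization(9.4, 300.0) == pytest.approx(3.2e-5,
                                                                    rel=0.01)

    def test_zero_field_gives_zero(self):
        assert pk.thermal_polarization(0.0, 300.0) == 0.0

    def test_polarizer_field_value(self):
        # scales linearly in B at these fields: 3.2e-5 · 0.4454/9.4
        expected = 3.201e-5 * 0.4454 / 9.4
        assert pk.thermal_polarization(0.4454, 300.0) == pytest.approx(
            expected, rel=1e-3)


class TestMaxPolarization:
    def test_ideal_case_is_fifty_percent(self):
        assert pk.max_polarization(1.0) == pytest.approx(0.50)

    def test_enrichment_92_percent(self):
        # 0.5·(4·0.92-1)/3 = 44.67%, the printed 44.6% up to rounding
        assert pk.max_polarization(0.92) * 100 == pytest.approx(44.67,
                                                                abs=0.01)

    def test_thermal_mixture_gives_zero(self):
        assert pk.max_polarization(0.25) == 0.0

    def test_affine_in_f_and_bounds(self):
        f = np.linspace(0.25, 1.0, 7)
        vals = np.array([pk.max_polarization(x) for x in f])
        assert np.allclose(np.diff(vals, 2), 0.0, atol=1e-15)
        with pytest.raises(ValueError):
            pk.max_polarization(0.2)


class TestQuantifyPolarization:
    def test_molar_polarization_headline_numbers(self):
        # P = 31.3% on 2 protons at 50 mM -> 31.3 mM molar polarization
        p_th = pk.thermal_polarization(0.4454, 300.0)
        q = pk.quantify_polarization(s_hyp=0.313 / p_th, s_th=1.0,
                                     correction=1.0, p_thermal=p_th,
                                     conc=50.0, n_protons=2)
        assert q.p == pytest.approx(0.313)
        assert q.molar_polarization == pytest.approx(31.3)
        # fraction of the enrichment ceiling at f = 0.92 is 70%
        assert round(q.p / pk.max_polarization(0.92) * 100) == 70

    def test_thermal_signal_recovers_thermal_polarization(self):
        p_th = 1.5e-6
        q = pk.quantify_polarization(1.0, 1.0, 1.0, p_th, conc=50.0)
        assert q.p == p_th
        assert q.enhancement == pytest.approx(1.0)

    def test_zero_thermal_reference_rejected(self):
        with pytest.raises(ValueError):
            pk.quantify_polarization(1.0, 0.0, 1.0, 1e-6, 50.0)

    def test_molar_polarization_sequence_invariance(self):
        # doubling P while halving the polarized proton count leaves the
        # molar polarization unchanged
        p_th = pk.thermal_polarization(0.4454, 300.0)
        q2 = pk.quantify_polarization(0.313 / p_th, 1.0, 1.0, p_th, 50.0, 2)
        q1 = pk.quantify_polarization(2 * 0.313 / p_th, 1.0, 1.0, p_th, 50.0, 1)
        assert q1.molar_polarization == pytest.approx(q2.molar_polarization)

    def test_linear_in_hyperpolarized_signal(self):
        p_th = 1e-6
        qa = pk.quantify_polarization(100.0, 1.0, 0.8, p_th, 50.0)
        qb = pk.quantify_polarization(200.0, 1.0, 0.8, p_th, 50.0)
        assert qb.p == pytest.approx(2 * qa.p)


class TestReactorVolume:
    def test_16mm_reactor_fill_volume(self):
        # ID 12.5 mm filled to 20 mm, hemispherical bottom: 2.199 mL,
        # matching the measured 2.215 mL within 1%
        vol = pk.reactor_volume(pk.ReactorGeometry(12.5, 20.0))
        assert vol == pytest.approx(2.199, abs=5e-4)
        assert vol == pytest.approx(2.215, rel=0.01)

    def test_5mm_tube_fill_volume(self):
        # ID 4.2 mm: 0.267 mL vs measured 0.265 mL
        vol = pk.reactor_volume(pk.ReactorGeometry(4.2, 20.0))
        assert vol == pytest.approx(0.267, abs=5e-4)
        assert vol == pytest.approx(0.265, rel=0.02)

    def test_flat_bottom_is_cylinder(self):
        vol = pk.reactor_volume(pk.ReactorGeometry(12.5, 20.0, bottom="flat"))
        assert vol == pytest.approx(math.pi * 6.25 ** 2 * 20.0 / 1000.0)

    def test_hemisphere_deficit_is_third_pi_r_cubed(self):
        flat = pk.reactor_volume(pk.ReactorGeometry(9.1, 25.0, bottom="flat"))
        hemi = pk.reactor_volume(pk.ReactorGeometry(9.1, 25.0))
        assert flat - hemi == pytest.approx(math.pi * 4.55 ** 3 / 3 / 1000.0)

    def test_fill_below_apex_rejected(self):
        with pytest.raises(ValueError):
            pk.ReactorGeometry(12.5, 5.0, bottom="hemispherical")


class TestCoefficientOfVariation:
    def test_constant_series_gives_zero(self):
        assert pk.coefficient_of_variation([4.2] * 10) == pytest.approx(
            0.0, abs=1e-12)

    def test_simple_worked_example(self):
        assert pk.coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_recovers_generator_cv(self):
        # injection generator at CV 0.63%: mean recovered CV within 20%
        cvs = []
        for seed in range(100):
            df = pk.gen_injection_series(mean=1.0, cv=0.0063, n=30,
                                         n_series=1, seed=seed)
            cvs.append(pk.coefficient_of_variation(df["integral"]))
        assert np.mean(cvs) == pytest.approx(0.0063, rel=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pk.coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            pk.coefficient_of_variation([-1.0, 1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(0.1, 10))
    def test_scale_invariance(self, mean, scale):
        vals = np.array([0.9, 1.0, 1.1, 1.05]) * mean
        a = pk.coefficient_of_variation(vals)
        b = pk.coefficient_of_variation(vals * scale)
        assert a == pytest.approx(b, rel=1e-9)
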