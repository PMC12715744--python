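"""Unit and property tests for the density-matrix engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import phipkit as pk
from phipkit.spin_core import signal_integral, single_spin_op

from conftest import rho_deviation


class TestBuildSpinSystem:
    def test_ea_d6_model_is_valid(self):
        sys2 = pk.build_spin_system([1.26, 4.12], [[0, 7.1], [7.1, 0]],
                                    b0=0.4454, ref_freq=18.717e6)
        assert sys2.dim == 4
        assert sys2.spins[0].shift == 1.26

    def test_single_spin_at_reference_has_zero_hamiltonian(self):
        sys1 = pk.build_spin_system([0.0], [[0.0]], b0=0.4454, ref_freq=18.717e6)
        assert np.allclose(sys1.hamiltonian, 0.0)

    @pytest.mark.parametrize("bad", [
        dict(j=[[0, 7.1], [6.0, 0]]),              # asymmetric
        dict(j=[[1.0, 7.1], [7.1, 0]]),            # nonzero diagonal
        dict(b0=-1.0),
        dict(ref_freq=0.0),
    ])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(shifts=[1.26, 4.12], j=[[0, 7.1], [7.1, 0]],
                      b0=0.4454, ref_freq=18.717e6)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            pk.build_spin_system(**kwargs)

    def test_hamiltonian_shift_term(self):
        # one spin at 4.12 ppm: H = 2π·δ·f_ref·1e-6·Iz
        sys1 = pk.build_spin_system([4.12], [[0.0]], 0.4454, 18.717e6)
        w = 2 * math.pi * 4.12e-6 * 18.717e6
        assert np.allclose(sys1.hamiltonian, w * single_spin_op(1, 0, "z"))


class TestPasadenaState:
    def test_thermal_para_fraction_gives_maximally_mixed(self):
        sysd = pk.ea_d6_system()
        st = pk.pasadena_state(sysd, enrichment=0.25)
        assert np.allclose(st.rho, np.eye(4) / 4)
        cfg = pk.preset_ope_config("EA-d6", tau=0.01)
        assert pk.run_ope(st, cfg) == pytest.approx(0.0, abs=1e-14)

    def test_pure_para_full_singlet_is_projector(self):
        sysd = pk.ea_d6_system()
        st = pk.pasadena_state(sysd, enrichment=1.0, dephased=False)
        evals = np.sort(np.linalg.eigvalsh(st.rho))
        assert np.allclose(evals, [0, 0, 0, 1], atol=1e-12)

    def test_enrichment_scaling(self):
        # deviation amplitude at f = 0.92 is (4·0.92-1)/3 of the f = 1 case
        s = pk.EnrichmentScale(0.92).s
        assert s == pytest.approx((4 * 0.92 - 1) / 3)
        sysd = pk.ea_d6_system()
        d1 = pk.pasadena_state(sysd, enrichment=1.0).rho - np.eye(4) / 4
        d92 = pk.pasadena_state(sysd, enrichment=0.92).rho - np.eye(4) / 4
        assert np.allclose(d92, s * d1, atol=1e-14)

    def test_equal_pair_indices_rejected(self):
        with pytest.raises(ValueError):
            pk.pasadena_state(pk.ea_d6_system(), pair=(1, 1))

    def test_extra_spins_unpolarized(self):
        sysh = pk.ea_h6_system()
        st = pk.pasadena_state(sysh, pair=(0, 3))
        # partial trace over the pair leaves the maximally mixed state:
        # total Iz expectation on spectator spins is zero
        for i in (1, 2, 4):
            assert abs(st.expect(sysh.op(i, "z"))) < 1e-14


class TestPulsesAndDelays:
    def test_90x_moves_iz_to_transverse_norm_preserved(self, single_spin):
        st = rho_deviation(single_spin, single_spin.op(0, "z"))
        out = pk.apply_pulse(st, 90, 0)
        assert abs(out.expect(single_spin.op(0, "z"))) < 1e-14
        assert out.expect(single_spin.op(0, "y")).real == pytest.approx(-0.5)

    def test_double_180_is_identity(self, two_spin_weak):
        st = pk.pasadena_state(two_spin_weak, dephased=False)
        out = pk.apply_pulse(pk.apply_pulse(st, 180, 37.0), 180, 37.0)
        assert np.allclose(out.rho, st.rho, atol=1e-12)

    def test_composite_90x180y90x_inverts_iz(self, single_spin):
        # brute-force oracle: multiply the three rotation generators
        u = np.eye(2, dtype=complex)
        for flip, phase in ((90, 0), (180, 90), (90, 0)):
            beta, phi = math.radians(flip), math.radians(phase)
            gen = math.cos(phi) * single_spin_op(1, 0, "x") + \
                math.sin(phi) * single_spin_op(1, 0, "y")
            u = expm(-1j * beta * gen) @ u
        iz = single_spin_op(1, 0, "z")
        assert np.allclose(u @ iz @ u.conj().T, -iz, atol=1e-12)
        # package path agrees
        st = rho_deviation(single_spin, iz)
        for flip, phase in ((90, 0), (180, 90), (90, 0)):
            st = pk.apply_pulse(st, flip, phase)
        assert st.expect(iz).real == pytest.approx(-0.5, abs=1e-12)

    def test_zero_delay_is_identity(self, two_spin_weak):
        st = pk.pasadena_state(two_spin_weak)
        assert np.allclose(pk.evolve_delay(st, 0.0).rho, st.rho)

    def test_negative_delay_rejected(self, two_spin_weak):
        with pytest.raises(ValueError):
            pk.evolve_delay(pk.pasadena_state(two_spin_weak), -1e-3)

    def test_antiphase_to_inphase_at_half_j_period(self, two_spin_weak):
        # product-operator closed form: 2I1xI2z --J--> I1y at t = 1/(2J)
        op = 2 * two_spin_weak.op(0, "x") @ two_spin_weak.op(1, "z")
        st = rho_deviation(two_spin_weak, op)
        out = pk.evolve_delay(st, 1.0 / (2 * 7.1))
        i1y = two_spin_weak.op(0, "y")
        # Tr(I1y·I1y) = 1 in the 4-dim space, so a unit I1y coefficient
        # appears as expectation 1
        assert out.expect(i1y).real == pytest.approx(1.0, abs=1e-10)
        assert abs(out.expect(op)) < 1e-10

    def test_offset_rotation_half_cycle(self):
        # 100 Hz offset for 5 ms = half a cycle: Ix -> -Ix
        ref = 1e6
        sys1 = pk.build_spin_system([100.0 / ref * 1e6], [[0.0]], 0.4454, ref)
        ix = sys1.op(0, "x")
        st = rho_deviation(sys1, ix)
        out = pk.evolve_delay(st, 0.005)
        assert out.expect(ix).real == pytest.approx(-0.5, abs=1e-10)

    def test_matrix_exponential_oracle_for_propagator(self, two_spin_weak):
        # eigendecomposition propagator vs scipy.linalg.expm
        t = 0.0123
        u_ref = expm(-1j * two_spin_weak.hamiltonian * t)
        assert np.allclose(two_spin_weak.propagator(t), u_ref, atol=1e-10)


class TestUnitarity:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 360), st.floats(0, 360),
                              st.floats(0, 0.05)),
                    min_size=1, max_size=6))
    def test_random_sequences_preserve_spectrum(self, steps):
        system = pk.ea_d6_system()
        state = pk.pasadena_state(system, dephased=False)
        ref = np.sort(np.linalg.eigvalsh(state.rho))
        for flip, phase, delay in steps:
            state = pk.apply_pulse(state, flip, phase)
            state = pk.evolve_delay(state, delay)
        evals = np.sort(np.linalg.eigvalsh(state.rho))
        assert np.allclose(evals, ref, atol=1e-10)
        assert np.trace(state.rho).real == pytest.approx(1.0, abs=1e-12)


class TestDetection:
    def test_maximally_mixed_gives_zero_fid(self, two_spin_weak):
        st = pk.pasadena_state(two_spin_weak, enrichment=0.25)
        fid = pk.detect_fid(st, duration=0.1, dwell=1e-3)
        assert np.allclose(fid.signal, 0.0, atol=1e-14)

    def test_unit_ix_deviation_normalization(self, single_spin):
        st = rho_deviation(single_spin, single_spin.op(0, "x"))
        fid = pk.detect_fid(st, duration=0.01, dwell=1e-3)
        assert fid.signal[0].real == pytest.approx(1.0, abs=1e-12)
        assert fid.integral == pytest.approx(1.0, abs=1e-12)

    def test_lorentzian_broadening_sets_fwhm(self, single_spin):
        # |s(t)| envelope exp(-π·8·t); spectral FWHM = 8 Hz within 2%
        st = pk.apply_pulse(pk.thermal_state(single_spin), 90, 90)
        fid = pk.detect_fid(st, duration=8.0, dwell=0.004, lw=8.0)
        assert np.allclose(np.abs(fid.signal),
                           np.exp(-math.pi * 8.0 * fid.time), atol=1e-10)
        spec = pk.fid_to_spectrum(fid)
        half = spec.real.max() / 2
        above = spec.freq_hz[spec.real >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(8.0, rel=0.02)

    def test_spectrum_integral_matches_first_point(self, single_spin):
        st = pk.apply_pulse(pk.thermal_state(single_spin), 90, 90)
        fid = pk.detect_fid(st, duration=8.0, dwell=0.004, lw=8.0)
        spec = pk.fid_to_spectrum(fid)
        assert spec.integral() == pytest.approx(fid.integral, rel=1e-3)

    def test_line_position_in_ppm_and_hz(self):
        # spin at 4.12 ppm with 18.717 MHz reference -> +77.11 Hz
        sys1 = pk.build_spin_system([4.12], [[0.0]], 0.4454, 18.717e6)
        st = pk.apply_pulse(pk.thermal_state(sys1), 90, 90)
        fid = pk.detect_fid(st, duration=16.0, dwell=0.002, lw=1.0)
        spec = pk.fid_to_spectrum(fid)
        peak = int(np.argmax(spec.real))
        expected_hz = 4.12e-6 * 18.717e6
        assert spec.freq_hz[peak] == pytest.approx(expected_hz, abs=0.1)
        assert spec.ppm[peak] == pytest.approx(4.12, abs=0.01)

    def test_spectrum_linearity(self, single_spin):
        st1 = pk.apply_pulse(pk.thermal_state(single_spin), 90, 90)
        st2 = pk.apply_pulse(pk.thermal_state(single_spin), 45, 90)
        f1 = pk.detect_fid(st1, 0.5, 1e-3, lw=4.0)
        f2 = pk.detect_fid(st2, 0.5, 1e-3, lw=4.0)
        fsum = pk.FidResult(time=f1.time, signal=f1.signal + f2.signal,
                            dwell=f1.dwell, lw=f1.lw, system=single_spin)
        s1 = pk.fid_to_spectrum(f1).values
        s2 = pk.fid_to_spectrum(f2).values
        ssum = pk.fid_to_spectrum(fsum).values
        assert np.allclose(s1 + s2, ssum, atol=1e-12)

    def test_bad_acquisition_parameters_rejected(self, single_spin):
        st = pk.thermal_state(single_spin)
        with pytest.raises(ValueError):
            pk.detect_fid(st, duration=1e-3, dwell=1e-2)


class TestStateValidation:
    def test_non_hermitian_rejected(self, single_spin):
        rho = np.array([[0.5, 0.5j], [0.5j, 0.5]])
        with pytest.raises(ValueError):
            pk.SpinState(rho, single_spin)

    def test_wrong_trace_rejected(self, single_spin):
        with pytest.raises(ValueError):
            pk.SpinState(np.eye(2), single_spin)
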