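import numpy as np
import pytest

import phipkit as pk


@pytest.fixture
def two_spin_weak():
    """Two protons, zero shifts, J = 7.1 Hz, secular (weak) coupling.

    This is the regime where the product-operator closed forms used as
    oracles are exact.
    """
    return pk.build_spin_system([0.0, 0.0], [[0.0, 7.1], [7.1, 0.0]],
                                b0=0.4454, ref_freq=18.717e6, coupling="weak")


@pytest.fixture
def single_spin():
    return pk.build_spin_system([0.0], [[0.0]], b0=0.4454, ref_freq=18.717e6)


@pytest.fixture
def table1():
    """Published per-reactor characterization values (text-authoritative).

    Keys: OD (mm) -> dict(fwhm_ppm, fwhm_hz, t2star_arg, t2star, t2, dstar).

    Note: the published table's first numeric column (1.05/1.57/2.50) is
    the ppm linewidth printed under a Hz heading; the running text gives
    the unambiguous pairing (ppm, Hz) used here.  The published T2* column
    is consistent with 1/(pi*x) applied to that first column, so it is
    carried as ``t2star_arg``.
    """
    return {
        5: dict(fwhm_ppm=1.047, fwhm_hz=19.855, t2star_arg=1.05,
                t2star=0.30, t2=4.38, dstar=0.41),
        10: dict(fwhm_ppm=1.574, fwhm_hz=29.847, t2star_arg=1.57,
                 t2star=0.20, t2=4.27, dstar=0.61),
        16: dict(fwhm_ppm=2.492, fwhm_hz=47.254, t2star_arg=2.50,
                 t2star=0.13, t2=3.91, dstar=0.83),
    }


def rho_deviation(system, op, scale=1.0):
    """Density matrix E/2^N + scale·op, validated as a SpinState."""
    rho = np.eye(system.dim, dtype=complex) / system.dim + scale * op
    return pk.SpinState(rho, system)
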