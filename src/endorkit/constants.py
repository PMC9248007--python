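"""Physical constants and nuclear data used throughout the package.

All hyperfine couplings are carried in kHz, spectral axes in MHz,
magnetic fields in tesla, distances in angstrom (geometry) or nm (DEER).
"""

from scipy import constants as _sc

#: Bohr magneton (J/T)
MU_B = _sc.physical_constants["Bohr magneton"][0]
#: nuclear magneton (J/T)
MU_N = _sc.physical_constants["nuclear magneton"][0]
#: Planck constant (J s)
H_PLANCK = _sc.h
#: mu_0 / 4 pi (T m / A)
MU0_OVER_4PI = _sc.mu_0 / (4.0 * _sc.pi)
#: free-electron g value (positive convention)
G_E_FREE = abs(_sc.physical_constants["electron g factor"][0])

# Nuclear g factors g_n = mu / (I * mu_N), from tabulated nuclear moments.
# Signs kept (17O is negative); Larmor frequencies use the magnitude.
NUCLEAR_G = {
    "1H": 5.5856946893,
    "2H": 0.8574382338,
    "19F": 5.257736,
    "17O": -0.757516,
}

NUCLEAR_SPIN = {
    "1H": 0.5,
    "2H": 1.0,
    "19F": 0.5,
    "17O": 2.5,
}

KNOWN_ISOTOPES = tuple(sorted(NUCLEAR_G))


def gamma_mhz_per_t(isotope: str) -> float:
    """Gyromagnetic ratio gamma/2pi in MHz/T for a known isotope label."""
    try:
        g_n = NUCLEAR_G[isotope]
    except KeyError:
        raise KeyError(
            f"unknown isotope {isotope!r}; known isotopes: {', '.join(KNOWN_ISOTOPES)}"
        ) from None
    return abs(g_n) * MU_N / H_PLANCK / 1e6
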