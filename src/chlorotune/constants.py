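"""Physical constants and unit conversions (CODATA-fixed values).

All internal energies are in eV; cm^-1, nm and mV appear only at I/O
boundaries.  The constants here are the single source of truth for every
conversion in the package.
"""

#: cm^-1 per eV
CM1_PER_EV = 8065.544

#: hc in eV*nm (photon energy E = HC_EV_NM / wavelength_nm)
HC_EV_NM = 1239.84193

#: reduced Planck constant, eV*s
HBAR_EV_S = 6.58212e-16

#: Boltzmann constant, eV/K
KB_EV_K = 8.61733e-5

#: default temperature, K (k_B*T = 0.025693 eV)
T_DEFAULT_K = 298.15

#: point-dipole coupling prefactor: V[cm^-1] = PREF * f * kappa * mu1*mu2[D^2] / R^3[A^3]
DIPOLE_COUPLING_PREFACTOR = 5034.1

#: oscillator strength prefactor: f = PREF * E[cm^-1] * |mu|^2[D^2]
OSC_STRENGTH_PREFACTOR = 4.702e-7

#: bumped when any constant above changes; recorded in CLI provenance blocks
CONSTANTS_VERSION = "1"


def ev_to_cm1(e_ev: float) -> float:
    """Convert energy from eV to wavenumbers (cm^-1)."""
    return e_ev * CM1_PER_EV


def cm1_to_ev(e_cm1: float) -> float:
    """Convert energy from wavenumbers (cm^-1) to eV."""
    return e_cm1 / CM1_PER_EV
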