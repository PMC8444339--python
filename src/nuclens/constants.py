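"""Physical constants and unit-conversion factors used across the package.

All values derive from :mod:`scipy.constants` (CODATA).  Internal unit
conventions: geometries in Å, Hessians in Hartree/Bohr², masses in amu,
wavenumbers in cm⁻¹, photon energies in eV, cross sections in cm².
"""

import math

import scipy.constants as _sc

# base SI
HBAR_J_S = _sc.hbar
E_CHARGE_C = _sc.e
M_E_KG = _sc.m_e
EPS0_F_M = _sc.epsilon_0
C_M_S = _sc.c
KB_J_K = _sc.k
N_A = _sc.N_A

# unit sizes in SI
EV_J = _sc.electron_volt
AMU_KG = _sc.atomic_mass
BOHR_M = _sc.physical_constants["Bohr radius"][0]
HARTREE_J = _sc.physical_constants["Hartree energy"][0]
ANGSTROM_M = 1e-10

BOHR_A = BOHR_M / ANGSTROM_M  # 0.529177... Å per Bohr

#: hc in eV·nm — photon energy E[eV] = HC_EV_NM / λ[nm]
HC_EV_NM = _sc.h * C_M_S / EV_J * 1e9

#: angular frequency (rad/s) of a 1 cm⁻¹ wavenumber: ω = 2πc·ν̃
OMEGA_PER_CM1 = 2.0 * math.pi * C_M_S * 100.0

#: wavenumber (cm⁻¹) corresponding to sqrt of a mass-weighted Hessian
#: eigenvalue of 1 Hartree/(amu·Bohr²): sqrt(Eh/(amu·a0²))/(2πc) ≈ 5140.49
CM1_PER_SQRT_HARTREE_AMU_BOHR2 = (
    math.sqrt(HARTREE_J / (AMU_KG * BOHR_M**2)) / OMEGA_PER_CM1
)

#: integrated cross-section prefactor C = πe²ħ/(2mcε₀), in eV·cm², so that
#: ∫σ(E) dE = C · f for a single unit-area line of oscillator strength f
SIGMA_PREFACTOR_EV_CM2 = (
    math.pi * E_CHARGE_C**2 * HBAR_J_S / (2.0 * M_E_KG * C_M_S * EPS0_F_M)
) / EV_J * 1e4

#: ε[M⁻¹cm⁻¹] = σ[cm²] · N_A / (10³ ln 10) ≈ 2.6154e20
EPS_PER_SIGMA = N_A / (1e3 * math.log(10.0))


def wigner_q_variance_amu_A2(freq_cm1: float, temperature_K: float = 0.0) -> float:
    """Variance of a mass-weighted normal coordinate Q in the harmonic
    vibrational Wigner distribution, in amu·Å².

    At T = 0 this is ħ/(2ω); at T > 0 it is ħ/(2ω)·coth(ħω/2k_BT).
    """
    if freq_cm1 <= 0:
        raise ValueError(f"need a positive wavenumber, got {freq_cm1} cm^-1")
    omega = freq_cm1 * OMEGA_PER_CM1  # rad/s
    var_si = HBAR_J_S / (2.0 * omega)  # kg·m²
    if temperature_K > 0:
        x = HBAR_J_S * omega / (2.0 * KB_J_K * temperature_K)
        var_si *= 1.0 / math.tanh(x)
    return var_si / (AMU_KG * ANGSTROM_M**2)
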