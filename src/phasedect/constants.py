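"""Physical constants (CODATA 2018) in the unit system used throughout.

Energies are in keV, cross sections in cm², electron densities in m⁻³
(converted to cm⁻³ inside attenuation formulas so that the empirical
photo-effect prefactor closes dimensionally).
"""

from types import MappingProxyType

#: classical electron radius [m]
R0_M = 2.8179403262e-15

#: Planck constant [keV s]
H_KEV_S = 4.135667696e-18

#: speed of light [m/s]
C_M_S = 2.99792458e8

#: electron rest energy [keV]
ME_C2_KEV = 510.99895

#: Avogadro constant [1/mol]
N_A = 6.02214076e23

#: hc [keV m]
HC_KEV_M = H_KEV_S * C_M_S

#: coefficient of the refractive-index decrement relation
#: delta = DELTA_COEFF * rho_e / E^2, with rho_e in m^-3 and E in keV
DELTA_COEFF = R0_M * HC_KEV_M**2 / (2.0 * 3.141592653589793)

#: Thomson cross section [cm²] — the E → 0 limit of Klein–Nishina
SIGMA_THOMSON_CM2 = 6.6524587321e-25

#: immutable view for introspection
CODATA = MappingProxyType(
    {
        "r0_m": R0_M,
        "h_keV_s": H_KEV_S,
        "c_m_s": C_M_S,
        "me_c2_keV": ME_C2_KEV,
        "N_A": N_A,
    }
)
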