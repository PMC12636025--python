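"""Physical constants (CODATA 2018) and unit conversions.

All thermodynamic quantities in this package are molar energies in
kcal·mol⁻¹, lengths in Å, masses in amu, wavenumbers in cm⁻¹ and
temperatures in K.
"""

# CODATA 2018 (SI)
K_B_SI = 1.380649e-23  # J·K⁻¹
H_SI = 6.62607015e-34  # J·s
C_CM_S = 2.99792458e10  # speed of light, cm·s⁻¹
N_A = 6.02214076e23  # mol⁻¹
AMU_KG = 1.66053906660e-27  # kg

CAL_J = 4.184  # thermochemical calorie

#: Gas constant in kcal·mol⁻¹·K⁻¹
R_KCAL = K_B_SI * N_A / (CAL_J * 1000.0)  # = 1.987204e-3

#: Eyring prefactor k_B/h in s⁻¹·K⁻¹ (multiply by T for k_B·T/h)
KB_OVER_H = K_B_SI / H_SI

#: 1 cm⁻¹ expressed as a molar energy, kcal·mol⁻¹
WAVENUMBER_TO_KCAL = H_SI * C_CM_S * N_A / (CAL_J * 1000.0)  # ≈ 1/349.755

#: Conversion factor for Hessian eigenvalues:
#: λ in kcal·mol⁻¹·Å⁻²·amu⁻¹  →  ω² in s⁻² is λ * HESS_EV_TO_S2
HESS_EV_TO_S2 = (CAL_J * 1000.0 / N_A) / (1e-20 * AMU_KG)


def kt_kcal(temperature: float) -> float:
    """Thermal energy k_B·T as a molar energy in kcal·mol⁻¹."""
    return R_KCAL * temperature
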