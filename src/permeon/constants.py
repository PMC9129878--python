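"""Physical constants and unit conversions.

Internal units throughout the package: Å, ps, kcal/mol, elementary charge,
kelvin.  Conversions to SI or electrophysiology units (pS, pA, mV) happen
only at the edges, through the helpers below.
"""

#: Boltzmann constant, kcal/(mol K)
KB_KCAL_MOL_K = 1.987204259e-3

#: Coulomb constant, kcal Å / (mol e^2); Phi = COULOMB * q / (eps * r)
COULOMB_KCAL_A_MOL_E2 = 332.0636

#: Elementary charge, C
E_CHARGE_C = 1.602176634e-19

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23

#: Gas constant, J/(mol K)
R_J_MOL_K = 8.31446261815324

#: Faraday constant, C/mol
FARADAY_C_MOL = 96485.33212

#: Conversion used for field-to-voltage arithmetic: V per (kcal/mol)/e
VOLT_PER_KCAL_MOL_E = 0.0434


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
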