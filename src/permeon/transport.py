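"""Single-channel conductance from a free-energy profile, and ohmic arithmetic.

A 1-D diffusion (Nernst–Planck-type) treatment gives the conductance

    γ = q² C S / (k_B T) · [ ∫_{z1}^{z2} exp(F(z)/k_B T) / D(z) dz ]⁻¹

with q the ion charge, C the bulk concentration, S the cross-sectional area
of the sampled cylinder, D the (flat by default) diffusion profile and F the
PMF anchored to zero in bulk.  The exponential of the barrier dominates:
γ is reported in pS, currents I = γV in pA, and permeation rates I/e in
ions/μs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, E_CHARGE_C, VOLT_PER_KCAL_MOL_E, kT
from .profiles import Profile

_KB_SI = 1.380649e-23  # J/K


@dataclass(frozen=True)
class ConductanceInputs:
    q: float = 1.0                 # e
    concentration: float = 0.1     # mol/L
    cross_section: float = 314.0   # Å^2
    diffusion: float = 2e-9        # m^2/s (K+ 2e-9, Na+ 1.5e-9)
    temperature: float = 298.0     # K
    z1: float | None = None        # Å; default: anchored-bulk profile edges
    z2: float | None = None

    def __post_init__(self):
        for name in ("concentration", "cross_section", "diffusion", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z1 is not None and self.z2 is not None and self.z1 >= self.z2:
            raise ValueError("z1 must be below z2")


@dataclass(frozen=True)
class FieldSpec:
    E_z: float          # kcal/(mol Å e)
    L_z: float          # Å

    def __post_init__(self):
        if self.L_z <= 0:
            raise ValueError("L_z must be positive")


def conductance_from_pmf(F: Profile, inputs: ConductanceInputs = ConductanceInputs(),
                         diffusion_profile: Profile | None = None) -> float:
    """Conductance γ in pS from a bulk-anchored free-energy profile.

    Trapezoidal integration of exp(F/k_B T)/D over [z1, z2]; any masked bin
    inside the bounds is an error (an undefined barrier region cannot be
    integrated through).
    """
    z = F.bin_centers
    z1 = inputs.z1 if inputs.z1 is not None else z[0]
    z2 = inputs.z2 if inputs.z2 is not None else z[-1]
    inside = (z >= z1) & (z <= z2)
    if not inside.any():
        raise ValueError("no bins inside [z1, z2]")
    if np.any(np.isnan(F.values[inside])):
        raise ValueError("masked free-energy bin inside the integration bounds")
    kt = kT(inputs.temperature)

    if diffusion_profile is None:
        D = np.full(int(inside.sum()), inputs.diffusion)
    else:
        if diffusion_profile.bin_centers.shape != z.shape:
            raise ValueError("diffusion profile must share the PMF bins")
        D = diffusion_profile.values[inside]

    integrand = np.exp(F.values[inside] / kt) / D          # s/m^2
    integral_si = np.trapezoid(integrand, z[inside] * 1e-10)  # s/m

    q_si = inputs.q * E_CHARGE_C
    conc_si = inputs.concentration * 1000.0 * AVOGADRO     # 1/m^3
    s_si = inputs.cross_section * 1e-20                    # m^2
    gamma_si = q_si**2 * conc_si * s_si / (_KB_SI * inputs.temperature) / integral_si
    return gamma_si * 1e12  # pS


def flat_pmf_conductance(inputs: ConductanceInputs, length: float) -> float:
    """Closed-form γ (pS) for a flat PMF over `length` Å: q²CSD/(k_B T L)."""
    q_si = inputs.q * E_CHARGE_C
    conc_si = inputs.concentration * 1000.0 * AVOGADRO
    s_si = inputs.cross_section * 1e-20
    gamma_si = (q_si**2 * conc_si * s_si * inputs.diffusion
                / (_KB_SI * inputs.temperature * length * 1e-10))
    return gamma_si * 1e12


def field_to_voltage(field: FieldSpec) -> float:
    """Transmembrane potential (mV) from a uniform field: Φ = E_z·L_z·0.0434 V."""
    return field.E_z * field.L_z * VOLT_PER_KCAL_MOL_E * 1000.0


def ohmic_current_and_rate(gamma_pS: float, voltage_mV: float) -> tuple[float, float]:
    """Ohmic current (pA) and permeation rate (ions/μs) at a given voltage."""
    current_pA = gamma_pS * voltage_mV * 1e-3  # pS * mV = 1e-3 pA
    rate_per_us = current_pA * 1e-12 / E_CHARGE_C * 1e-6
    return current_pA, rate_per_us
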