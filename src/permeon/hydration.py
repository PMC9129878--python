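"""Smooth coordination-number counting and hydration profiles.

The number of oxygens coordinating an ion is measured with the rational
switching function

    S = Σ_j [1 − (r_j/r0)^100] / [1 − (r_j/r0)^200]
      = Σ_j 1 / (1 + (r_j/r0)^100),

which is numerically a step at r0 (value 1/2 exactly at r = r0, the
removable singularity of the first form) yet differentiable.  Shell radii
r0 follow the minima of the ion–oxygen RDF in bulk water: first shell 3.5 Å
(K+) / 3.2 Å (Na+), first+second shells 6.0 / 5.7 Å.  The exponents are
fixed at 100/200 and deliberately not re-tuned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Species, TrajectoryFrame, minimum_image
from .reweight import observable_profile

#: Bulk-water reference coordination numbers for reporting depletion ΔN
#: (external constants, not recomputed here): K+ first shell ~7, first two ~31.
BULK_COORDINATION_K = {"first": 7.0, "first_plus_second": 31.0}

_SHELL_R0 = {
    (Species.K, "first"): 3.5,
    (Species.NA, "first"): 3.2,
    (Species.K, "first_plus_second"): 6.0,
    (Species.NA, "first_plus_second"): 5.7,
}


@dataclass(frozen=True)
class SwitchingParams:
    r0: float
    numerator_exponent: int = 100
    denominator_exponent: int = 200

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.numerator_exponent <= 0 or self.denominator_exponent != 2 * self.numerator_exponent:
            raise ValueError("exponents must be positive with denominator = 2 x numerator")


def switching_count(distances, params: SwitchingParams) -> float:
    """Smooth count of distances below r0 (exactly 1/2 at r = r0)."""
    r = np.asarray(distances, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    t = r / params.r0
    n = params.numerator_exponent
    # 1/(1+t^n): overflow in t^n for t >> 1 harmlessly saturates to 0
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + t**n)
    return float(np.sum(s))


def shell_r0(species: Species, shell: str) -> float:
    """Tabulated shell radius r0 (Å) for a species and shell choice."""
    species = Species(species)
    if shell not in ("first", "first_plus_second"):
        raise ValueError(f"unknown shell {shell!r}")
    try:
        return _SHELL_R0[(species, shell)]
    except KeyError:
        raise ValueError(f"no r0 tabulated for {species.value} / {shell}") from None


def coordination_numbers(frame: TrajectoryFrame, oxygen_source: str = "water",
                         shell: str = "first",
                         use_minimum_image: bool = True) -> np.ndarray:
    """Per-ion switching counts against water or protein oxygens in one frame."""
    if oxygen_source == "water":
        oxygens = frame.water_oxygen_positions
        if oxygens.shape[0] == 0:
            raise ValueError("frame has no water oxygens")
    elif oxygen_source == "protein":
        if frame.protein is None:
            oxygens = np.empty((0, 3))
        else:
            mask = np.char.upper(frame.protein.elements.astype(str)) == "O"
            oxygens = frame.protein.positions[mask]
    else:
        raise ValueError(f"unknown oxygen source {oxygen_source!r}")

    counts = np.zeros(frame.ion_positions.shape[0])
    if oxygens.shape[0] == 0:
        return counts
    box = frame.box_lengths if use_minimum_image else None
    for k, (pos, sp) in enumerate(zip(frame.ion_positions, frame.ion_species)):
        params = SwitchingParams(shell_r0(sp, shell))
        delta = minimum_image(oxygens - pos, box)
        counts[k] = switching_count(np.linalg.norm(delta, axis=1), params)
    return counts


def coordination_profile(frames, ion_z, ion_R, weights, bin_centers, *,
                         oxygen_source: str = "water", shell: str = "first",
                         R0: float = 10.0):
    """Reweighted mean coordination number along the pore axis.

    ``frames`` supplies the oxygen environments; ``ion_z``/``ion_R`` are the
    matching (n_frames, n_ions) pore coordinates and ``weights`` the
    snapshot-weight table from the reweighting stage.
    """
    obs = np.stack([coordination_numbers(fr, oxygen_source, shell) for fr in frames])
    return observable_profile(obs, ion_z, ion_R, weights, bin_centers, R0,
                              quantity=f"{oxygen_source}-oxygen coordination ({shell} shell)",
                              units="count")
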