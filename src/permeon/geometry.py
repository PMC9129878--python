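"""Trajectory frames, pore-axis construction, and permeation-event counting.

The pore axis is defined by two centers of selected protein atoms (centers A
and B, Cα groups flanking the channel constriction); ion positions are
expressed in cylindrical pore coordinates (z, R) relative to the midpoint of
the two centers, with z the signed projection on the A–B axis and R the
perpendicular distance to it.  Ion-axis geometry honours the minimum-image
convention of the (orthorhombic) simulation box, since production
trajectories are wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

DEGENERATE_AXIS_TOL = 1e-6  # Å


class Species(str, Enum):
    K = "K+"
    NA = "Na+"
    CS = "Cs+"


@dataclass
class ProteinAtoms:
    """Per-atom protein records needed by axis construction and electrostatics."""

    resids: np.ndarray          # residue numbers
    names: np.ndarray           # atom names, e.g. "CA"
    elements: np.ndarray        # element symbols, e.g. "O"
    charges: np.ndarray         # partial charges, e
    radii: np.ndarray           # radii, Å
    positions: np.ndarray       # (n, 3) Å

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        for name in ("resids", "names", "elements", "charges", "radii"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("protein positions must be finite")
        if not np.all(np.isfinite(np.asarray(self.charges, dtype=float))):
            raise ValueError("partial charges must be finite")


@dataclass
class TrajectoryFrame:
    """One simulation snapshot: ions, water oxygens, and protein atoms."""

    frame_index: int
    time: float                       # ps
    box_lengths: np.ndarray           # (3,) Å
    ion_positions: np.ndarray         # (n_ions, 3) Å
    ion_species: list                 # Species per ion
    water_oxygen_positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))
    protein: ProteinAtoms | None = None

    def __post_init__(self):
        self.box_lengths = np.asarray(self.box_lengths, dtype=float).reshape(3)
        self.ion_positions = np.asarray(self.ion_positions, dtype=float).reshape(-1, 3)
        self.water_oxygen_positions = np.asarray(
            self.water_oxygen_positions, dtype=float).reshape(-1, 3)
        if np.any(self.box_lengths <= 0):
            raise ValueError("box_lengths must be positive")
        if not np.all(np.isfinite(self.ion_positions)):
            raise ValueError("ion positions must be finite")
        if len(self.ion_species) != self.ion_positions.shape[0]:
            raise ValueError("one species label per ion required")
        self.ion_species = [Species(s) for s in self.ion_species]


@dataclass
class PoreAxisFrame:
    """Pore-axis frame: centers A and B, their midpoint origin, and unit axis."""

    center_A: np.ndarray
    center_B: np.ndarray
    origin: np.ndarray
    axis_unit: np.ndarray

    def __post_init__(self):
        for name in ("center_A", "center_B", "origin", "axis_unit"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > 1e-9:
            raise ValueError("axis_unit must be a unit vector")


@dataclass
class IonPoreCoordinate:
    z: float  # Å, signed projection on the axis (origin at the A/B midpoint)
    R: float  # Å, perpendicular distance to the axis (>= 0)


def minimum_image(delta: np.ndarray, box_lengths: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box_lengths is None:
        return delta
    box = np.asarray(box_lengths, dtype=float)
    return delta - box * np.round(delta / box)


def select_calpha(protein: ProteinAtoms, resids) -> np.ndarray:
    """Indices of Cα atoms belonging to the given residue numbers."""
    wanted = set(int(r) for r in np.atleast_1d(resids))
    mask = (protein.names == "CA") & np.isin(protein.resids, list(wanted))
    return np.nonzero(mask)[0]


def compute_pore_axis(frame: TrajectoryFrame, selection_A, selection_B,
                      orient_positive_toward_A: bool = True) -> PoreAxisFrame:
    """Build the pore-axis frame from two protein-atom selections.

    Centers A and B are unweighted centroids of the selected atoms; the axis
    unit vector points from B to A (flip with ``orient_positive_toward_A``),
    and the origin is the A/B midpoint — the channel constriction, which
    defines z = 0 for all downstream profiles.
    """
    if frame.protein is None:
        raise ValueError("frame carries no protein atoms")
    sel_A = np.atleast_1d(np.asarray(selection_A, dtype=int))
    sel_B = np.atleast_1d(np.asarray(selection_B, dtype=int))
    if sel_A.size == 0 or sel_B.size == 0:
        raise ValueError("empty atom selection")
    center_A = frame.protein.positions[sel_A].mean(axis=0)
    center_B = frame.protein.positions[sel_B].mean(axis=0)
    ab = center_A - center_B
    norm = np.linalg.norm(ab)
    if norm < DEGENERATE_AXIS_TOL:
        raise ValueError(f"degenerate pore axis: |A - B| = {norm:.3g} Å")
    axis = ab / norm
    if not orient_positive_toward_A:
        axis = -axis
    return PoreAxisFrame(center_A, center_B, (center_A + center_B) / 2, axis)


def ion_pore_coordinates(frame: TrajectoryFrame, axis: PoreAxisFrame,
                         use_minimum_image: bool = True) -> list[IonPoreCoordinate]:
    """Cylindrical pore coordinates (z, R) for every ion in the frame."""
    box = frame.box_lengths if use_minimum_image else None
    delta = minimum_image(frame.ion_positions - axis.origin, box)
    z = delta @ axis.axis_unit
    perp = delta - np.outer(z, axis.axis_unit)
    R = np.linalg.norm(perp, axis=1)
    return [IonPoreCoordinate(float(zi), float(ri)) for zi, ri in zip(z, R)]


def count_permeation_events(z_series, R_series, z_lo: float = -15.0,
                            z_hi: float = 15.0, R0: float = 10.0) -> tuple[int, int]:
    """Count completed pore transits of one ion.

    A transit is counted when the ion goes from beyond one z bound to beyond
    the other while remaining within R0 of the axis whenever it is inside
    the pore region [z_lo, z_hi]; excursions that leave the axis cylinder or
    retreat without completing do not count.

    Returns ``(inward, outward)`` — inward meaning from above z_hi to below
    z_lo (lumen to cytosol in the package's sign convention).
    """
    z = np.asarray(z_series, dtype=float)
    R = np.asarray(R_series, dtype=float)
    if z.size == 0:
        raise ValueError("empty series")
    if z.shape != R.shape:
        raise ValueError("z and R series must have equal length")
    if z_lo >= z_hi:
        raise ValueError("z_lo must be below z_hi")

    inward = outward = 0
    armed = None  # side from which a transit is in progress: 'hi' | 'lo' | None
    for zi, ri in zip(z, R):
        if zi > z_hi:
            if armed == "lo":
                outward += 1
            armed = "hi"
        elif zi < z_lo:
            if armed == "hi":
                inward += 1
            armed = "lo"
        else:
            # inside the pore region: leaving the axis cylinder voids the attempt
            if ri > R0:
                armed = None
    return inward, outward


def count_periodic_transits(z_series, R_series, box_z: float,
                            z_lo: float = -15.0, z_hi: float = 15.0,
                            R0: float = 10.0) -> tuple[int, int]:
    """Permeation counting for z-wrapped (periodic) trajectories.

    Wrap jumps (|Δz| > box_z/2) teleport the ion between the reservoirs
    without crossing the pore; the series is split at each jump and the
    segments are scanned independently so jumps never register as transits.
    """
    z = np.asarray(z_series, dtype=float)
    R = np.asarray(R_series, dtype=float)
    if z.size == 0:
        raise ValueError("empty series")
    jumps = np.nonzero(np.abs(np.diff(z)) > box_z / 2)[0] + 1
    inward = outward = 0
    for seg in np.split(np.arange(z.size), jumps):
        i, o = count_permeation_events(z[seg], R[seg], z_lo, z_hi, R0)
        inward += i
        outward += o
    return inward, outward
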