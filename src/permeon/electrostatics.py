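"""Finite-difference linearized-Poisson electrostatics on a lattice.

The ion–protein interaction energy is E_k = q_k Φ(r_k), where Φ is the
potential generated by the protein partial charges alone in a heterogeneous
dielectric: protein interior ε_p, implicit membrane slab ε_m, bulk water
ε_s, a lower-dielectric cylinder of pore water ε_s′, and a small cavity
around the ion ε_k (the ion's own charge is absent from the solve).  Zero
ionic strength: the Debye–Hückel screening term is zero, so the equation is
∇·(ε∇Φ) = −4π k_e ρ with k_e = 332.0636 kcal Å/(mol e²), Φ in kcal/mol/e.

Discretization: 7-point flux stencil on a cubic lattice with harmonic-mean
face dielectrics, trilinear charge spreading, Dirichlet boundaries from the
analytic Coulomb potential of the total charge in bulk solvent, solved by
preconditioned conjugate gradients (scipy.sparse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import COULOMB_KCAL_A_MOL_E2 as KE
from .reweight import observable_profile

REGION_BULK, REGION_MEMBRANE, REGION_PORE_WATER, REGION_CAVITY, REGION_PROTEIN = range(5)


@dataclass(frozen=True)
class RegionSpec:
    """Dielectric constants and geometry of the implicit environment."""

    eps_protein: float = 2.0
    eps_membrane: float = 2.0
    eps_bulk: float = 80.0
    eps_pore_water: float = 40.0
    eps_ion_cavity: float = 2.0
    membrane_thickness: float = 28.8   # Å
    pore_cylinder_radius: float = 18.0  # Å
    pore_cylinder_height: float = 28.8  # Å
    probe_radius: float = 1.0           # Å
    ion_cavity_radius: float = 2.0      # Å

    def __post_init__(self):
        for name in ("eps_protein", "eps_membrane", "eps_bulk",
                     "eps_pore_water", "eps_ion_cavity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("membrane_thickness", "pore_cylinder_radius",
                     "pore_cylinder_height", "probe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def eps_of_region(self) -> np.ndarray:
        return np.array([self.eps_bulk, self.eps_membrane, self.eps_pore_water,
                         self.eps_ion_cavity, self.eps_protein])


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice: n points per axis, uniform spacing, centered at `center`."""

    n: int = 150
    spacing: float = 1.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("grid too small")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def axes(self):
        half = self.spacing * (self.n - 1) / 2
        c = np.asarray(self.center, dtype=float)
        return tuple(c[d] - half + self.spacing * np.arange(self.n) for d in range(3))

    def coords(self):
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")


@dataclass
class DielectricLattice:
    grid: GridSpec
    region_codes: np.ndarray  # (n,n,n) ints
    eps: np.ndarray           # (n,n,n)


@dataclass
class PotentialLattice:
    grid: GridSpec
    values: np.ndarray        # (n,n,n), kcal/mol/e
    residual: float


def build_dielectric_map(atom_positions, atom_radii, region: RegionSpec,
                         grid: GridSpec, ion_position=None) -> DielectricLattice:
    """Assign every lattice point a dielectric region.

    Precedence (high to low): protein > ion cavity > pore-water cylinder >
    membrane slab > bulk.  The protein interior is the union of atom spheres
    inflated by the probe radius, followed by one binary-closing pass that
    approximates probe-reentrant surface smoothing.  The membrane slab and
    the pore cylinder are centered on the grid center, the cylinder axis
    along z.
    """
    X, Y, Z = grid.coords()
    cx, cy, cz = grid.center
    codes = np.full((grid.n,) * 3, REGION_BULK, dtype=np.int8)

    slab = np.abs(Z - cz) <= region.membrane_thickness / 2
    codes[slab] = REGION_MEMBRANE

    cyl = (((X - cx) ** 2 + (Y - cy) ** 2 <= region.pore_cylinder_radius**2)
           & (np.abs(Z - cz) <= region.pore_cylinder_height / 2))
    codes[cyl] = REGION_PORE_WATER

    if ion_position is not None:
        ion = np.asarray(ion_position, dtype=float)
        rc = region.ion_cavity_radius
        cav = ((X - ion[0]) ** 2 + (Y - ion[1]) ** 2 + (Z - ion[2]) ** 2) <= rc**2
        codes[cav] = REGION_CAVITY

    atom_positions = np.asarray(atom_positions, dtype=float).reshape(-1, 3)
    if atom_positions.shape[0]:
        atom_radii = np.broadcast_to(np.asarray(atom_radii, dtype=float),
                                     (atom_positions.shape[0],))
        x, y, z = grid.axes()
        reach = atom_radii + region.probe_radius
        if (np.any(atom_positions - reach[:, None] < [x[0], y[0], z[0]])
                or np.any(atom_positions + reach[:, None] > [x[-1], y[-1], z[-1]])):
            raise ValueError("protein extends beyond the lattice")
        inside = np.zeros(codes.shape, dtype=bool)
        for pos, rad in zip(atom_positions, reach):
            # only visit the local bounding box of each atom sphere
            i0 = np.maximum(((pos - rad) - [x[0], y[0], z[0]]) / grid.spacing, 0)
            i1 = ((pos + rad) - [x[0], y[0], z[0]]) / grid.spacing + 1
            i0 = i0.astype(int)
            i1 = np.minimum(i1.astype(int) + 1, grid.n)
            sl = tuple(slice(a, b) for a, b in zip(i0, i1))
            d2 = ((X[sl] - pos[0]) ** 2 + (Y[sl] - pos[1]) ** 2 + (Z[sl] - pos[2]) ** 2)
            inside[sl] |= d2 <= rad**2
        inside = ndi.binary_closing(inside)
        codes[inside] = REGION_PROTEIN

    eps = region.eps_of_region()[codes]
    return DielectricLattice(grid, codes, eps)


def uniform_dielectric(grid: GridSpec, eps: float) -> DielectricLattice:
    """Homogeneous dielectric lattice (validation and reference solves)."""
    codes = np.full((grid.n,) * 3, REGION_BULK, dtype=np.int8)
    return DielectricLattice(grid, codes, np.full((grid.n,) * 3, float(eps)))


def planar_interface_dielectric(grid: GridSpec, eps_upper: float,
                                eps_lower: float, z_interface: float = 0.0) -> DielectricLattice:
    """Two half-space dielectrics split by the plane z = z_interface."""
    _, _, Z = grid.coords()
    lower = Z < z_interface
    codes = np.where(lower, REGION_MEMBRANE, REGION_BULK).astype(np.int8)
    eps = np.where(lower, float(eps_lower), float(eps_upper))
    return DielectricLattice(grid, codes, eps)


def spread_charges_trilinear(positions, charges, grid: GridSpec) -> np.ndarray:
    """Distribute point charges to the 8 surrounding lattice nodes (units: e)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.broadcast_to(np.asarray(charges, dtype=float), (positions.shape[0],))
    x, y, z = grid.axes()
    origin = np.array([x[0], y[0], z[0]])
    q_grid = np.zeros((grid.n,) * 3)
    frac = (positions - origin) / grid.spacing
    if np.any(frac < 0) or np.any(frac > grid.n - 1):
        raise ValueError("charge outside lattice")
    i0 = np.minimum(frac.astype(int), grid.n - 2)
    f = frac - i0
    for dx in (0, 1):
        wx = np.where(dx, f[:, 0], 1 - f[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, f[:, 1], 1 - f[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, f[:, 2], 1 - f[:, 2])
                np.add.at(q_grid, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                          charges * wx * wy * wz)
    return q_grid


def _boundary_potential(grid: GridSpec, positions, charges, eps_bulk: float) -> np.ndarray:
    """Analytic Coulomb potential of all charges in bulk dielectric (Dirichlet BC)."""
    X, Y, Z = grid.coords()
    phi = np.zeros((grid.n,) * 3)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.broadcast_to(np.asarray(charges, dtype=float), (positions.shape[0],))
    for pos, q in zip(positions, charges):
        if q == 0:
            continue
        r = np.sqrt((X - pos[0]) ** 2 + (Y - pos[1]) ** 2 + (Z - pos[2]) ** 2)
        r = np.maximum(r, grid.spacing / 2)
        phi += KE * q / (eps_bulk * r)
    return phi


def solve_linearized_poisson(charge_positions, charges, dielectric: DielectricLattice,
                             tolerance: float = 1e-8, max_iter: int = 10000,
                             eps_boundary: float | None = None,
                             boundary_potential: np.ndarray | None = None) -> PotentialLattice:
    """Solve ∇·(ε∇Φ) = −4π k_e ρ on the lattice (zero ionic strength).

    Dirichlet boundary values default to the analytic Coulomb potential of
    the charges in bulk solvent (``eps_boundary``); validation solves with a
    known far field may pass an explicit ``boundary_potential`` lattice.
    The interior is solved with a diagonally preconditioned conjugate-
    gradient iteration on the symmetric 7-point flux operator (harmonic-mean
    face dielectrics).
    """
    grid = dielectric.grid
    n = grid.n
    h = grid.spacing
    eps = dielectric.eps
    if boundary_potential is not None:
        phi_b = np.asarray(boundary_potential, dtype=float)
        if phi_b.shape != (n, n, n):
            raise ValueError("boundary_potential must match the lattice shape")
    else:
        if eps_boundary is None:
            eps_boundary = float(np.median(eps[0]))  # boundary layer dielectric
        phi_b = _boundary_potential(grid, charge_positions, charges, eps_boundary)
    q_grid = spread_charges_trilinear(charge_positions, charges, grid)

    # face dielectrics (harmonic mean), arrays of shape (n-1, n, n) etc.
    def hmean(a, b):
        return 2 * a * b / (a + b)

    fx = hmean(eps[:-1, :, :], eps[1:, :, :])
    fy = hmean(eps[:, :-1, :], eps[:, 1:, :])
    fz = hmean(eps[:, :, :-1], eps[:, :, 1:])

    interior = np.zeros((n,) * 3, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = -np.ones((n,) * 3, dtype=np.int64)
    n_unk = int(interior.sum())
    idx[interior] = np.arange(n_unk)

    # A Φ = b with A = Σ_f ε_f (Φ_i − Φ_nb): SPD; b = 4π k_e q/h + BC fluxes
    rows, cols, vals = [], [], []
    diag = np.zeros(n_unk)
    b = 4 * np.pi * KE * q_grid[interior] / h

    ii, jj, kk = np.nonzero(interior)
    me = idx[ii, jj, kk]
    for axis, faces in ((0, fx), (1, fy), (2, fz)):
        for sign in (-1, +1):
            off = [0, 0, 0]
            off[axis] = sign
            ni, nj, nk = ii + off[0], jj + off[1], kk + off[2]
            if axis == 0:
                ef = faces[np.minimum(ii, ni), jj, kk]
            elif axis == 1:
                ef = faces[ii, np.minimum(jj, nj), kk]
            else:
                ef = faces[ii, jj, np.minimum(kk, nk)]
            diag[me] += ef
            nb = idx[ni, nj, nk]
            is_int = nb >= 0
            rows.append(me[is_int])
            cols.append(nb[is_int])
            vals.append(-ef[is_int])
            # Dirichlet neighbour: move to RHS
            bd = ~is_int
            b_add = np.zeros(n_unk)
            np.add.at(b_add, me[bd], ef[bd] * phi_b[ni[bd], nj[bd], nk[bd]])
            b += b_add

    rows.append(me)
    cols.append(me)
    vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_unk, n_unk))
    M = sp.diags(1.0 / A.diagonal())
    x, info = spla.cg(A, b, rtol=tolerance, maxiter=max_iter, M=M,
                      x0=phi_b[interior])
    res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
    if info != 0:
        raise RuntimeError(f"Poisson solver did not converge: info={info}, "
                           f"relative residual={res:.3e}")
    phi = phi_b.copy()
    phi[interior] = x
    return PotentialLattice(grid, phi, res)


def interpolate_potential(potential: PotentialLattice, position) -> float:
    """Trilinear interpolation of the lattice potential at a point."""
    grid = potential.grid
    x, y, z = grid.axes()
    pos = np.asarray(position, dtype=float).reshape(3)
    frac = (pos - [x[0], y[0], z[0]]) / grid.spacing
    if np.any(frac < 0) or np.any(frac > grid.n - 1):
        raise ValueError("position outside lattice")
    i0 = np.minimum(frac.astype(int), grid.n - 2)
    f = frac - i0
    val = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0]) * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                val += w * potential.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return float(val)


def ion_protein_energy(q_ion: float, potential: PotentialLattice, ion_position) -> float:
    """E_k = q_k · Φ(r_k) in kcal/mol, with Φ from a protein-charges-only solve."""
    if q_ion == 0:
        return 0.0
    return q_ion * interpolate_potential(potential, ion_position)


def ion_energy_for_frame(protein_positions, protein_charges, protein_radii,
                         ion_positions, ion_charges, region: RegionSpec,
                         grid: GridSpec, tolerance: float = 1e-8) -> np.ndarray:
    """Per-ion electrostatic interaction energies for one configuration.

    One Poisson solve per ion: the ion's cavity enters the dielectric map
    but its own charge never enters the source term.
    """
    ion_positions = np.asarray(ion_positions, dtype=float).reshape(-1, 3)
    ion_charges = np.broadcast_to(np.asarray(ion_charges, dtype=float),
                                  (ion_positions.shape[0],))
    energies = np.zeros(ion_positions.shape[0])
    for k, (pos, q) in enumerate(zip(ion_positions, ion_charges)):
        diel = build_dielectric_map(protein_positions, protein_radii, region, grid,
                                    ion_position=pos)
        pot = solve_linearized_poisson(protein_positions, protein_charges, diel,
                                       tolerance=tolerance)
        energies[k] = ion_protein_energy(q, pot, pos)
    return energies


def electrostatic_energy_profile(frames, ion_z, ion_R, weights, bin_centers, *,
                                 region: RegionSpec = RegionSpec(),
                                 grid: GridSpec = GridSpec(),
                                 ion_charge: float = 1.0, R0: float = 10.0,
                                 tolerance: float = 1e-8):
    """Reweighted ion–protein electrostatic energy along the pore axis."""
    rows = []
    for fr in frames:
        if fr.protein is None:
            rows.append(np.zeros(fr.ion_positions.shape[0]))
            continue
        rows.append(ion_energy_for_frame(
            fr.protein.positions, fr.protein.charges, fr.protein.radii,
            fr.ion_positions, ion_charge, region, grid, tolerance))
    obs = np.stack(rows)
    return observable_profile(obs, ion_z, ion_R, weights, bin_centers, R0,
                              quantity="ion-protein electrostatic energy",
                              units="kcal/mol")
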