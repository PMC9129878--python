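"""Dielectric-map construction and the linearized-Poisson lattice solver."""

import numpy as np
import pytest

from permeon.constants import COULOMB_KCAL_A_MOL_E2 as KE
from permeon.electrostatics import (GridSpec, RegionSpec, REGION_BULK,
                                    REGION_MEMBRANE, REGION_PORE_WATER,
                                    REGION_PROTEIN, build_dielectric_map,
                                    interpolate_potential, ion_energy_for_frame,
                                    ion_protein_energy,
                                    planar_interface_dielectric,
                                    solve_linearized_poisson,
                                    uniform_dielectric)

REGION = RegionSpec()
NO_ATOMS = np.empty((0, 3))


class TestDielectricMap:
    def test_geometry_without_atoms(self):
        grid = GridSpec(n=41, spacing=1.0)
        diel = build_dielectric_map(NO_ATOMS, [], REGION, grid)
        X, Y, Z = grid.coords()
        slab = np.abs(Z) <= REGION.membrane_thickness / 2
        cyl = (X**2 + Y**2 <= REGION.pore_cylinder_radius**2) & \
              (np.abs(Z) <= REGION.pore_cylinder_height / 2)
        assert np.all(diel.region_codes[cyl] == REGION_PORE_WATER)
        assert np.all(diel.region_codes[slab & ~cyl] == REGION_MEMBRANE)
        assert np.all(diel.region_codes[~slab] == REGION_BULK)
        assert np.all(diel.eps[~slab] == REGION.eps_bulk)
        assert np.all(diel.eps[cyl] == REGION.eps_pore_water)

    def test_single_atom_sphere(self):
        grid = GridSpec(n=41, spacing=1.0)
        diel = build_dielectric_map([[0.0, 0.0, 0.0]], [2.0], REGION, grid)
        X, Y, Z = grid.coords()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        inside = r <= 2.0 + REGION.probe_radius
        assert np.all(diel.region_codes[inside] == REGION_PROTEIN)
        assert np.all(diel.eps[inside] == REGION.eps_protein)

    def test_region_volumes_match_analytic(self):
        grid = GridSpec(n=61, spacing=1.0)
        diel = build_dielectric_map(NO_ATOMS, [], REGION, grid)
        h3 = grid.spacing**3
        v_cyl = (diel.region_codes == REGION_PORE_WATER).sum() * h3
        exact_cyl = (np.pi * REGION.pore_cylinder_radius**2
                     * REGION.pore_cylinder_height)
        # one voxel layer over the cylinder surface
        surf = (2 * np.pi * REGION.pore_cylinder_radius * REGION.pore_cylinder_height
                + 2 * np.pi * REGION.pore_cylinder_radius**2) * grid.spacing
        assert abs(v_cyl - exact_cyl) < surf

    def test_protein_beyond_grid_rejected(self):
        grid = GridSpec(n=21, spacing=1.0)
        with pytest.raises(ValueError, match="beyond"):
            build_dielectric_map([[50.0, 0.0, 0.0]], [2.0], REGION, grid)


class TestPoissonSolver:
    def test_zero_charges_zero_potential(self):
        grid = GridSpec(n=17, spacing=1.0)
        pot = solve_linearized_poisson(NO_ATOMS, [], uniform_dielectric(grid, 80.0))
        np.testing.assert_allclose(pot.values, 0.0, atol=1e-12)

    def test_point_charge_coulomb(self):
        """+1e in homogeneous ε = 80: Coulomb within 3% beyond 5 spacings."""
        grid = GridSpec(n=33, spacing=1.0)
        pot = solve_linearized_poisson([[0.0, 0.0, 0.0]], [1.0],
                                       uniform_dielectric(grid, 80.0),
                                       tolerance=1e-10)
        for r in (5.0, 7.0, 10.0, 12.0):
            phi = interpolate_potential(pot, (r, 0.0, 0.0))
            exact = KE / (80.0 * r)
            assert phi == pytest.approx(exact, rel=0.03)

    def test_linearity_in_charge(self):
        grid = GridSpec(n=25, spacing=1.0)
        diel = build_dielectric_map(NO_ATOMS, [], REGION, grid)
        p1 = solve_linearized_poisson([[3.0, 0.0, 0.0]], [1.0], diel, tolerance=1e-12)
        p2 = solve_linearized_poisson([[3.0, 0.0, 0.0]], [2.0], diel, tolerance=1e-12)
        np.testing.assert_allclose(p2.values, 2 * p1.values, atol=1e-6)

    def test_grid_refinement_consistency(self):
        """Halving the spacing changes the Coulomb potential < 2% at r ≥ 5."""
        coarse = solve_linearized_poisson(
            [[0.0, 0.0, 0.0]], [1.0],
            uniform_dielectric(GridSpec(n=33, spacing=1.0), 80.0), tolerance=1e-10)
        fine = solve_linearized_poisson(
            [[0.0, 0.0, 0.0]], [1.0],
            uniform_dielectric(GridSpec(n=65, spacing=0.5), 80.0), tolerance=1e-10)
        for r in (5.0, 8.0, 12.0):
            a = interpolate_potential(coarse, (r, 0.0, 0.0))
            b = interpolate_potential(fine, (r, 0.0, 0.0))
            assert abs(a - b) / abs(b) < 0.02

    def test_reciprocity(self):
        """Energy of A in the field of B equals B in the field of A."""
        grid = GridSpec(n=25, spacing=1.0)
        diel = planar_interface_dielectric(grid, 80.0, 2.0)
        pos_a, pos_b = np.array([0.0, 0.0, 5.0]), np.array([3.0, 0.0, 2.0])
        pot_a = solve_linearized_poisson([pos_a], [1.0], diel, tolerance=1e-12,
                                         eps_boundary=80.0)
        pot_b = solve_linearized_poisson([pos_b], [1.0], diel, tolerance=1e-12,
                                         eps_boundary=80.0)
        e_ab = interpolate_potential(pot_a, pos_b)
        e_ba = interpolate_potential(pot_b, pos_a)
        # the interior operator is exactly symmetric; the approximate Coulomb
        # Dirichlet boundary breaks reciprocity at the few-percent level
        assert e_ab == pytest.approx(e_ba, rel=0.03)

    def test_image_charge_closed_form(self):
        """Planar ε1/ε2 interface: probe potential matches the image charge.

        The lattice dielectric jumps between node planes, so the effective
        interface sits half a cell below z = 0; the reaction part of the
        potential (interface solve minus homogeneous solve, which cancels
        the discretized direct term) must match k_e q'/(ε1 r_image) to 5%.
        """
        grid = GridSpec(n=65, spacing=1.0)
        e1, e2, d = 80.0, 2.0, 8.0
        z0 = -0.5
        z_img = 2 * z0 - d
        src = np.array([[0.0, 0.0, d]])
        X, Y, Z = grid.coords()
        r_src = np.maximum(np.sqrt(X**2 + Y**2 + (Z - d) ** 2), 0.5)
        r_img = np.maximum(np.sqrt(X**2 + Y**2 + (Z - z_img) ** 2), 0.5)
        q_img = (e1 - e2) / (e1 + e2)
        phi_exact = np.where(Z >= z0, KE / e1 * (1 / r_src + q_img / r_img),
                             KE * 2 / ((e1 + e2) * r_src))
        pot_int = solve_linearized_poisson(
            src, [1.0], planar_interface_dielectric(grid, e1, e2),
            tolerance=1e-10, boundary_potential=phi_exact)
        pot_hom = solve_linearized_poisson(
            src, [1.0], uniform_dielectric(grid, e1), tolerance=1e-10,
            eps_boundary=e1)
        for probe in [(0.0, 0.0, 16.0), (6.0, 0.0, 10.0), (0.0, 4.0, 6.0)]:
            num = (interpolate_potential(pot_int, probe)
                   - interpolate_potential(pot_hom, probe))
            r_i = np.linalg.norm(np.asarray(probe) - [0.0, 0.0, z_img])
            exact = KE * q_img / (e1 * r_i)
            assert num == pytest.approx(exact, rel=0.05)

    def test_born_monotonicity_diagnostic(self):
        """The reaction potential at a cation grows less favorable as it
        approaches the low-dielectric membrane slab from bulk."""
        grid = GridSpec(n=41, spacing=1.0)
        reactions = []
        for z in (18.0, 15.0, 12.0):
            diel = build_dielectric_map(
                NO_ATOMS, [],
                RegionSpec(membrane_thickness=20.0, pore_cylinder_radius=1.0,
                           pore_cylinder_height=20.0), grid)
            hom = uniform_dielectric(grid, 80.0)
            p_het = solve_linearized_poisson([[0.0, 0.0, z]], [1.0], diel,
                                             tolerance=1e-10, eps_boundary=80.0)
            p_hom = solve_linearized_poisson([[0.0, 0.0, z]], [1.0], hom,
                                             tolerance=1e-10, eps_boundary=80.0)
            reactions.append(interpolate_potential(p_het, (0.0, 0.0, z))
                             - interpolate_potential(p_hom, (0.0, 0.0, z)))
        assert reactions[0] < reactions[1] < reactions[2]


class TestIonProteinEnergy:
    def test_zero_charge_zero_energy(self):
        grid = GridSpec(n=17, spacing=1.0)
        pot = solve_linearized_poisson([[0.0, 0.0, 0.0]], [1.0],
                                       uniform_dielectric(grid, 80.0))
        assert ion_protein_energy(0.0, pot, (3.0, 0.0, 0.0)) == 0.0

    def test_linear_in_ion_charge(self):
        grid = GridSpec(n=17, spacing=1.0)
        pot = solve_linearized_poisson([[0.0, 0.0, 0.0]], [1.0],
                                       uniform_dielectric(grid, 80.0))
        e1 = ion_protein_energy(1.0, pot, (3.0, 0.0, 0.0))
        e2 = ion_protein_energy(2.0, pot, (3.0, 0.0, 0.0))
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_position_outside_grid(self):
        grid = GridSpec(n=17, spacing=1.0)
        pot = solve_linearized_poisson(NO_ATOMS, [], uniform_dielectric(grid, 80.0))
        with pytest.raises(ValueError):
            ion_protein_energy(1.0, pot, (100.0, 0.0, 0.0))

    def test_cation_attracted_to_negative_charge(self):
        """A cation near a fixed negative protein charge has E < 0, most
        negative at closest approach."""
        grid = GridSpec(n=33, spacing=1.0)
        region = RegionSpec(membrane_thickness=10.0, pore_cylinder_radius=6.0,
                            pore_cylinder_height=10.0)
        energies = ion_energy_for_frame(
            [[0.0, 6.0, 0.0]], [-1.0], [1.7],
            [[0.0, 0.0, -8.0], [0.0, 0.0, -4.0], [0.0, 0.0, 0.0]], 1.0,
            region, grid, tolerance=1e-9)
        assert np.all(energies < 0)
        assert energies[2] < energies[1] < energies[0]


class TestEnergyProfile:
    def test_neutral_protein_zero_profile(self):
        from permeon.electrostatics import electrostatic_energy_profile
        from permeon.profiles import uniform_bins
        from permeon.reweight import snapshot_weights
        from conftest import make_frame, make_protein
        from test_reweight import FLAT

        grid = GridSpec(n=25, spacing=1.0)
        region = RegionSpec(membrane_thickness=8.0, pore_cylinder_radius=4.0,
                            pore_cylinder_height=8.0)
        frames = [make_frame([[0.0, 0.0, z]],
                             protein=make_protein([[0.0, 5.0, 0.0]],
                                                  charges=[0.0]))
                  for z in (-4.0, 0.0, 4.0)]
        ion_z = np.array([[-4.0], [0.0], [4.0]])
        ion_R = np.zeros_like(ion_z)
        w = snapshot_weights(np.ones((3, 2)), FLAT, 298.0)
        prof = electrostatic_energy_profile(frames, ion_z, ion_R, w,
                                            uniform_bins(-6, 6, 2.0),
                                            region=region, grid=grid,
                                            tolerance=1e-8)
        np.testing.assert_allclose(prof.values[prof.defined], 0.0, atol=1e-8)

    def test_charge_ring_matches_compositional_oracle(self):
        """Profile equals per-frame lattice energies pushed through the
        reweighted-average oracle."""
        from permeon.electrostatics import electrostatic_energy_profile
        from permeon.profiles import uniform_bins
        from permeon.reweight import observable_profile, snapshot_weights
        from conftest import make_frame, make_protein
        from test_reweight import FLAT

        grid = GridSpec(n=29, spacing=1.0)
        region = RegionSpec(membrane_thickness=8.0, pore_cylinder_radius=5.0,
                            pore_cylinder_height=8.0)
        ring = [[6.0, 0.0, 0.0], [-6.0, 0.0, 0.0], [0.0, 6.0, 0.0], [0.0, -6.0, 0.0]]
        charges = [-0.5, -0.5, -0.5, -0.5]
        z_positions = [[-5.0, 3.0], [-1.0, 6.0]]
        frames = [make_frame([[0.0, 0.0, za], [0.0, 0.0, zb]],
                             protein=make_protein(ring, charges=charges))
                  for za, zb in z_positions]
        ion_z = np.array(z_positions)
        ion_R = np.zeros_like(ion_z)
        w = snapshot_weights(np.ones((2, 2)), FLAT, 298.0)
        bins = uniform_bins(-8, 8, 2.0)
        prof = electrostatic_energy_profile(frames, ion_z, ion_R, w, bins,
                                            region=region, grid=grid,
                                            tolerance=1e-9)
        # oracle: independent per-frame energy evaluation + explicit averaging
        obs = np.stack([ion_energy_for_frame(ring, charges, [1.7] * 4,
                                             fr.ion_positions, 1.0, region,
                                             grid, tolerance=1e-9)
                        for fr in frames])
        oracle = observable_profile(obs, ion_z, ion_R, w, bins)
        np.testing.assert_allclose(prof.values[prof.defined],
                                   oracle.values[oracle.defined], rtol=1e-9)
        assert np.all(prof.values[prof.defined] < 0)
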