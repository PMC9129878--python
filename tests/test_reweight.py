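"""Snapshot reweighting, occupancy/PMF/observable profiles, split-half."""

import numpy as np
import pytest

from permeon.constants import kT
from permeon.metadynamics import BiasGrid, EffectiveBias
from permeon.profiles import uniform_bins
from permeon.reweight import (observable_profile, occupancy_profile,
                              pmf_from_occupancy, snapshot_weights,
                              split_half_profiles)


def bias_from_array(values_fn):
    grid = BiasGrid(zeta_min=-2.0, zeta_max=12.0, spacing=0.1)
    A, B = np.meshgrid(grid.axis, grid.axis, indexing="ij")
    grid.values = values_fn(A, B)
    return EffectiveBias(grid, (0.0, 1.0))


FLAT = bias_from_array(lambda A, B: np.zeros_like(A))
T = 298.0


class TestSnapshotWeights:
    def test_constant_bias_uniform_weights(self, rng):
        cv = rng.uniform(0, 10, size=(40, 2))
        w = snapshot_weights(cv, FLAT, T)
        np.testing.assert_allclose(w.weights, 1 / 40, rtol=1e-12)

    def test_kt_ln2_gives_ratio_two(self):
        eb = bias_from_array(lambda A, B: np.where(A > 5, kT(T) * np.log(2), 0.0))
        w = snapshot_weights([(8.0, 8.0), (2.0, 2.0)], eb, T)
        assert w.weights[0] / w.weights[1] == pytest.approx(2.0, rel=1e-9)

    def test_matches_formula_oracle(self, rng):
        eb = bias_from_array(lambda A, B: np.sin(A) + 0.3 * B)
        cv = rng.uniform(0, 10, size=(25, 2))
        w = snapshot_weights(cv, eb, T)
        v = eb.grid.value_at(cv[:, 0], cv[:, 1])
        expected = np.exp(v / kT(T))
        expected /= expected.sum()
        np.testing.assert_allclose(w.weights, expected, rtol=1e-10)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            snapshot_weights(np.empty((0, 2)), FLAT, T)

    def test_offset_invariance(self, rng):
        """Adding a constant to the effective bias changes no weight."""
        eb1 = bias_from_array(lambda A, B: 0.2 * A)
        eb2 = bias_from_array(lambda A, B: 0.2 * A + 7.7)
        cv = rng.uniform(0, 10, size=(30, 2))
        np.testing.assert_allclose(snapshot_weights(cv, eb1, T).weights,
                                   snapshot_weights(cv, eb2, T).weights,
                                   rtol=1e-10)


class TestOccupancyProfile:
    def test_single_fixed_ion(self):
        bins = uniform_bins(-5, 5, 0.5)
        w = snapshot_weights(np.ones((10, 2)), FLAT, T)
        ion_z = np.zeros((10, 1))
        ion_R = np.zeros((10, 1))
        prof = occupancy_profile(ion_z, ion_R, w, bins)
        center_bin = np.digitize(0.0, prof.edges()) - 1
        assert prof.values.sum() == pytest.approx(1.0)
        assert prof.values[center_bin] == pytest.approx(1.0)

    def test_far_from_axis_excluded(self):
        bins = uniform_bins(-5, 5, 0.5)
        w = snapshot_weights(np.ones((4, 2)), FLAT, T)
        prof = occupancy_profile(np.zeros((4, 1)), np.full((4, 1), 12.0), w,
                                 bins, R0=10.0)
        assert prof.values.sum() == 0.0

    def test_uniform_cylinder_is_flat(self, rng):
        bins = uniform_bins(-10, 10, 1.0)
        n_snap, n_ions = 400, 10
        ion_z = rng.uniform(-10, 10, size=(n_snap, n_ions))
        ion_R = rng.uniform(0, 5, size=(n_snap, n_ions))
        w = snapshot_weights(np.ones((n_snap, 2)), FLAT, T)
        prof = occupancy_profile(ion_z, ion_R, w, bins)
        # each in-bin ion contributes w = 1/n_snap: raw counts are values*n_snap
        counts = prof.values * n_snap
        expected = n_snap * n_ions / bins.size
        sigma = np.sqrt(expected)
        assert np.all(np.abs(counts - expected) < 4 * sigma)


class TestPmf:
    def test_two_bin_ratio_gives_kt(self):
        bins = uniform_bins(0, 1, 0.5)
        from permeon.profiles import Profile
        occ = Profile(bins, np.array([1.0, np.exp(-1)]), np.array([1.0, np.exp(-1)]))
        pmf = pmf_from_occupancy(occ, T, anchor_region=((0.0, 0.3),))
        dF = pmf.values[1] - pmf.values[0]
        assert dF == pytest.approx(kT(T), rel=1e-9)
        assert kT(T) == pytest.approx(0.592, abs=5e-4)

    def test_flat_occupancy_zero_after_anchoring(self):
        bins = uniform_bins(-5, 5, 0.5)
        from permeon.profiles import Profile
        occ = Profile(bins, np.full(bins.size, 0.05), np.full(bins.size, 0.05))
        pmf = pmf_from_occupancy(occ, T, anchor_region=((-5.0, 5.0),))
        np.testing.assert_allclose(pmf.values, 0.0, atol=1e-12)

    def test_all_zero_errors(self):
        bins = uniform_bins(-5, 5, 0.5)
        from permeon.profiles import Profile
        occ = Profile(bins, np.zeros(bins.size), np.zeros(bins.size))
        with pytest.raises(ValueError):
            pmf_from_occupancy(occ, T)

    def test_unbiased_equals_boltzmann_histogram(self, rng):
        """With a constant bias the PMF is the naive Boltzmann estimate."""
        bins = uniform_bins(-5, 5, 1.0)
        ion_z = rng.normal(0, 3, size=(2000, 1))
        ion_R = np.zeros_like(ion_z)
        w = snapshot_weights(np.ones((2000, 2)), FLAT, T)
        occ = occupancy_profile(ion_z, ion_R, w, bins)
        pmf = pmf_from_occupancy(occ, T, anchor_region=((-5.0, 5.0),))
        counts, _ = np.histogram(ion_z[:, 0], bins=occ.edges())
        naive = -kT(T) * np.log(counts / counts.sum())
        rho = counts / counts.sum()
        naive -= np.sum(naive * rho) / rho.sum()
        np.testing.assert_allclose(pmf.values, naive, atol=1e-9)


class TestObservableProfile:
    def test_constant_observable(self, rng):
        bins = uniform_bins(-10, 10, 1.0)
        ion_z = rng.uniform(-10, 10, size=(100, 4))
        ion_R = np.zeros_like(ion_z)
        w = snapshot_weights(np.ones((100, 2)), FLAT, T)
        prof = observable_profile(np.full_like(ion_z, 3.3), ion_z, ion_R, w, bins)
        np.testing.assert_allclose(prof.values[prof.defined], 3.3, rtol=1e-12)

    def test_identity_observable_tracks_bin_centers(self, rng):
        bins = uniform_bins(-10, 10, 1.0)
        ion_z = rng.uniform(-10, 10, size=(3000, 4))
        ion_R = np.zeros_like(ion_z)
        w = snapshot_weights(np.ones((3000, 2)), FLAT, T)
        prof = observable_profile(ion_z, ion_z, ion_R, w, bins)
        d = prof.defined
        assert np.all(np.abs(prof.values[d] - prof.bin_centers[d]) <= 0.5)

    def test_matches_weighted_mean_oracle(self, rng):
        bins = uniform_bins(-10, 10, 2.0)
        n = 200
        ion_z = rng.uniform(-10, 10, size=(n, 3))
        ion_R = rng.uniform(0, 15, size=(n, 3))
        obs = rng.normal(size=(n, 3))
        eb = bias_from_array(lambda A, B: 0.4 * A)
        cv = rng.uniform(0, 10, size=(n, 2))
        w = snapshot_weights(cv, eb, T)
        prof = observable_profile(obs, ion_z, ion_R, w, bins, R0=10.0)
        edges = prof.edges()
        for b in range(bins.size):
            num = den = 0.0
            for i in range(n):
                for k in range(3):
                    if (ion_R[i, k] <= 10.0 and edges[b] <= ion_z[i, k] < edges[b + 1]):
                        num += w.weights[i] * obs[i, k]
                        den += w.weights[i]
            if den > 0:
                assert prof.values[b] == pytest.approx(num / den, rel=1e-9)
            else:
                assert np.isnan(prof.values[b])

    def test_shape_mismatch(self):
        w = snapshot_weights(np.ones((3, 2)), FLAT, T)
        with pytest.raises(ValueError):
            observable_profile(np.zeros((3, 2)), np.zeros((3, 3)),
                               np.zeros((3, 3)), w, uniform_bins(0, 1, 0.5))


class TestSplitHalf:
    def test_duplicated_halves_zero_difference(self, rng):
        n = 50
        ion_z = rng.uniform(-5, 5, size=(n, 2))
        times = np.arange(2 * n, dtype=float)
        ion_z2 = np.vstack([ion_z, ion_z])
        ion_R = np.zeros_like(ion_z2)
        cv = np.ones((2 * n, 2))
        _, _, diff = split_half_profiles(times, cv, ion_z2, ion_R, FLAT,
                                         uniform_bins(-5, 5, 1.0), temperature=T,
                                         anchor_region=((-5.0, 5.0),))
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_constant_observable_difference(self):
        times = np.arange(20.0)
        ion_z = np.zeros((20, 1))
        ion_R = np.zeros((20, 1))
        cv = np.ones((20, 2))
        obs = np.concatenate([np.full((10, 1), 2.0), np.full((10, 1), 5.0)])
        _, _, diff = split_half_profiles(times, cv, ion_z, ion_R, FLAT,
                                         uniform_bins(-1, 1, 0.5), temperature=T,
                                         observable=obs)
        assert diff == pytest.approx(3.0, abs=1e-12)

    def test_single_snapshot_errors(self):
        with pytest.raises(ValueError):
            split_half_profiles([0.0], np.ones((1, 2)), np.zeros((1, 1)),
                                np.zeros((1, 1)), FLAT, uniform_bins(-1, 1, 0.5))
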