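import numpy as np
import pytest

from permeon.geometry import ProteinAtoms, Species, TrajectoryFrame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_frame(ion_positions, species=None, waters=None, protein=None,
               box=(200.0, 200.0, 200.0), time=0.0, index=0):
    ion_positions = np.atleast_2d(np.asarray(ion_positions, dtype=float))
    if species is None:
        species = [Species.K] * ion_positions.shape[0]
    return TrajectoryFrame(
        frame_index=index, time=time, box_lengths=np.asarray(box),
        ion_positions=ion_positions, ion_species=species,
        water_oxygen_positions=np.empty((0, 3)) if waters is None else waters,
        protein=protein)


def make_protein(positions, charges=None, radii=None, names=None,
                 resids=None, elements=None):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    return ProteinAtoms(
        resids=np.arange(1, n + 1) if resids is None else np.asarray(resids),
        names=np.array(["CA"] * n) if names is None else np.asarray(names),
        elements=np.array(["C"] * n) if elements is None else np.asarray(elements),
        charges=np.zeros(n) if charges is None else np.asarray(charges, dtype=float),
        radii=np.full(n, 1.7) if radii is None else np.asarray(radii, dtype=float),
        positions=positions)


@pytest.fixture(scope="session")
def full_toy_pmf():
    """The full-scale desk pipeline: 8 walkers x 625k steps (5e6 total).

    Shared by the end-to-end recovery and split-half convergence checks;
    runs once per session (several minutes).
    """
    from permeon.pipeline import run_toy_metadynamics_pmf

    return run_toy_metadynamics_pmf(n_walkers=8, n_steps=625_000, seed=1)
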