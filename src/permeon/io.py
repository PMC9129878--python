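"""Trajectory and tabular I/O.

Standard MD formats (PDB/GRO topology plus DCD/XTC/XYZ coordinates) are read
through MDAnalysis; the toy simulator emits a plain tabular trajectory
(TSV: frame, time_ps, species, x, y, z) that round-trips losslessly at 10
significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import ProteinAtoms, Species, TrajectoryFrame

# --------------------------------------------------------------------------
# internal tabular trajectory format (toy-simulator output)

_TRAJ_COLUMNS = ["frame", "time_ps", "species", "x", "y", "z"]


def write_tabular_trajectory(path, frames: list[TrajectoryFrame]) -> None:
    rows = []
    for fr in frames:
        for pos, sp in zip(fr.ion_positions, fr.ion_species):
            rows.append((fr.frame_index, fr.time, sp.value, *pos))
    with open(path, "w") as fh:
        box = frames[0].box_lengths if frames else np.ones(3)
        fh.write(f"# box: {box[0]:.10g} {box[1]:.10g} {box[2]:.10g}\n")
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for row in rows:
            fh.write(f"{row[0]}\t{row[1]:.10g}\t{row[2]}\t"
                     f"{row[3]:.10g}\t{row[4]:.10g}\t{row[5]:.10g}\n")


def read_tabular_trajectory(path) -> list[TrajectoryFrame]:
    box = np.ones(3)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# box:"):
            box = np.array([float(x) for x in first.split(":")[1].split()])
    df = pd.read_csv(path, sep="\t", comment="#")
    frames = []
    for idx, grp in df.groupby("frame", sort=True):
        frames.append(TrajectoryFrame(
            frame_index=int(idx),
            time=float(grp["time_ps"].iloc[0]),
            box_lengths=box,
            ion_positions=grp[["x", "y", "z"]].to_numpy(),
            ion_species=[Species(s) for s in grp["species"]],
        ))
    return frames


# --------------------------------------------------------------------------
# standard MD formats via MDAnalysis

_SPECIES_BY_NAME = {
    "K": Species.K, "POT": Species.K, "K+": Species.K,
    "NA": Species.NA, "SOD": Species.NA, "NA+": Species.NA,
    "CS": Species.CS, "CES": Species.CS, "CS+": Species.CS,
}


def iter_md_frames(topology, trajectory=None, *,
                   ion_selection="name K POT NA SOD CS CES",
                   water_oxygen_selection="name OW OH2",
                   protein_selection="protein",
                   default_radius=1.7):
    """Yield :class:`TrajectoryFrame` objects from standard MD files.

    Partial charges and radii are taken from the topology when present and
    default to zero / ``default_radius`` otherwise (plain PDB carries
    neither).
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    ions = u.select_atoms(ion_selection)
    waters = u.select_atoms(water_oxygen_selection)
    prot = u.select_atoms(protein_selection)

    species = []
    for name in ions.names:
        key = name.strip().upper()
        if key not in _SPECIES_BY_NAME:
            raise ValueError(f"unrecognized ion atom name {name!r}")
        species.append(_SPECIES_BY_NAME[key])

    def _attr(group, name, default):
        try:
            return np.asarray(getattr(group, name), dtype=float)
        except (AttributeError, mda.exceptions.NoDataError):
            return np.full(len(group), default, dtype=float)

    for ts in u.trajectory:
        box = ts.dimensions[:3] if ts.dimensions is not None else np.full(3, 1e6)
        protein = None
        if len(prot):
            try:
                elements = np.asarray(prot.elements)
            except (AttributeError, mda.exceptions.NoDataError):
                elements = np.array([n.strip()[:1] for n in prot.names])
            protein = ProteinAtoms(
                resids=np.asarray(prot.resids),
                names=np.asarray(prot.names),
                elements=elements,
                charges=_attr(prot, "charges", 0.0),
                radii=_attr(prot, "radii", default_radius),
                positions=prot.positions.astype(float),
            )
        yield TrajectoryFrame(
            frame_index=int(ts.frame),
            time=float(ts.time),
            box_lengths=np.asarray(box, dtype=float),
            ion_positions=ions.positions.astype(float),
            ion_species=list(species),
            water_oxygen_positions=waters.positions.astype(float),
            protein=protein,
        )
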