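"""Binned profiles along the pore axis and their text I/O.

A :class:`Profile` holds any per-bin quantity along z — ion occupancy, free
energy, hydration number, electrostatic energy — together with the summed
statistical weight ("effective counts") behind each bin.  Bins with zero
effective count are *masked* (value NaN), never zero-filled.

The on-disk format is TSV with ``# key: value`` header lines followed by the
columns ``z_center  value  effective_count``; values are written with 10
significant digits so a write/read round trip is bit-stable at that
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SPACING_RTOL = 1e-9


@dataclass
class Profile:
    """A quantity binned along the pore axis.

    Parameters
    ----------
    bin_centers
        Uniformly spaced, strictly increasing bin centers in Å.
    values
        Per-bin quantity; NaN marks masked (undefined) bins.
    effective_counts
        Per-bin summed statistical weight (>= 0).
    metadata
        Free-form annotations (quantity name, units, r0, ...).
    """

    bin_centers: np.ndarray
    values: np.ndarray
    effective_counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.effective_counts = np.asarray(self.effective_counts, dtype=float)
        n = self.bin_centers.size
        if self.values.shape != (n,) or self.effective_counts.shape != (n,):
            raise ValueError("bin_centers, values, effective_counts must have equal length")
        if n >= 2:
            d = np.diff(self.bin_centers)
            if np.any(d <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if np.max(np.abs(d - d[0])) > _SPACING_RTOL * max(1.0, abs(d[0])):
                raise ValueError("bin spacing must be uniform")
        if np.any(self.effective_counts < 0):
            raise ValueError("effective_counts must be >= 0")

    @property
    def spacing(self) -> float:
        if self.bin_centers.size < 2:
            raise ValueError("spacing undefined for a single bin")
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of bins with a defined (non-NaN) value."""
        return ~np.isnan(self.values)

    def edges(self) -> np.ndarray:
        """Bin edges implied by the uniform centers."""
        h = self.spacing
        return np.concatenate([self.bin_centers - h / 2, [self.bin_centers[-1] + h / 2]])


def uniform_bins(z_min: float, z_max: float, width: float) -> np.ndarray:
    """Uniform bin centers covering [z_min, z_max] with the given bin width."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    n = int(round((z_max - z_min) / width))
    return z_min + width * (np.arange(n) + 0.5)


def write_profile(path, profile: Profile) -> None:
    with open(path, "w") as fh:
        for key, val in profile.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: z_center\tvalue\teffective_count\n")
        for z, v, c in zip(profile.bin_centers, profile.values, profile.effective_counts):
            fh.write(f"{z:.10g}\t{v:.10g}\t{c:.10g}\n")


def read_profile(path) -> Profile:
    metadata = {}
    centers, values, counts = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    if key.strip() != "columns":
                        metadata[key.strip()] = val.strip()
                continue
            z, v, c = line.split("\t")
            centers.append(float(z))
            values.append(float(v))
            counts.append(float(c))
    return Profile(np.array(centers), np.array(values), np.array(counts), metadata)
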