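"""Post-hoc reweighting of metadynamics trajectories and profile estimators.

Each snapshot X_i gets a statistical weight proportional to
exp(V̄(ζA_i, ζB_i)/k_B T), where V̄ is the time-averaged bias: snapshots
sampled where the accumulated bias is large sit in regions that are easy
only because of the bias, and are up-weighted to undo it.  Occupancy
profiles ρ(z_α) sum those weights over ions that fall in bin α within R0 of
the pore axis; the free-energy profile is F = −k_B T ln ρ up to a constant
chosen so F ≈ 0 in bulk, and reweighted observable profiles divide the
weighted observable sum by ρ.

Array conventions: snapshot-major.  ``ion_z``/``ion_R``/observables are
(n_snapshots, n_ions) arrays; weights are (n_snapshots,).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import kT
from .metadynamics import EffectiveBias
from .profiles import Profile

logger = logging.getLogger(__name__)

DEFAULT_R0 = 10.0  # Å, pore-cylinder radius for occupancy restriction


@dataclass
class SnapshotWeightTable:
    weights: np.ndarray          # (n_snapshots,), sums to 1
    temperature: float           # K
    source_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-12 * max(1, self.weights.size):
            raise ValueError("weights must sum to 1")

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class FreeEnergyProfile(Profile):
    anchor_region: tuple = ((-40.0, -30.0), (30.0, 40.0))
    offset: float = 0.0  # the constant C' subtracted during anchoring


def snapshot_weights(cv_pairs, effective_bias: EffectiveBias,
                     temperature: float = 298.0) -> SnapshotWeightTable:
    """Snapshot weights w(X_i) ∝ exp(V̄(ζA_i, ζB_i)/k_B T), normalized.

    The bias is looked up by nearest grid cell; CV values outside the grid
    are clamped to its edge with a logged warning.
    """
    cv = np.asarray(cv_pairs, dtype=float).reshape(-1, 2)
    if cv.shape[0] == 0:
        raise ValueError("empty snapshot set")
    grid = effective_bias.grid
    out = ((cv < grid.zeta_min) | (cv > grid.zeta_max)).any(axis=1)
    if out.any():
        logger.warning("%d/%d CV pairs outside the bias grid were clamped",
                       int(out.sum()), cv.shape[0])
    log_w = grid.value_at(cv[:, 0], cv[:, 1]) / kT(temperature)
    log_w -= logsumexp(log_w)
    return SnapshotWeightTable(np.exp(log_w), temperature)


def _in_pore(ion_R: np.ndarray, R0: float) -> np.ndarray:
    return np.asarray(ion_R, dtype=float) <= R0


def occupancy_profile(ion_z, ion_R, weights: SnapshotWeightTable,
                      bin_centers, R0: float = DEFAULT_R0) -> Profile:
    """Reweighted ion occupancy ρ(z_α): per-bin sum of snapshot weights.

    Every ion of a snapshot that lies in bin α and within R0 of the axis
    contributes that snapshot's weight to bin α (and to no other bin).
    """
    ion_z = np.asarray(ion_z, dtype=float)
    ion_R = np.asarray(ion_R, dtype=float)
    prof = Profile(np.asarray(bin_centers, dtype=float),
                   np.zeros(len(bin_centers)), np.zeros(len(bin_centers)))
    edges = prof.edges()
    keep = _in_pore(ion_R, R0)
    w_per_ion = np.broadcast_to(weights.weights[:, None], ion_z.shape)[keep]
    rho, _ = np.histogram(ion_z[keep], bins=edges, weights=w_per_ion)
    prof.values = rho.astype(float)
    prof.effective_counts = rho.astype(float)
    prof.metadata = {"quantity": "ion occupancy", "units": "probability", "R0": R0}
    return prof


def pmf_from_occupancy(occupancy: Profile, temperature: float = 298.0,
                       anchor_region=((-40.0, -30.0), (30.0, 40.0))) -> FreeEnergyProfile:
    """Free-energy profile F(z) = −k_B T ln ρ(z) + C′.

    C′ anchors the occupancy-weighted mean of F over the bulk anchor region
    to zero; bins with zero occupancy are masked (NaN), never zero-filled.
    """
    rho = occupancy.values
    if not np.any(rho > 0):
        raise ValueError("occupancy is zero everywhere")
    kt = kT(temperature)
    with np.errstate(divide="ignore"):
        F = np.where(rho > 0, -kt * np.log(np.where(rho > 0, rho, 1.0)), np.nan)
    z = occupancy.bin_centers
    regions = anchor_region if hasattr(anchor_region[0], "__len__") else (anchor_region,)
    in_anchor = np.zeros(z.size, dtype=bool)
    for lo, hi in regions:
        in_anchor |= (z >= lo) & (z <= hi)
    usable = in_anchor & (rho > 0)
    if not usable.any():
        raise ValueError("anchor region contains no bin with nonzero occupancy")
    offset = float(np.sum(F[usable] * rho[usable]) / np.sum(rho[usable]))
    return FreeEnergyProfile(
        bin_centers=z, values=F - offset, effective_counts=occupancy.effective_counts,
        metadata={"quantity": "free energy", "units": "kcal/mol",
                  "temperature_K": temperature},
        anchor_region=tuple(tuple(r) for r in regions), offset=offset)


def observable_profile(observable, ion_z, ion_R, weights: SnapshotWeightTable,
                       bin_centers, R0: float = DEFAULT_R0,
                       quantity: str = "observable", units: str = "") -> Profile:
    """Reweighted mean of a per-ion observable along z (masked where ρ = 0)."""
    obs = np.asarray(observable, dtype=float)
    ion_z = np.asarray(ion_z, dtype=float)
    ion_R = np.asarray(ion_R, dtype=float)
    if obs.shape != ion_z.shape or ion_z.shape != ion_R.shape:
        raise ValueError("observable, ion_z, ion_R must share one shape")
    prof = Profile(np.asarray(bin_centers, dtype=float),
                   np.zeros(len(bin_centers)), np.zeros(len(bin_centers)))
    edges = prof.edges()
    keep = _in_pore(ion_R, R0)
    w_per_ion = np.broadcast_to(weights.weights[:, None], ion_z.shape)[keep]
    rho, _ = np.histogram(ion_z[keep], bins=edges, weights=w_per_ion)
    num, _ = np.histogram(ion_z[keep], bins=edges, weights=w_per_ion * obs[keep])
    with np.errstate(invalid="ignore"):
        values = np.where(rho > 0, num / np.where(rho > 0, rho, 1.0), np.nan)
    prof.values = values
    prof.effective_counts = rho
    prof.metadata = {"quantity": quantity, "units": units, "R0": R0}
    return prof


def split_half_profiles(times, cv_pairs, ion_z, ion_R, effective_bias: EffectiveBias,
                        bin_centers, *, temperature: float = 298.0,
                        R0: float = DEFAULT_R0, observable=None,
                        anchor_region=((-40.0, -30.0), (30.0, 40.0))):
    """Profiles from the first and second temporal halves, plus their gap.

    Weights are recomputed and renormalized within each half.  Returns
    ``(profile_first, profile_second, mean_abs_difference)`` where the
    difference is averaged over bins defined in both halves.  ``observable``
    selects the reweighted-observable profile; by default the free-energy
    profile is compared.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two snapshots to split")
    cv = np.asarray(cv_pairs, dtype=float).reshape(-1, 2)
    ion_z = np.asarray(ion_z, dtype=float)
    ion_R = np.asarray(ion_R, dtype=float)
    order = np.argsort(times, kind="stable")
    halves = np.array_split(order, 2)

    def build(idx):
        w = snapshot_weights(cv[idx], effective_bias, temperature)
        if observable is None:
            occ = occupancy_profile(ion_z[idx], ion_R[idx], w, bin_centers, R0)
            return pmf_from_occupancy(occ, temperature, anchor_region)
        obs = np.asarray(observable, dtype=float)
        return observable_profile(obs[idx], ion_z[idx], ion_R[idx], w, bin_centers, R0)

    first, second = build(halves[0]), build(halves[1])
    shared = first.defined & second.defined
    if not shared.any():
        raise ValueError("no bin is defined in both halves")
    diff = float(np.mean(np.abs(first.values[shared] - second.values[shared])))
    return first, second, diff
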