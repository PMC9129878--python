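"""End-to-end toy-pore pipeline: metadynamics → reweighting → PMF → conductance.

This is the desk-scale analogue of the production workflow: run multiple
metadynamics walkers on the toy pore, time-average the shared bias over a
late (approximately stationary) window, reweight the pooled snapshots, and
histogram the ions into a bulk-anchored free-energy profile that can be fed
to the conductance integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metadynamics import effective_bias_from_hills
from .profiles import uniform_bins
from .reweight import (FreeEnergyProfile, occupancy_profile, pmf_from_occupancy,
                       snapshot_weights, split_half_profiles)
from .synthetic import ToyPoreParams, ToyRun, analytic_toy_pmf, simulate_toy_pore

DEFAULT_ANCHOR = ((-40.0, -30.0), (30.0, 40.0))


@dataclass
class ToyPmfResult:
    run: ToyRun
    pmf: FreeEnergyProfile
    pmf_true: np.ndarray          # analytic PMF on the same bins
    rms_error: float              # kcal/mol over the comparison range
    split_half_gap: float         # mean |ΔF| between temporal halves


def reweighted_pmf_from_run(run: ToyRun, *, window: tuple[float, float],
                            bin_width: float = 0.5, R0: float = 10.0,
                            anchor_region=DEFAULT_ANCHOR,
                            compare_range: float = 20.0) -> ToyPmfResult:
    """Reweight a biased toy run into a PMF and score it against ground truth."""
    p = run.params
    bins = uniform_bins(-p.box_z / 2, p.box_z / 2, bin_width)
    eb = effective_bias_from_hills(run.hills, window, grid=run.bias)
    times, cv, ion_z, ion_R = run.pooled(window[0], window[1])
    weights = snapshot_weights(cv, eb, p.temperature)
    occ = occupancy_profile(ion_z, ion_R, weights, bins, R0)
    pmf = pmf_from_occupancy(occ, p.temperature, anchor_region)

    truth = analytic_toy_pmf(p, bins, anchor_region).pmf.values
    sel = (np.abs(pmf.bin_centers) <= compare_range) & pmf.defined
    if not sel.any():
        raise ValueError("no defined bins inside the comparison range")
    rms = float(np.sqrt(np.mean((pmf.values[sel] - truth[sel]) ** 2)))

    _, _, gap = split_half_profiles(times, cv, ion_z, ion_R, eb, bins,
                                    temperature=p.temperature, R0=R0,
                                    anchor_region=anchor_region)
    return ToyPmfResult(run, pmf, truth, rms, gap)


def truncate_run(run: ToyRun, t_max: float) -> ToyRun:
    """The same run as if it had been stopped at time t_max (ps)."""
    keep = run.times <= t_max
    return ToyRun(run.params, run.times[keep], run.ion_z[keep], run.ion_R[keep],
                  run.cv[keep], [h for h in run.hills if h.time <= t_max],
                  run.bias, run.seed, run.n_walkers)


def run_toy_metadynamics_pmf(params: ToyPoreParams = ToyPoreParams(), *,
                             n_walkers: int = 8, n_steps: int = 625_000,
                             seed: int = 1, sample_every: int = 20,
                             window_fraction: float = 0.6,
                             bin_width: float = 0.5) -> ToyPmfResult:
    """Run the full desk-scale pipeline (default: 5e6 total Brownian steps)."""
    run = simulate_toy_pore(params, n_steps=n_steps, n_walkers=n_walkers,
                            seed=seed, sample_every=sample_every,
                            metadynamics=True)
    t_end = float(run.times[-1])
    window = ((1.0 - window_fraction) * t_end, t_end)
    return reweighted_pmf_from_run(run, window=window, bin_width=bin_width)
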