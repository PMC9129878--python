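"""Free-energy perturbation analysis of K+/Na+ selectivity.

Per-window free energies use one-sided exponential averaging,
ΔG_i = −k_B T ln ⟨exp(−ΔU/k_B T)⟩ (log-sum-exp stabilized), accumulated
along the λ schedule into a ΔG(λ) curve.  Sampling error is gauged by the
hysteresis between forward (K+→Na+) and backward (Na+→K+) transformations;
the selectivity of a site is the differential ΔΔG = ΔG_bulk − ΔG_site
between the same alchemical exchange performed in bulk water and at the
site, with exp(ΔΔG/k_B T) the implied fold-preference for K+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kT

_LAMBDA_TOL = 1e-9


def fep_schedule(context: str = "pore") -> np.ndarray:
    """λ values for a context: 0.04 steps then finer 0.02 steps near λ = 1.

    bulk: 0.04 on [0, 0.8], 0.02 on [0.8, 1] (30 windows);
    pore: 0.04 on [0, 0.96], 0.02 on [0.96, 1] (26 windows).
    """
    if context == "bulk":
        coarse_end = 0.8
    elif context == "pore":
        coarse_end = 0.96
    else:
        raise ValueError(f"unknown FEP context {context!r}")
    lam = np.concatenate([np.arange(0.0, coarse_end - 1e-12, 0.04),
                          np.arange(coarse_end, 1.0 + 1e-12, 0.02)])
    lam[-1] = 1.0
    return np.round(lam, 10)


@dataclass
class FepWindowSamples:
    window_index: int
    lambda_from: float
    lambda_to: float
    delta_u: np.ndarray           # kcal/mol, samples of U(λ_to) − U(λ_from)
    equilibration_discarded: int = 0
    restraint_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delta_u = np.atleast_1d(np.asarray(self.delta_u, dtype=float))
        if self.delta_u.size < 1:
            raise ValueError("window needs at least one retained sample")
        if abs(self.lambda_from - self.lambda_to) < _LAMBDA_TOL:
            raise ValueError("lambda_from and lambda_to must differ")


@dataclass
class FepResult:
    lambdas: np.ndarray           # λ grid including both endpoints
    cumulative: np.ndarray        # ΔG(λ) from the curve's own start, kcal/mol
    direction: str                # 'forward' (λ 0→1) | 'backward' (λ 1→0)
    temperature: float

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if abs(self.cumulative[0]) > 1e-12:
            raise ValueError("cumulative curve must start at 0")

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])


def fep_delta_g(windows: list[FepWindowSamples], temperature: float = 298.0) -> FepResult:
    """Exponential-average ΔG over a sequence of λ windows tiling [0, 1]."""
    if not windows:
        raise ValueError("no windows supplied")
    windows = sorted(windows, key=lambda w: w.window_index)
    lam = [windows[0].lambda_from]
    for w in windows:
        if abs(w.lambda_from - lam[-1]) > _LAMBDA_TOL:
            raise ValueError(f"gap or overlap in λ coverage at window {w.window_index}: "
                             f"expected λ_from={lam[-1]}, got {w.lambda_from}")
        lam.append(w.lambda_to)
    forward = lam[-1] > lam[0]
    if not ({min(lam), max(lam)} == {0.0, 1.0}):
        raise ValueError("windows must tile [0, 1]")

    kt = kT(temperature)
    dg = []
    for w in windows:
        n = w.delta_u.size
        dg.append(-kt * (logsumexp(-w.delta_u / kt) - np.log(n)))
    cumulative = np.concatenate([[0.0], np.cumsum(dg)])
    return FepResult(np.array(lam), cumulative,
                     "forward" if forward else "backward", temperature)


def hysteresis(forward: FepResult, backward: FepResult) -> float:
    """Max |disagreement| (kcal/mol) between forward and backward ΔG(λ) curves.

    The backward curve, accumulated from λ = 1, implies a forward curve
    ΔG_fwd(1) + ΔG_bwd(λ); the hysteresis is the largest absolute gap to
    the measured forward curve on the union λ grid (linear interpolation).
    Zero for perfectly consistent runs.
    """
    if forward.direction != "forward" or backward.direction != "backward":
        raise ValueError("pass one forward and one backward result")
    if abs(forward.temperature - backward.temperature) > 1e-9:
        raise ValueError("mismatched temperatures")
    for res in (forward, backward):
        if {res.lambdas[0], res.lambdas[-1]} != {0.0, 1.0}:
            raise ValueError("curves must span [0, 1]")
    grid = np.union1d(forward.lambdas, backward.lambdas)
    f = np.interp(grid, forward.lambdas, forward.cumulative)
    # backward λ axis is decreasing; flip for interpolation
    b = np.interp(grid, backward.lambdas[::-1], backward.cumulative[::-1])
    implied = forward.total + b
    return float(np.max(np.abs(f - implied)))


def selectivity_differential(delta_g_site: float, delta_g_bulk: float,
                             temperature: float = 298.0) -> tuple[float, float]:
    """Site-vs-bulk selectivity: ΔΔG = ΔG_bulk − ΔG_site and its fold-preference.

    Positive ΔΔG means the site disfavors the K+→Na+ exchange more than bulk
    water does, i.e. the site is K+-selective relative to bulk; the fold
    preference is exp(ΔΔG/k_B T).
    """
    ddg = delta_g_bulk - delta_g_site
    return ddg, float(np.exp(ddg / kT(temperature)))


# --------------------------------------------------------------------------
# tabular I/O: window_index, lambda_from, lambda_to, delta_u_kcal

def read_fep_samples(path) -> list[FepWindowSamples]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    windows = []
    for (idx, lf, lt), grp in df.groupby(
            ["window_index", "lambda_from", "lambda_to"], sort=True):
        windows.append(FepWindowSamples(int(idx), float(lf), float(lt),
                                        grp["delta_u_kcal"].to_numpy()))
    return windows


def write_fep_samples(path, windows: list[FepWindowSamples]) -> None:
    with open(path, "w") as fh:
        fh.write("window_index\tlambda_from\tlambda_to\tdelta_u_kcal\n")
        for w in windows:
            for du in w.delta_u:
                fh.write(f"{w.window_index}\t{w.lambda_from:.10g}\t"
                         f"{w.lambda_to:.10g}\t{du:.10g}\n")
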