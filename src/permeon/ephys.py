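"""Patch-clamp analysis: IV curves, reversal potentials, bi-ionic
permeability ratios, and the hyperbolic inhibitor dose-response fit.

Whole-cell sweeps (voltage steps from a 0 mV holding potential) are reduced
to an IV curve by averaging the current inside a plateau window; channel-
specific currents are isolated by subtracting an inhibitor-blocked IV.  The
reversal potential E_rev interpolates the zero-current crossing, and under
bi-ionic conditions (one permeant cation per side, equal valence) yields the
permeability ratio through the GHK relation

    P_in/P_out = ([out]/[in]) · exp(−E_rev F / R T).

Inhibitor block is quantified with the hyperbolic dose-response model
I = I_min + (I_max − I_min)·IC50/(IC50 + [inhibitor]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import FARADAY_C_MOL, R_J_MOL_K

logger = logging.getLogger(__name__)

DEFAULT_STEP_VOLTAGES = np.arange(-100, 101, 20)  # mV


@dataclass
class SweepSet:
    """Voltage-step sweeps: one sampled current trace per step voltage."""

    voltages: np.ndarray          # mV, unique
    times: np.ndarray             # ms, shared sample times, sorted
    currents: np.ndarray          # (n_voltages, n_samples) pA
    condition: str = "control"
    holding_potential: float = 0.0  # mV

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.unique(self.voltages).size != self.voltages.size:
            raise ValueError("step voltages must be unique")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if self.currents.shape != (self.voltages.size, self.times.size):
            raise ValueError("currents must be (n_voltages, n_samples)")


@dataclass
class IVCurve:
    voltages: np.ndarray   # mV
    currents: np.ndarray   # pA, one mean current per voltage
    window: tuple[float, float] | None = None  # ms

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("one current per voltage required")


@dataclass(frozen=True)
class BiIonicConditions:
    internal_ion: str = "Cs+"
    internal_mM: float = 150.0
    external_ion: str = "Na+"
    external_mM: float = 150.0
    temperature: float = 295.0  # K; room temperature, recording T unstated

    def __post_init__(self):
        if self.internal_mM <= 0 or self.external_mM <= 0:
            raise ValueError("concentrations must be positive")


@dataclass
class DoseResponse:
    concentrations: np.ndarray    # mM
    currents: np.ndarray          # normalized
    I_max: float | None = None
    I_min: float | None = None
    IC50: float | None = None     # mM
    residual_norm: float | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.concentrations.shape != self.currents.shape:
            raise ValueError("one current per concentration required")


def iv_from_sweeps(sweeps: SweepSet, window: tuple[float, float]) -> IVCurve:
    """IV curve: mean current inside the time window, per step voltage."""
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must have t_start < t_end")
    if t0 < sweeps.times[0] or t1 > sweeps.times[-1]:
        raise ValueError("averaging window outside the trace span")
    inside = (sweeps.times >= t0) & (sweeps.times <= t1)
    if not inside.any():
        raise ValueError("averaging window contains no samples")
    return IVCurve(sweeps.voltages.copy(), sweeps.currents[:, inside].mean(axis=1),
                   window=(t0, t1))


def subtract_background(iv_control: IVCurve, iv_inhibited: IVCurve) -> IVCurve:
    """Channel-specific IV: control minus inhibitor-blocked currents."""
    if (iv_control.voltages.shape != iv_inhibited.voltages.shape
            or np.max(np.abs(iv_control.voltages - iv_inhibited.voltages)) > 1e-9):
        raise ValueError("voltage grids differ")
    return IVCurve(iv_control.voltages.copy(),
                   iv_control.currents - iv_inhibited.currents,
                   window=iv_control.window)


def reversal_potential(iv: IVCurve) -> float:
    """Zero-current voltage by linear interpolation between bracketing points.

    With several crossings the one nearest 0 mV is returned with a warning.
    """
    order = np.argsort(iv.voltages)
    v = iv.voltages[order]
    i = iv.currents[order]
    crossings = []
    for a in range(v.size - 1):
        if i[a] == 0.0:
            crossings.append(float(v[a]))
        elif i[a] * i[a + 1] < 0:
            crossings.append(float(v[a] - i[a] * (v[a + 1] - v[a]) / (i[a + 1] - i[a])))
    if i[-1] == 0.0:
        crossings.append(float(v[-1]))
    if not crossings:
        raise ValueError("IV curve does not cross zero current")
    if len(crossings) > 1:
        logger.warning("multiple zero crossings %s; using the one nearest 0 mV",
                       crossings)
    return min(crossings, key=abs)


def biionic_permeability_ratio(e_rev_mV: float,
                               conditions: BiIonicConditions = BiIonicConditions()) -> float:
    """P_internal/P_external from the bi-ionic reversal potential (GHK).

    E_rev is the membrane potential (inside relative to outside); a more
    permeant internal cation drives E_rev negative.
    """
    rt_f = R_J_MOL_K * conditions.temperature / FARADAY_C_MOL  # volts
    return (conditions.external_mM / conditions.internal_mM) * float(
        np.exp(-e_rev_mV * 1e-3 / rt_f))


def _dose_response_model(conc, I_max, I_min, ic50):
    return I_min + (I_max - I_min) * ic50 / (ic50 + conc)


def fit_dose_response(data: DoseResponse) -> DoseResponse:
    """Least-squares fit of the hyperbolic dose-response model (IC50 > 0)."""
    conc = data.concentrations
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if conc.min() > 0.05 * max(conc.max(), 1e-12):
        raise ValueError("need a zero or near-zero concentration point")
    i = data.currents
    p0 = (float(i.max()), float(i.min()), float(np.median(conc[conc > 0])))
    try:
        popt, _ = curve_fit(_dose_response_model, conc, i, p0=p0,
                            bounds=([-np.inf, -np.inf, 1e-12], np.inf),
                            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"dose-response fit did not converge: {err}") from err
    resid = i - _dose_response_model(conc, *popt)
    return DoseResponse(conc, i, I_max=float(popt[0]), I_min=float(popt[1]),
                        IC50=float(popt[2]),
                        residual_norm=float(np.linalg.norm(resid)))


# --------------------------------------------------------------------------
# tabular sweep I/O: sweep_voltage_mV, time_ms, current_pA, condition

def read_sweeps(path) -> dict[str, SweepSet]:
    """Read sweep tables (TSV/CSV) into one SweepSet per condition label."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    out = {}
    for cond, grp in df.groupby(df.get("condition", "control")):
        pivot = grp.pivot_table(index="sweep_voltage_mV", columns="time_ms",
                                values="current_pA")
        out[str(cond)] = SweepSet(pivot.index.to_numpy(dtype=float),
                                  pivot.columns.to_numpy(dtype=float),
                                  pivot.to_numpy(dtype=float), condition=str(cond))
    return out


def write_sweeps(path, sweeps: SweepSet) -> None:
    rows = []
    for v, trace in zip(sweeps.voltages, sweeps.currents):
        for t, i in zip(sweeps.times, trace):
            rows.append((v, t, i, sweeps.condition))
    pd.DataFrame(rows, columns=["sweep_voltage_mV", "time_ms", "current_pA",
                                "condition"]).to_csv(path, sep="\t", index=False)
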