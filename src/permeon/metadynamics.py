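"""Metadynamics bias bookkeeping: hills, grids, schedules, walkers.

The bias acts on the two soft-min CVs (ζA, ζB).  Hills are 2-D Gaussians of
width 0.25 Å deposited every 4 ps by each walker into one shared grid.  The
lower boundary ζ = 0 is made flux-free by also depositing, per CV dimension,
a mirror-image Gaussian reflected across ζ = 0 (same sign and height), so
the bias gradient normal to the boundary vanishes for on-boundary hills.

The hill height follows a piecewise-linear schedule (raised from h0 to
h_peak over the first ramp, then lowered back to h0), and the reweighting
stage consumes a *time average* of the accumulated bias over a window where
it has become approximately stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAUSSIAN_CUTOFF_SIGMAS = 8.0  # truncation radius for hill deposition


@dataclass
class HillRecord:
    time: float                  # ps
    center: tuple[float, float]  # (ζA, ζB), Å
    widths: tuple[float, float] = (0.25, 0.25)  # (σA, σB), Å
    height: float = 0.0035       # kcal/mol
    walker_id: int = 0

    def __post_init__(self):
        if self.widths[0] <= 0 or self.widths[1] <= 0:
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("hill center must be finite")


@dataclass
class BiasGrid:
    """2-D lattice over (ζA, ζB) holding accumulated bias in kcal/mol."""

    zeta_min: float = -2.0
    zeta_max: float = 42.0
    spacing: float = 0.05
    values: np.ndarray = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        n = int(round((self.zeta_max - self.zeta_min) / self.spacing)) + 1
        self.axis = self.zeta_min + self.spacing * np.arange(n)
        if self.values is None:
            self.values = np.zeros((n, n))
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (n, n):
                raise ValueError("values shape inconsistent with grid axes")

    def copy(self) -> "BiasGrid":
        return BiasGrid(self.zeta_min, self.zeta_max, self.spacing, self.values.copy())

    def _index(self, zeta: np.ndarray) -> np.ndarray:
        idx = np.round((np.asarray(zeta) - self.zeta_min) / self.spacing).astype(int)
        return np.clip(idx, 0, self.axis.size - 1)

    def value_at(self, zeta_a, zeta_b) -> np.ndarray:
        """Nearest-cell bias lookup; out-of-range CVs are clamped."""
        return self.values[self._index(zeta_a), self._index(zeta_b)]

    def gradient_at(self, zeta_a, zeta_b) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference bias gradient (∂V/∂ζA, ∂V/∂ζB) at grid cells."""
        ia = self._index(zeta_a)
        ib = self._index(zeta_b)
        n = self.axis.size
        ia_p, ia_m = np.minimum(ia + 1, n - 1), np.maximum(ia - 1, 0)
        ib_p, ib_m = np.minimum(ib + 1, n - 1), np.maximum(ib - 1, 0)
        ga = (self.values[ia_p, ib] - self.values[ia_m, ib]) / ((ia_p - ia_m) * self.spacing)
        gb = (self.values[ia, ib_p] - self.values[ia, ib_m]) / ((ib_p - ib_m) * self.spacing)
        return ga, gb


@dataclass
class EffectiveBias:
    """Time-averaged bias V̄(ζA, ζB) over a stationary window."""

    grid: BiasGrid
    averaging_window: tuple[float, float]  # (t_start, t_end), ps

    def __post_init__(self):
        if self.averaging_window[0] >= self.averaging_window[1]:
            raise ValueError("averaging window must have t_start < t_end")


@dataclass(frozen=True)
class HeightSchedule:
    """Piecewise-linear hill-height schedule (times in ns).

    h0 → h_peak over [0, t_rise_end], then back down to h0 reached at
    t_decay_end, constant h0 afterwards.
    """

    h0: float = 0.0035       # kcal/mol
    h_peak: float = 0.007    # kcal/mol
    t_rise_end: float = 30.0   # ns
    t_decay_end: float = 100.0  # ns

    def __post_init__(self):
        if self.h0 > self.h_peak:
            raise ValueError("h0 must not exceed h_peak")
        if self.t_rise_end > self.t_decay_end:
            raise ValueError("t_rise_end must not exceed t_decay_end")


K_SCHEDULE = HeightSchedule(0.0035, 0.007, 30.0, 100.0)
NA_SCHEDULE = HeightSchedule(0.0035, 0.007, 50.0, 250.0)


def schedule_height(t_ns: float, schedule: HeightSchedule = K_SCHEDULE) -> float:
    """Hill height at simulation time t (ns)."""
    if t_ns < 0:
        raise ValueError("time must be >= 0")
    s = schedule
    if t_ns <= s.t_rise_end:
        if s.t_rise_end == 0:
            return s.h_peak
        return s.h0 + (s.h_peak - s.h0) * t_ns / s.t_rise_end
    if t_ns <= s.t_decay_end:
        if s.t_decay_end == s.t_rise_end:
            return s.h0
        frac = (t_ns - s.t_rise_end) / (s.t_decay_end - s.t_rise_end)
        return s.h_peak + (s.h0 - s.h_peak) * frac
    return s.h0


def _add_gaussian(grid: BiasGrid, center: tuple[float, float],
                  widths: tuple[float, float], height: float) -> None:
    ca, cb = center
    sa, sb = widths
    ax = grid.axis
    ia0, ia1 = np.searchsorted(ax, [ca - GAUSSIAN_CUTOFF_SIGMAS * sa,
                                    ca + GAUSSIAN_CUTOFF_SIGMAS * sa])
    ib0, ib1 = np.searchsorted(ax, [cb - GAUSSIAN_CUTOFF_SIGMAS * sb,
                                    cb + GAUSSIAN_CUTOFF_SIGMAS * sb])
    if ia0 >= ia1 or ib0 >= ib1:
        return
    ga = np.exp(-0.5 * ((ax[ia0:ia1] - ca) / sa) ** 2)
    gb = np.exp(-0.5 * ((ax[ib0:ib1] - cb) / sb) ** 2)
    grid.values[ia0:ia1, ib0:ib1] += height * np.outer(ga, gb)


def deposit_hill(grid: BiasGrid, hill: HillRecord, boundary: str = "mirror",
                 scale: float = 1.0) -> BiasGrid:
    """Add one hill (plus boundary images) to the grid, in place.

    ``boundary='mirror'`` adds, for each CV dimension, the image Gaussian
    reflected across ζ = 0; ``boundary='none'`` deposits only the main
    Gaussian.  ``scale`` multiplies the height (used by the time-averaging
    shortcut).  Deposition is additive, so hill order never matters.
    """
    h = hill.height * scale
    ca, cb = hill.center
    _add_gaussian(grid, (ca, cb), hill.widths, h)
    if boundary == "mirror":
        _add_gaussian(grid, (-ca, cb), hill.widths, h)
        _add_gaussian(grid, (ca, -cb), hill.widths, h)
    elif boundary != "none":
        raise ValueError(f"unknown boundary rule {boundary!r}")
    return grid


def merge_walker_hills(streams: list[list[HillRecord]]) -> list[HillRecord]:
    """Merge per-walker hill streams into one time-ordered sequence.

    Each stream must already be time-sorted; ties are broken by walker_id.
    """
    for stream in streams:
        times = [h.time for h in stream]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("walker hill stream is not time-sorted")
    merged = [h for stream in streams for h in stream]
    merged.sort(key=lambda h: (h.time, h.walker_id))
    return merged


def time_average_bias(bias_snapshots: list[BiasGrid], times,
                      window: tuple[float, float]) -> EffectiveBias:
    """Pointwise arithmetic mean of bias-grid snapshots within a time window."""
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must have t_start < t_end")
    times = np.asarray(times, dtype=float)
    inside = [g for g, t in zip(bias_snapshots, times) if t0 <= t <= t1]
    if not inside:
        raise ValueError("no bias snapshots inside the averaging window")
    mean = inside[0].copy()
    mean.values = np.mean([g.values for g in inside], axis=0)
    return EffectiveBias(mean, (t0, t1))


def effective_bias_from_hills(hills: list[HillRecord], window: tuple[float, float],
                              grid: BiasGrid | None = None,
                              boundary: str = "mirror") -> EffectiveBias:
    """Exact continuous-time average of the growing bias over a window.

    The accumulated bias is piecewise constant between hill depositions, so
    its time average over [t0, t1] equals the sum of hills weighted by the
    fraction of the window during which each was present:
    weight 1 for hills laid before t0, (t1 − t_h)/(t1 − t0) for hills laid
    inside the window, 0 after t1.  Equivalent to averaging densely stored
    grid snapshots, without storing them.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must have t_start < t_end")
    grid = BiasGrid() if grid is None else grid.copy()
    grid.values = np.zeros_like(grid.values)
    for hill in hills:
        if hill.time >= t1:
            continue
        w = 1.0 if hill.time <= t0 else (t1 - hill.time) / (t1 - t0)
        deposit_hill(grid, hill, boundary=boundary, scale=w)
    return EffectiveBias(grid, (t0, t1))


def stationarity_drift(eb_first: EffectiveBias, eb_second: EffectiveBias) -> float:
    """Max pointwise |V̄| drift between two window halves (diagnostic only)."""
    return float(np.max(np.abs(eb_first.grid.values - eb_second.grid.values)))


# --------------------------------------------------------------------------
# hills file dialect: whitespace-separated text, one hill per line

_HILLS_HEADER = "# time_ps zetaA zetaB sigmaA sigmaB height_kcal walker_id"


def write_hills(path, hills: list[HillRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(_HILLS_HEADER + "\n")
        for h in hills:
            fh.write(f"{h.time:.10g} {h.center[0]:.10g} {h.center[1]:.10g} "
                     f"{h.widths[0]:.10g} {h.widths[1]:.10g} {h.height:.10g} "
                     f"{h.walker_id}\n")


def read_hills(path) -> list[HillRecord]:
    hills = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, za, zb, sa, sb, h, wid = line.split()
            hills.append(HillRecord(float(t), (float(za), float(zb)),
                                    (float(sa), float(sb)), float(h), int(wid)))
    return hills
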