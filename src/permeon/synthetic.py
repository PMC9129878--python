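"""Synthetic data with known ground truth for every analysis stage.

The central piece is a Brownian-dynamics "toy pore": non-interacting ions in
a cylinder (uniform accessible cross-section along z, so the axial PMF is
exactly the imposed axial potential), with a Gaussian axial barrier at the
origin mimicking the channel constriction, optional constant electric field,
and optional live metadynamics coupling through the soft-min CVs.  Because
the ground-truth PMF is analytic, the whole metadynamics → reweighting →
conductance chain can be validated end to end at desk scale.

Also here: hydration point-cloud fixtures with exact expected switching
counts, Gaussian FEP window samples with closed-form ΔG, and synthetic
voltage-step recordings with a prescribed conductance and reversal
potential.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .colvar import SoftMinParams
from .constants import kT
from .ephys import DoseResponse, SweepSet
from .fep import FepWindowSamples, fep_schedule
from .metadynamics import (BiasGrid, HeightSchedule, HillRecord, K_SCHEDULE,
                           deposit_hill, schedule_height)
from .profiles import Profile, uniform_bins


@dataclass(frozen=True)
class ToyPoreParams:
    """A stated toy world: scales mirror the real system qualitatively.

    Pore half-length 15 Å with reservoirs to ±40 Å, a 7 kcal/mol Gaussian
    barrier of width 2 Å at the constriction (the K+ barrier scale), K+-like
    diffusion D = 0.2 Å²/ps (2e-9 m²/s), and a 5 Å-radius confining
    cylinder uniform along z so the analytic PMF equals the axial potential.
    """

    n_ions: int = 16
    box_z: float = 80.0            # Å, ions span z in [-box_z/2, box_z/2]
    pore_radius: float = 5.0       # Å, radial confinement (uniform in z)
    confinement_k: float = 10.0    # kcal/(mol Å²), harmonic wall stiffness
    barrier_height: float = 7.0    # kcal/mol (U0)
    barrier_width: float = 2.0     # Å (Gaussian sigma)
    temperature: float = 298.0     # K
    diffusion: float = 0.2         # Å²/ps
    timestep: float = 0.2          # ps
    field_Ez: float = 0.0          # kcal/(mol Å e)
    charge: float = 1.0            # e
    periodic_z: bool = False       # wrap z (voltage runs) vs reflecting walls

    def __post_init__(self):
        for name in ("n_ions", "box_z", "pore_radius", "confinement_k",
                     "temperature", "diffusion", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.barrier_height < 0 or self.barrier_width <= 0:
            raise ValueError("barrier height must be >= 0 and width positive")
        if self.diffusion * self.timestep > 0.1 * self.barrier_width**2:
            raise ValueError("unstable timestep: D*dt must be << barrier width^2")


@dataclass
class SyntheticGroundTruth:
    pmf: Profile                 # analytic F_true(z), anchored to 0 in bulk
    params: ToyPoreParams
    seed: int | None = None


@dataclass
class ToyRun:
    """Sampled output of a toy-pore run (snapshot-major arrays)."""

    params: ToyPoreParams
    times: np.ndarray            # (S,) ps
    ion_z: np.ndarray            # (S, W, N) Å
    ion_R: np.ndarray            # (S, W, N) Å
    cv: np.ndarray               # (S, W, 2) (ζA, ζB)
    hills: list = field(default_factory=list)
    bias: BiasGrid | None = None
    seed: int | None = None
    n_walkers: int = 1

    def pooled(self, t_min: float = -np.inf, t_max: float = np.inf):
        """Flatten walkers into one snapshot list within a time window."""
        keep = (self.times >= t_min) & (self.times <= t_max)
        S = int(keep.sum())
        W = self.ion_z.shape[1]
        times = np.repeat(self.times[keep], W)
        cv = self.cv[keep].reshape(S * W, 2)
        ion_z = self.ion_z[keep].reshape(S * W, -1)
        ion_R = self.ion_R[keep].reshape(S * W, -1)
        return times, cv, ion_z, ion_R


def _axial_force(z: np.ndarray, p: ToyPoreParams) -> np.ndarray:
    """−dU/dz for the Gaussian barrier plus the constant-field term."""
    w2 = p.barrier_width**2
    f = p.barrier_height * z / w2 * np.exp(-0.5 * z**2 / w2)
    return f + p.charge * p.field_Ez


def _softmin_batch(dz: np.ndarray, params: SoftMinParams):
    """ζ and dζ/dz for (W, N) batches of signed ΔZ values."""
    a = params.beta / (np.abs(dz) + params.C)
    L = logsumexp(a, axis=-1)
    zeta = params.beta / L - params.C
    p = softmax(a, axis=-1)
    grad = ((params.beta / L**2)[..., None] * p
            * params.beta / (np.abs(dz) + params.C) ** 2 * np.sign(dz))
    return zeta, grad


def simulate_toy_pore(params: ToyPoreParams = ToyPoreParams(), *,
                      n_steps: int = 100_000, n_walkers: int = 1,
                      seed: int = 0, sample_every: int = 20,
                      metadynamics: bool = False,
                      bias_grid: BiasGrid | None = None,
                      hill_interval_ps: float = 4.0,
                      hill_width: float = 0.25,
                      height_schedule: HeightSchedule = K_SCHEDULE,
                      cv_params: SoftMinParams = SoftMinParams(),
                      center_A_z: float = -0.5, center_B_z: float = +0.5) -> ToyRun:
    """Overdamped Langevin dynamics of the toy pore, optionally biased.

    All walkers advance in lockstep and share one bias grid; each walker
    deposits a hill (with boundary images) every ``hill_interval_ps`` at its
    current (ζA, ζB), with the height taken from the schedule at the walker
    simulation time.  Deterministic for a fixed seed.
    """
    p = params
    rng = np.random.default_rng(seed)
    dt = p.timestep
    kt = kT(p.temperature)
    mobility = p.diffusion / kt
    noise_sd = np.sqrt(2 * p.diffusion * dt)
    half_z = p.box_z / 2

    pos = np.empty((n_walkers, p.n_ions, 3))
    r = p.pore_radius * np.sqrt(rng.uniform(size=(n_walkers, p.n_ions)))
    theta = rng.uniform(0, 2 * np.pi, size=(n_walkers, p.n_ions))
    pos[:, :, 0] = r * np.cos(theta)
    pos[:, :, 1] = r * np.sin(theta)
    # start ions outside the barrier region, split between the two reservoirs
    sign = np.where(np.arange(p.n_ions) % 2 == 0, 1.0, -1.0)
    pos[:, :, 2] = sign * rng.uniform(5.0, half_z - 1.0, size=(n_walkers, p.n_ions))

    grid = bias_grid if bias_grid is not None else (BiasGrid() if metadynamics else None)
    hills: list[HillRecord] = []
    hill_interval = max(1, int(round(hill_interval_ps / dt)))

    n_samples = n_steps // sample_every
    times = np.empty(n_samples)
    ion_z = np.empty((n_samples, n_walkers, p.n_ions))
    ion_R = np.empty((n_samples, n_walkers, p.n_ions))
    cv_out = np.empty((n_samples, n_walkers, 2))
    i_sample = 0

    for step in range(1, n_steps + 1):
        z = pos[:, :, 2]
        force = np.zeros_like(pos)
        force[:, :, 2] = _axial_force(z, p)

        # radial harmonic wall, uniform along z
        rad = np.sqrt(pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2)
        over = rad > p.pore_radius
        if over.any():
            pull = np.where(over, -p.confinement_k * (rad - p.pore_radius)
                            / np.maximum(rad, 1e-12), 0.0)
            force[:, :, 0] += pull * pos[:, :, 0]
            force[:, :, 1] += pull * pos[:, :, 1]

        if grid is not None:
            za, ga = _softmin_batch(z - center_A_z, cv_params)
            zb, gb = _softmin_batch(z - center_B_z, cv_params)
            dva, dvb = grid.gradient_at(za, zb)
            force[:, :, 2] -= dva[:, None] * ga + dvb[:, None] * gb

        pos += mobility * force * dt + noise_sd * rng.standard_normal(pos.shape)

        z = pos[:, :, 2]
        if p.periodic_z:
            pos[:, :, 2] = (z + half_z) % p.box_z - half_z
        else:
            # reflecting walls in z
            out_hi = z > half_z
            out_lo = z < -half_z
            z[out_hi] = 2 * half_z - z[out_hi]
            z[out_lo] = -2 * half_z - z[out_lo]
            pos[:, :, 2] = np.clip(z, -half_z, half_z)

        t = step * dt
        if metadynamics and step % hill_interval == 0:
            za, _ = _softmin_batch(pos[:, :, 2] - center_A_z, cv_params)
            zb, _ = _softmin_batch(pos[:, :, 2] - center_B_z, cv_params)
            height = schedule_height(t / 1000.0, height_schedule)
            for w in range(n_walkers):
                hill = HillRecord(t, (float(za[w]), float(zb[w])),
                                  (hill_width, hill_width), height, walker_id=w)
                deposit_hill(grid, hill)
                hills.append(hill)

        if step % sample_every == 0 and i_sample < n_samples:
            za, _ = _softmin_batch(pos[:, :, 2] - center_A_z, cv_params)
            zb, _ = _softmin_batch(pos[:, :, 2] - center_B_z, cv_params)
            times[i_sample] = t
            ion_z[i_sample] = pos[:, :, 2]
            ion_R[i_sample] = np.sqrt(pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2)
            cv_out[i_sample, :, 0] = za
            cv_out[i_sample, :, 1] = zb
            i_sample += 1

    return ToyRun(p, times[:i_sample], ion_z[:i_sample], ion_R[:i_sample],
                  cv_out[:i_sample], hills, grid, seed, n_walkers)


def analytic_toy_pmf(params: ToyPoreParams, bin_centers=None,
                     anchor_region=((-40.0, -30.0), (30.0, 40.0))) -> SyntheticGroundTruth:
    """Exact PMF of the toy pore: barrier plus field term, anchored in bulk."""
    if bin_centers is None:
        bin_centers = uniform_bins(-params.box_z / 2, params.box_z / 2, 0.5)
    z = np.asarray(bin_centers, dtype=float)
    F = (params.barrier_height * np.exp(-0.5 * z**2 / params.barrier_width**2)
         - params.charge * params.field_Ez * z)
    in_anchor = np.zeros(z.size, dtype=bool)
    for lo, hi in anchor_region:
        in_anchor |= (z >= lo) & (z <= hi)
    if in_anchor.any():
        F = F - F[in_anchor].mean()
    prof = Profile(z, F, np.ones_like(F),
                   {"quantity": "analytic free energy", "units": "kcal/mol"})
    return SyntheticGroundTruth(prof, params)


# --------------------------------------------------------------------------
# hydration fixtures

def generate_hydration_fixture(ion_position, n_in: int, n_out: int, r0: float,
                               seed: int = 0, r_out_max: float | None = None):
    """Oxygen point cloud with an exact expected switching count.

    Places n_in oxygens uniformly at r < 0.9 r0 and n_out beyond 1.3 r0
    (where a single oxygen contributes < 1e-11), so the rational switching
    count equals n_in to well within 1e-6.
    """
    if n_in < 0 or n_out < 0:
        raise ValueError("requested counts must be >= 0")
    rng = np.random.default_rng(seed)
    ion = np.asarray(ion_position, dtype=float).reshape(3)
    r_out_max = 2.0 * r0 if r_out_max is None else r_out_max
    if r_out_max <= 1.3 * r0:
        raise ValueError("outer placement shell is empty: raise r_out_max")

    def shell(n, r_lo, r_hi):
        u = rng.uniform(size=n)
        radii = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1 / 3)
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return ion + radii[:, None] * v

    inner = shell(n_in, 0.0, 0.9 * r0)
    outer = shell(n_out, 1.3 * r0, r_out_max)
    return np.vstack([inner, outer])


# --------------------------------------------------------------------------
# FEP samples

def generate_fep_samples(mus, sigmas, n: int, temperature: float = 298.0,
                         seed: int = 0, context: str = "pore"):
    """Gaussian per-window FEP samples with closed-form ground truth.

    Forward window i draws ΔU ~ N(μ_i, σ_i²), whose exponential average is
    ΔG_i = μ_i − σ_i²/(2 k_B T).  The backward run is generated
    Crooks-consistently: the reverse-step work distribution of a Gaussian
    forward process has mean −μ_i + σ_i²/k_B T and the same σ_i, which makes
    backward ΔG_i exactly −ΔG_i(forward) and lets hysteresis vanish as
    n → ∞.  Returns ``(forward, backward, total_dg_true)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = fep_schedule(context)
    n_win = lam.size - 1
    mus = np.broadcast_to(np.asarray(mus, dtype=float), (n_win,))
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (n_win,))
    kt = kT(temperature)
    rng = np.random.default_rng(seed)

    forward, backward = [], []
    for i in range(n_win):
        du_f = rng.normal(mus[i], sigmas[i], size=n)
        forward.append(FepWindowSamples(i, float(lam[i]), float(lam[i + 1]), du_f))
    for j, i in enumerate(range(n_win - 1, -1, -1)):
        mu_b = -mus[i] + sigmas[i] ** 2 / kt
        du_b = rng.normal(mu_b, sigmas[i], size=n)
        backward.append(FepWindowSamples(j, float(lam[i + 1]), float(lam[i]), du_b))
    dg_true = float(np.sum(mus - sigmas**2 / (2 * kt)))
    return forward, backward, dg_true


# --------------------------------------------------------------------------
# synthetic recordings

def generate_synthetic_recording(gamma_pS: float = 50.0, e_rev_mV: float = -76.0,
                                 noise_sd_pA: float = 0.0,
                                 voltages=None, seed: int = 0, *,
                                 inhibited_fraction: float = 0.1,
                                 leak_pS: float = 0.0,
                                 t_total_ms: float = 200.0, dt_ms: float = 1.0,
                                 t_step_ms: float = 20.0):
    """Voltage-step sweeps with a prescribed channel conductance.

    Returns ``(control, inhibited)`` SweepSets: the control plateau carries
    the full channel current γ(V − E_rev) plus an ohmic leak, the inhibited
    one only ``inhibited_fraction`` of the channel component (same leak), so
    background subtraction recovers (1 − fraction) of the channel IV.
    """
    if gamma_pS < 0:
        raise ValueError("conductance must be >= 0")
    voltages = (np.arange(-100, 101, 20, dtype=float) if voltages is None
                else np.asarray(voltages, dtype=float))
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_total_ms + dt_ms / 2, dt_ms)
    on = times >= t_step_ms

    def sweep(channel_scale, condition):
        currents = np.zeros((voltages.size, times.size))
        for i, v in enumerate(voltages):
            chan = channel_scale * gamma_pS * (v - e_rev_mV) * 1e-3  # pA
            leak = leak_pS * v * 1e-3
            currents[i] = np.where(on, chan + leak, 0.0)
        currents += noise_sd_pA * rng.standard_normal(currents.shape)
        return SweepSet(voltages.copy(), times, currents, condition=condition)

    return sweep(1.0, "control"), sweep(inhibited_fraction, "+AP-6")


def generate_dose_response(concentrations, I_max: float = 1.0, I_min: float = 0.0,
                           ic50_mM: float = 2.0, noise_fraction: float = 0.0,
                           seed: int = 0) -> DoseResponse:
    """Normalized currents obeying the hyperbolic inhibition model."""
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    ideal = I_min + (I_max - I_min) * ic50_mM / (ic50_mM + conc)
    noisy = ideal * (1.0 + noise_fraction * rng.standard_normal(conc.shape))
    return DoseResponse(conc, noisy)
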