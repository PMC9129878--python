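# permeon

Analysis machinery for studying how a narrow, hydrophobic ion channel
conducts and selects between cations — built around the workflow used for
the lysosomal K+ channel TMEM175, whose pore has no canonical selectivity
filter and instead discriminates K+ from Na+ at a constriction formed by
isoleucine side chains.

The package is aimed at simulators and channel biophysicists who have (or
want to emulate) enhanced-sampling MD of ion permeation and matching
patch-clamp recordings, and need every quantitative step between raw
trajectories and publishable numbers:

- **Collective variables** — the soft-min ion-proximity coordinate
  ζ = β / ln Σₖ exp(β/(|ΔZₖ|+C)) − C, a smooth lower bound on the smallest
  axial ion–center distance that biases permeation without presuming how
  many ions take part (`permeon.colvar`).
- **Metadynamics bookkeeping** — Gaussian hill deposition with boundary
  images at ζ = 0, piecewise-linear height schedules, multiple-walker
  merging, and time-averaged effective bias V̄(ζA, ζB)
  (`permeon.metadynamics`).
- **Reweighting** — snapshot weights w ∝ exp(V̄/k_BT), ion-occupancy
  profiles ρ(z), potentials of mean force F(z) = −k_BT ln ρ(z) + C′, general
  reweighted observable profiles, and split-half error diagnostics
  (`permeon.reweight`).
- **Hydration analysis** — the rational switching count
  S = Σⱼ 1/(1+(rⱼ/r₀)¹⁰⁰) with tabulated shell radii (K+ 3.5/6.0 Å,
  Na+ 3.2/5.7 Å) for water- and protein-oxygen coordination profiles
  (`permeon.hydration`).
- **Continuum electrostatics** — a finite-difference linearized-Poisson
  solver on a lattice with protein/membrane/bulk/pore-water/ion-cavity
  dielectric regions, giving ion–protein interaction energies E = qΦ
  (`permeon.electrostatics`).
- **Transport** — single-channel conductance from the PMF,
  γ = q²CS/(k_BT) · [∫ e^{F(z)/k_BT}/D(z) dz]⁻¹, field-to-voltage
  conversion, and ohmic current/permeation-rate arithmetic
  (`permeon.transport`).
- **FEP selectivity** — exponential averaging over λ windows, forward/
  backward hysteresis, and site-vs-bulk selectivity differentials ΔΔG
  (`permeon.fep`).
- **Electrophysiology** — IV curves from voltage-step sweeps, inhibitor
  background subtraction, reversal potentials, GHK bi-ionic permeability
  ratios, and hyperbolic IC50 dose-response fits (`permeon.ephys`).
- **Synthetic ground truth** — a Brownian-dynamics toy pore (with live
  metadynamics coupling and optional voltage), hydration fixtures, Gaussian
  FEP samples, and synthetic recordings, so the entire pipeline is testable
  without cluster-scale MD (`permeon.synthetic`, `permeon.pipeline`).

## Worked example

Run the desk-scale analogue of the production workflow — eight metadynamics
walkers in a toy pore with a 7 kcal/mol barrier, reweight the pooled
snapshots with the time-averaged bias, and compare the recovered free-energy
profile with the analytic truth:

```python
from permeon.pipeline import run_toy_metadynamics_pmf
from permeon.transport import ConductanceInputs, conductance_from_pmf

result = run_toy_metadynamics_pmf(n_walkers=8, n_steps=625_000, seed=1)
print(f"PMF RMS error: {result.rms_error:.3f} kcal/mol")
print(f"split-half |dF|: {result.split_half_gap:.3f} kcal/mol")
print(f"conductance: "
      f"{conductance_from_pmf(result.pmf, ConductanceInputs(z1=-30, z2=30)):.3g} pS")
```

which prints (seed 1):

```
PMF RMS error: 0.143 kcal/mol
split-half |dF|: 0.046 kcal/mol
conductance: 0.175 pS
```

The RMS error says the reweighted profile reproduces the known 7 kcal/mol
barrier to well under thermal energy; the split-half gap is the internal
error estimate from comparing profiles built on each temporal half; the
conductance converts the recovered barrier into a single-channel current
scale via the 1-D diffusion integral (sub-pS, as expected for a barrier of
~12 k_BT at 100 mM).

The electrophysiology arithmetic works directly on printed numbers, e.g. a
bi-ionic reversal potential of −76 mV under 150 mM Cs+ (inside) / 150 mM
Na+ (outside) at room temperature:

```python
from permeon.ephys import biionic_permeability_ratio
biionic_permeability_ratio(-76.0)   # -> 19.88, i.e. P_Cs/P_Na ≈ 20
```

## Command line

A thin CLI mirrors the file-oriented workflows: `permeon axis`, `permeon
events`, `permeon colvar`, `permeon hills-merge`, `permeon bias-average`,
`permeon pmf`, `permeon conductance`, `permeon voltage`, `permeon fep`,
`permeon ephys`, and `permeon synth {toy-pore,fep,recording}`. Run any of
them with `--help`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main analyses from scratch —
the full 5×10⁶-step toy-pore metadynamics → reweighting → PMF → conductance
pipeline plus the transport, bi-ionic, FEP, and dose-response computations —
and writes its result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A summary of every quantity computed is printed to stdout (~6 minutes on one
CPU).

## Layout

```
src/permeon/          library (all computation)
tests/                pytest suite, incl. end-to-end acceptance checks
scripts/acceptance.py from-scratch verification run
docs/methods.md       models, parameters, numerical choices, limitations
```
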