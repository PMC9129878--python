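# Methods

This note records the models implemented in `permeon`, the parameters that
matter, the numerical choices, and what the synthetic ground truth does and
does not establish.

## Geometry and conventions

All internal units are Å, ps, kcal/mol, and elementary charges; conversions
to SI/electrophysiology units (pS, pA, mV) happen only in `constants` and at
I/O edges. The pore axis connects two centers A and B built as *unweighted*
centroids of Cα selections flanking the channel constriction (for Cα-only
groups a mass-weighted centroid is numerically indistinguishable, since all
Cα masses are equal). The origin, z = 0, is the A/B midpoint — the
constriction — with positive z toward center A (luminal side by default,
configurable). Ion positions become (z, R): signed axial projection and
perpendicular distance, computed under the minimum-image convention because
production trajectories are wrapped.

A permeation event is a double-threshold transit: the ion must go from
beyond one bound (defaults ±15 Å) to beyond the other while staying within
R0 = 10 Å of the axis whenever inside the bounds. The two thresholds make
the count robust to recrossing noise at a single dividing surface. For
periodic (voltage-driven) trajectories, `count_periodic_transits` splits the
series at wrap jumps so teleports across the box never register as transits.

## Collective variables

The biased coordinate is a soft minimum over ions of the axial distance to a
virtual center:

    ζ = β / ln Σ_k exp( β / (|ΔZ_k| + C) ) − C,    β = 100 Å, C = 2 Å.

ΔZ_k is the *Cartesian* Z-component of the ion–center separation. Key
properties, all tested: exact identity ζ = |ΔZ| for one ion; ζ ≤ min|ΔZ_k|
always, with equality as β → ∞; insensitivity to far ions; smooth gradients
(needed to apply bias forces in the toy simulator). Evaluation is
log-sum-exp stabilized so ions sitting on the center (exponent β/C) cannot
overflow. Two such variables, ζA and ζB, are defined against centers ~1 Å
apart along the pore; biasing the pair prevents an ion from "hiding" exactly
at a single center where one variable loses sensitivity.

## Metadynamics bias

Hills are 2-D Gaussians (default width 0.25 Å per dimension) deposited every
4 ps by each walker into one shared grid; deposition is additive, so walker
and time ordering never affect the final bias. The hill height follows a
piecewise-linear schedule: for K+-like runs it rises 0.0035 → 0.007 kcal/mol
over the first 30 ns and decays back to 0.0035 by 100 ns (Na+-like: 50 ns /
250 ns). Only two times parameterize the schedule, so the plateau between
ramp-up and ramp-down has zero length; "gradually" is read as linear, the
simplest monotone interpolation.

Because ζ ≥ 0 is (nearly) a hard boundary, each hill also deposits one
mirror Gaussian per CV dimension reflected across ζ = 0, with the same sign
and height. This makes the bias gradient normal to the boundary vanish for
on-boundary hills and removes the systematic under-filling a bare Gaussian
would leave near ζ = 0. (A sign-flipped image would *cancel* bias at the
boundary, defeating its purpose; "inverted" is understood as the mirrored
geometry.)

The bias grid spans ζ ∈ [−2, 42] Å at 0.05 Å spacing — ≥5 points per hill
width, and a lower edge below zero because the soft-min can dip slightly
negative when several ions crowd the center.

## Reweighting

Snapshot weights follow w(X_i) ∝ exp(V̄(ζA_i, ζB_i)/k_BT), where V̄ is the
*time average* of the accumulated bias over a window in which it has become
approximately stationary (the pipeline default: the last 60% of the run).
Bias lookup is nearest-cell, deliberately without interpolation, matching
the "assign each snapshot to a grid point" procedure. Out-of-grid CV values
are clamped with a logged warning. The time average is computed exactly from
the hill log: the accumulated bias is piecewise constant between
depositions, so V̄ over [t0, t1] is the hill sum weighted by each hill's
residence fraction in the window — equivalent to averaging densely stored
grid snapshots (tested), without the memory.

Occupancy ρ(z) sums snapshot weights over ions within R0 per bin (0.5 Å bins
by default); F(z) = −k_BT ln ρ(z) + C′, with C′ fixing the
occupancy-weighted mean of F over the bulk anchor region (default
|z| ∈ [30, 40] Å, both sides pooled) to zero. Empty bins are masked NaN,
never zero-filled, and the conductance integral refuses to integrate across
them. Observable profiles divide the weighted observable sum by ρ bin-wise.
The split-half diagnostic recomputes weights and profiles independently on
each temporal half (renormalized within the half) and reports the mean
absolute difference over bins defined in both.

Two error regimes govern this diagnostic. While statistical noise
dominates, the half-to-half gap decreases with simulation length (toy runs:
≈0.14 → 0.08 → 0.04 kcal/mol as total sampling doubles twice). At longer
lengths it plateaus at a floor of a few times 0.01 kcal/mol set by the
*shape drift* of the still-growing bias: with constant-rate, non-tempered
hill deposition, the bias deposited during any averaging window perturbs
the two halves differently by a roughly length-independent amount, so the
gap stops shrinking (and can fluctuate upward) no matter how long the run
is. Convergence claims based on this diagnostic should therefore be made in
the statistics-dominated regime, or after hill deposition has been ramped
down much further than the default schedule does.

## Hydration counting

Coordination numbers use S = Σ_j [1 − (r/r₀)¹⁰⁰]/[1 − (r/r₀)²⁰⁰], evaluated
in the equivalent stable form 1/(1 + (r/r₀)¹⁰⁰) with the removable
singularity fixed at exactly 1/2 for r = r₀. Shell radii follow the minima
of the bulk-water ion–oxygen RDF: K+ 3.5 Å (first shell) / 6.0 Å (first two
shells), Na+ 3.2 / 5.7 Å; exponents are fixed at 100/200 and not re-tuned.
"Protein oxygens" means every protein atom with element O (backbone and side
chain); the switching function localizes the count, so no pre-selection
cylinder is applied to waters. Bulk reference numbers used to report
depletion ΔN (K+: ~7 first shell, ~31 first two shells) are external
constants, not recomputed — computing them would require explicit-water MD,
which is out of scope.

## Continuum electrostatics

Ion–protein interaction energies are E_k = q_k Φ(r_k) with Φ the potential
of the protein partial charges alone in a heterogeneous dielectric: protein
interior ε_p = 2 (or 1), membrane slab ε_m = 2 (28.8 Å thick), bulk water
ε_s = 80, pore water ε_s′ = 40 in a cylinder of radius 18 Å and height
28.8 Å, and a small ε = 2 cavity (radius 2 Å) at the ion, whose own charge
is excluded from the source term. Region precedence: protein > cavity >
pore cylinder > slab > bulk. The protein interior is the union of atom
spheres inflated by a 1 Å probe with one binary-closing pass as an
approximation to a re-entrant molecular surface; the exact construction used
by production solvers is not reproducible from its description, and this
approximation is accurate to about one voxel layer (tested against analytic
volumes).

The linearized Poisson equation ∇·(ε∇Φ) = −4π k_e ρ (zero ionic strength —
no screening term is part of the model) is discretized with the 7-point flux
stencil, harmonic-mean face dielectrics, and trilinear charge spreading, and
solved by diagonally preconditioned conjugate gradients to a relative
residual of 1e-8 (configurable). Dirichlet boundaries default to the
analytic Coulomb potential of the total charge in bulk dielectric —
standard for a single focused grid — and validation problems with a known
far field can supply exact boundary values. Validation: a point charge in
homogeneous ε = 80 matches Coulomb within 3% beyond 5 grid spacings; the
reaction potential across a planar ε 80/2 interface matches the image-charge
closed form within 5% once the half-cell offset of the lattice interface is
accounted for. The default production lattice is 150³ points at 1 Å; tests
use smaller focused grids since cost scales with N³.

## Conductance and voltage

γ = q²CS/(k_BT) · [∫_{z1}^{z2} e^{F(z)/k_BT}/D(z) dz]⁻¹, trapezoid rule over
the PMF bins, D flat by default (K+ 2×10⁻⁹ m²/s, Na+ 1.5×10⁻⁹ m²/s, from the
simulation literature) with an optional per-bin D profile; C = 100 mM and
S = 314 Å² are the sampling cylinder's concentration and cross-section. All
unit bridging between molecular and SI units is centralized in `constants`.
A flat PMF reduces to γ = q²CSD/(k_BT·L) exactly (closed form used in
tests). Membrane voltage from a constant applied field uses
Φ = E_z·L_z·0.0434 V per (kcal/mol)/e; currents are I = γV and permeation
rates I/e. On the toy pore at low barrier, the γ-predicted crossing rate
matches the voltage-run event count within ~10% (asserted at factor 2).

## FEP selectivity

Per-window free energies use one-sided exponential averaging
ΔG_i = −k_BT ln⟨e^{−ΔU/k_BT}⟩ (log-sum-exp stabilized), accumulated along λ
schedules that tile [0, 1]: steps of 0.04 then 0.02 near λ = 1 (bulk: 30
windows; pore: 26 windows — the finer tail starts at 0.8 and 0.96
respectively). BAR is deliberately not used: the protocol's error control is
the forward/backward hysteresis, defined as the largest gap between the
forward ΔG(λ) curve and the forward curve implied by the backward run
(linear interpolation onto the union λ grid). Harmonic ion-exchange
restraints and flat-bottom confinement from the sampling protocol are
carried as window metadata only — this module analyzes energy differences,
it does not sample. The selectivity differential is
ΔΔG = ΔG_bulk − ΔG_site (positive = the site favors K+ relative to bulk
water), with fold preference exp(ΔΔG/k_BT); at 298 K, 0.5 kcal/mol
corresponds to 2.33-fold.

## Electrophysiology

IV points are plateau means inside a user window; channel-specific currents
are control minus inhibitor-blocked sweeps on identical voltage grids.
Reversal potentials interpolate the zero crossing linearly (multiple
crossings: nearest 0 mV, with a warning). Bi-ionic permeability ratios use
the monovalent GHK form P_in/P_out = ([out]/[in])·e^{−E_rev F/RT}; the
recording temperature defaults to 295 K (room temperature; this is the
choice that reconciles E_rev = −76 mV with a ratio of 20). The sign
convention is physiological: membrane potential inside minus outside, so a
more permeant internal cation gives negative E_rev. Dose-response inhibition
is fit by unweighted least squares to
I = I_min + (I_max − I_min)·IC50/(IC50 + [inhibitor]) with IC50 constrained
positive.

## Synthetic ground truth (and its limits)

The toy pore is overdamped Langevin dynamics of *non-interacting* ions in a
cylinder: x ← x + (D/k_BT)F dt + √(2D dt)·N(0,1), with a Gaussian axial
barrier (default 7 kcal/mol high, 2 Å wide — the K+ barrier scale), a
harmonic radial wall at 5 Å uniform along z, reflecting (or periodic, for
voltage runs) ends at ±40 Å, K+-like D = 0.2 Å²/ps, dt = 0.2 ps, and 16
ions. Because the accessible cross-section is uniform in z and ions do not
interact, the exact PMF equals the imposed axial potential (plus −qE_z·z
under a field) — this is what makes end-to-end validation possible. The
stability guard requires D·dt ≪ (barrier width)².

Metadynamics coupling is live: walkers advance in lockstep, share one bias
grid, feel the bias force through the soft-min gradients, and deposit hills
on the production schedule. The full desk run (8 walkers × 625k steps =
5×10⁶ steps, ~125 ns/walker) recovers the 7 kcal/mol barrier with RMS error
≈ 0.14 kcal/mol over |z| ≤ 20 Å in ~6 minutes on one CPU.

What a green toy-pore test does *not* establish: force-field realism,
ion–ion correlation effects (the toy is single-ion by construction, though
the real analysis also found a single-ion mechanism), hydration coupling to
the permeation coordinate, protein flexibility, or the statistical behavior
of the estimators under the much slower diffusion of a crowded channel.

FEP samples are Gaussian per window with closed-form
ΔG_i = μ_i − σ_i²/2k_BT. The backward direction is generated
Crooks-consistently (reverse-work mean −μ + σ²/k_BT, same σ) so that the
backward estimate converges to exactly −ΔG_forward and hysteresis vanishes
with sampling — a "negate the mean" backward would leave a constant σ²/k_BT
bias that no amount of sampling removes. Synthetic recordings superimpose
ohmic channel and leak components with Gaussian noise; the dose-response
generator applies multiplicative noise to the hyperbolic model. The
simulation-study dose design (0, 1, 2, 3, 4, 8, 64, 256 mM for a 2 mM IC50)
brackets the IC50 and anchors both saturation limits, the standard design
for a 3-parameter fit.

## Numerical choices and edge cases

- Hills are truncated at 8σ during deposition (relative error < 1e-14 of a
  hill, tested against untruncated sums at 1e-10).
- Bin width 0.5 Å: resolves the ~15 Å hydrophobic span with ~30 bins while
  keeping per-bin counts usable.
- Weight degeneracy: an effective sample size below 10 logs a warning.
- `switching_count` saturates overflow for r ≫ r₀ harmlessly to 0.
- Degenerate pore axis (|A−B| < 1e-6 Å), empty selections, empty snapshot
  sets, unsorted walker streams, λ-coverage gaps, and masked PMF bins inside
  conductance bounds all raise informative errors.
- Reproducibility: every stochastic generator is a pure function of
  (parameters, seed); per-walker randomness derives from one seeded
  generator, so runs are bit-identical for a fixed seed.

## Known limitations

- No well-tempered metadynamics, no on-the-fly MD coupling beyond the toy
  simulator, no 2-D PMFs, and no block-bootstrap errors (split-half only).
- The Poisson solver is a desk-scale validation tool: no ionic strength,
  no multigrid acceleration, and an approximate molecular surface.
- No position-dependent diffusion estimation; D(z) profiles must be
  supplied.
- Axon binary formats are not parsed; sweeps must arrive as TSV/CSV tables.
- No capacitance/series-resistance compensation or liquid-junction
  corrections in the ephys module.
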