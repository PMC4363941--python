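# Methods

`actinsim` is a particle-based stochastic simulator of actin filament
formation at the interface between a cell and a flat or micro-structured
substrate.  Every molecule is an individual hard disk diffusing by Brownian
motion in a 2D continuous domain; behavior is expressed as rules over
species, binding sites and attributes.  This note records the model, its
assumptions, the numerical choices, and what the synthetic scenarios do and
do not show about real cells.

## Model

### Species and geometry

| species  | diameter (μm) | D (μm²/a.u.) | sites / attributes |
|----------|---------------|--------------|--------------------|
| actin    | 0.05          | 0.63         | pointed, barbed (180° apart), branchL/branchR (±70° off the growth axis) |
| integrin | 0.06          | 0.58         | one filament site; `focal ∈ {yes, no}` |
| cofilin  | 0.02          | 1.00         | `active ∈ {yes, no}` |
| CofReg   | 0.03          | 0.82         | — |
| Arp2/3   | 0.04          | 0.71         | mother, daughter |

Sizes are proportional to protein-size surrogates and deliberately coarse:
one "actin" disk stands for a segment of a filament *bundle*, which is what
fluorescence imaging resolves.  Diffusion coefficients scale with 1/√size,
anchored at cofilin (D = 1).  Times are arbitrary units (a.u.); rates are
per a.u.  The filament-length unit conversion is μm = particle count ×
0.05 μm.

The domain is a square with reflective walls.  A micro-pillared substrate is
a 3×3 grid of 5 μm square regions at 10 μm pitch, centered in a
27.5-μm-square domain — the unique square in which the pillars cover
225/756.25 = 29.75% of the system.  Regions have *soft* boundaries:
particles may straddle them, membership is the particle's center position,
and transfer rules gate crossings (only integrin is gated here).  Grooves
are full-height stripes of the same width and pitch.  A planar substrate has
no regions; the whole domain counts as surface contact.

### Reactions

Second-order reactions are collision-triggered: they can fire only when a
particle's Brownian step produces an overlap, with a stated probability per
collision (all 1 by default).  First-order reactions follow exponential
clocks.  The rule set:

* **Nucleation** — a focal-adhesion integrin (`focal=yes`, site free) binds
  a free actin monomer by its pointed end.  The filament axis is fixed at
  nucleation: drawn from N(0°, σ²) about the horizontal (σ = 7.5/15/30°), or,
  unconstrained, set to the approach direction of the first actin.
* **Elongation** — a free monomer binds the chain's free barbed end and is
  placed collinearly (bound particles are placed at exact site angles,
  independent of the collision direction, which keeps chains straight).
  Filaments are immobile: any bound particle stops diffusing.
* **Branching** (off by default) — Arp2/3 occupies a branch site (±70° from
  the growth axis) and then accepts a free actin, starting a branch chain.
* **Severing** — active cofilin colliding with a filament actin whose
  pointed end is bound releases all of that actin's bonds (probability
  `pSevering`, default 1).  Any actin left with a free pointed end and a
  bound barbed end dissolves by the trunk-dissolution rule; its rate is ∞ by
  default, so the whole orphaned downstream chain (and its branches) is
  converted to free monomers within the same timestep.  The integrin-rooted
  stump keeps a free barbed end and can regrow.
* **Cofilin regulation** — one of two mutually exclusive mechanisms
  (selected by zeroing `pCofDeactAtInt` or `rCofRegAppearance`): direct
  deactivation on contact with a focal adhesion, or a lumped diffusible
  intermediate *CofReg* that is created next to each focal adhesion at
  `rCofRegAppearance` (per FA), decays at `rCofRegDisappearance`, and
  deactivates cofilin catalytically on collision.  Deactivated cofilin
  reactivates at `rCofilinReactivation`.
* **Focal adhesions** — on structured surfaces an integrin entering a
  region becomes `focal=yes` instantly (`instantFA`, the default) or by rate
  `rIntComplexFormation` while inside; in the instant variant the focal
  state stands for binding a surface-sensing agent that exists only on the
  structure, so an unbound integrin that leaves the region reverts to
  `focal=no` (filament-anchoring FAs are immobile and never leave).  On
  planar surfaces the rate applies everywhere.  An FA with no filament bound
  dissolves at `rFAdissolution` (0.1).  The hampered-entry/slowdown variant
  gates entry at `pIntegrinEnter` < 1 and scales D by `slowdownFactor`
  inside regions.
* **Replenishment** — every 1 a.u. the free-actin pool is topped back up to
  its initial count at uniform random overlap-free positions, standing in
  for recruitment from the cytosol; actin is never removed, so total actin
  is non-decreasing.

### Executor

The engine processes a single event queue (timestamps, ties by insertion
order).  A move event for particle *i* proposes a displacement with
independent N(0, 2·D·Δt) components, reflects it at the walls, evaluates
transfer rules if the center crosses a region boundary (a rejected crossing
is a blocked attempt), and then tests overlaps.  On a collision, the first
matching rule (declaration order) is tried on the nearest overlapping
partner with one probability roll; success applies the reaction and nudges
the mover out of any residual overlap, failure undoes the attempt.  After 4
failed attempts the particle keeps its position; the next move event is
scheduled either way.  Per-particle time steps solve √(2·D·Δt) = k·d_min,
i.e., every species moves with the same per-axis step length of k times the
smallest particle diameter (k = 1 by default).

First-order clocks are exponential and are (re)drawn whenever a particle's
rule applicability changes; an infinite rate fires within the same timestep,
which is what makes trunk dissolution cascade.  A single seeded RNG stream
drives everything; identical (model, parameters, seed) give bit-identical
trajectories.

### Numerical choices

* Overlap is strict (`dist < r₁+r₂`); tangency is not a collision.  Region
  rectangles are closed; the overlap-resolution clearance is ε = 1e-6 μm.
* Overlap resolution pushes the mover along the line of centers to contact
  + ε (random direction for coincident centers); pushes that would exit the
  domain are reflected and re-checked, falling back to the opposite side or
  a nearby free position in crowded corners.
* Bind placements that would overlap a third particle roll the whole
  reaction back; the collision then counts as a blocked move.
* Collision queries use a uniform spatial hash with cell size equal to the
  largest particle diameter, so a 3×3 neighborhood is exhaustive.

## Observables

Filament complexes are connected components of the bond graph (always
trees; one integrin at the pointed-most position).  The *main chain* is the
root-to-leaf path with the most actins; branch chains are extracted
recursively.  Reported statistics: average/maximum main-chain length
(particles and μm), per-complex total actin counts, and the **orientation
dispersion** — each chain contributes an axial segment (orientation = fitted
principal axis of its member centers, weight = its length), the angles are
doubled (θ ≡ θ+180°), and the statistic is the angular deviation of the
weighted resultant normalized by its maximum: 100·√(1−R̄), from 0% (one
preferred orientation) to 100% (uniform).  For segments drawn N(0, σ²) the
closed form is 100·√(1−exp(−2σ²)): 35.8% at σ=15° and 65.0% at σ=30°.
Regional cofilin statistics classify each cofilin by the region containing
its center (active/total on and between structures).  Snapshots render the
state to PNG with filament interiors, tips, free monomers, rooted and free
integrins in distinct colors and dashed region outlines.

## Study conditions and test scale

The default scenario is the base study condition: 250 actin, 400 cofilin,
100 integrin in the 27.5 μm pillared domain, CofReg regulation
(appearance/disappearance rates scanned over {0.5, 2}), σ = 15°, collision
probabilities 1, t_end = 48 a.u.  The physical constants (sizes, diffusion
coefficients, `rCofilinReactivation`) have no authoritative values at this
level of abstraction; the values above are this package's calibrated
choices and are all configurable.

The test suite exercises the same model on geometrically similar miniatures:
a half-linear-scale layout (13.75 μm domain, 2.5 μm pillars at 5 μm pitch —
the pillar share is exactly preserved) with amounts scaled by area (63
actin, 100 cofilin, 25 integrin) run to t = 12, and a quarter-scale layout
(16/25/6) for multi-condition scans, with step factor k = 2.  Measured
consequences of this scale, worth keeping in mind when reading test
assertions:

* Collision-limited rates are understated at k = 2 (≈3.5× for actin-sized
  targets) because steps comparable to the target diameter tunnel past it.
  The artifact is identical across conditions, so cross-condition orderings
  (planar vs. pillared, low vs. high severing) are unaffected; physics
  checks (step variance, MSD, exponential clocks, the SSA comparison) run
  at k = 1.
* With the calibrated constants the CofReg→cofilin deactivation rate is
  ≈0.4/a.u. per cofilin at study densities, so active-cofilin fractions
  equilibrate between 0.55 and 1.0 across the scanned conditions.  The
  qualitative results — shorter filaments with more active cofilin, shorter
  filaments on pillars than on planar substrates, active cofilin depleted
  more on pillars than between them — all reproduce, but absolute filament
  lengths and regional fractions depend strongly on this constant choice,
  and the regional depletion signal (a few hundredths) is only resolvable
  in replicate means, not single runs.
* Simulated filaments are straight segments with idealized severing; the
  synthetic scenarios say nothing about filament bending, bundling,
  treadmilling, nucleotide states or mechanics, all of which are outside
  the model.

## Known limitations

2D only; excluded volume causes spurious blocking/trapping that a 3D model
would not have (filaments cannot cross or overgrow each other); bound
structures never move; no forces; reaction probabilities are per collision
and therefore entangled with the step length; the well-mixed limit matches
mass-action kinetics only while spatial depletion is mild.
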