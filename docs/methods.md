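# Methods

## Model and assumptions

The culture is described as two phases on the unit square: a cancer-cell
volume fraction α ∈ [0, 1] and everything else (medium/extracellular
material).  Because adherent cells are fixed in the plate over the
observation window, all transport terms for the cell phase are dropped;
the stated zero-flux wall condition for α is then vacuous and generates
no stencil.  Each grid node evolves by the scalar balance

    dα/dt = (1+s₁) α (1−α) C / (1+s₁C) − (s₂+s₃C) α / (1+s₄C),

logistic growth saturating in oxygen minus an oxygen-modulated death
term.  All quantities are nondimensional as written: no hidden rate
constants are reintroduced, time is read directly in hours (so the 1 h
step is literal), and oxygen is scaled so the medium value is 1.  The
parameters absorb whatever physical scalings would otherwise appear.

Oxygen carries no time derivative: it is treated as quasi-steady and
re-solved after every cell step,

    ∇²C = Q α C / (1+Q₁C),

with the one-dimensional second derivative of the original statement
read as the 2-D Laplacian (the simulation domain is two-dimensional).
Two boundary statements coexist: constant oxygen outside the cells and
zero gradient on the walls.  They are honoured without overdetermining
any node by imposing Dirichlet C = 1 on *medium* nodes (nodes outside
the cell phase at t = 0) and homogeneous Neumann on the four outer
walls.  Whether the original computation pinned medium nodes, wall
nodes, or both is not recoverable; this choice is the one that makes
both statements non-redundant.

At C = 1 the growth coefficient (1+s₁)C/(1+s₁C) equals 1 exactly — the
code computes the coefficient before multiplying by α(1−α) so the
cancellation is exact in floating point as well, which is what makes
the s₁ sensitivity span *identically* zero when oxygen is decoupled.

A documented quirk of the parameterization: as written, larger s₂/s₃
(and smaller s₄) increase death.  Prose summaries sometimes state the
opposite association between parameter changes and cytotoxicity; this
package follows the equation, and its monotonicity tests assert that
direction (72-h viability non-increasing in s₂, s₃; non-decreasing in
s₄).

## Discretization and numerics

* Grid: uniform nodes on the unit square, default 50×50 for standalone
  runs; the examples, tests and acceptance runs use 10–25 nodes per
  axis, which the grid-refinement check justifies (doubling the
  resolution moves 72-h viability by well under 0.5%).
* Cell step: with oxygen frozen, every node is an independent scalar
  ODE advanced by `ode_substeps` (default 10) classical RK4 steps per
  1 h step.  The result may leave [0, 1] only by round-off: a clamp
  larger than 10⁻¹² (or any non-finite value, which stiff corners of
  the parameter box can produce at fixed substep counts) raises an
  error instead of being silently absorbed.
* Oxygen solve: Picard iteration with the saturation denominator
  lagged, each iterate a sparse direct solve of the 5-point stencil
  (Neumann walls by mirroring, Dirichlet rows replaced by identity).
  Convergence when successive iterates differ by less than 10⁻⁸ in max
  norm; the previous step's field warm-starts the next solve.
  Dirichlet values are re-pinned exactly after each linear solve so the
  medium-node invariant C = 1 holds bit-exactly.
* Viability: 100 × trapezoidal integral of α over the domain, relative
  to the t = 0 field — t = 0 is the treatment/normalization time, so
  the reading starts at exactly 100%.
* Closed-form oracle: with C constant the dynamics reduce to
  dα/dt = (a−b)α − aα² with a = (1+s₁)C/(1+s₁C), b = (s₂+s₃C)/(1+s₄C),
  solved exactly by a logistic-type formula (evaluated via e^{−rt} when
  r = a−b > 0 so long horizons cannot overflow).  With Q = 0 the full
  simulator must agree with this formula at every node and hour to
  10⁻⁴, which pins the stepper's accuracy independently of the PDE
  machinery.

## Estimation

The objective is the unweighted sum of squared percent-viability
residuals over all supplied points; RTCA and flow points enter with
equal weight (the objective as stated prints no weights), and
observation times must land exactly on recorded simulation times — no
interpolation.  Stage 1 runs SLSQP from `n_starts` (default 16)
Latin-hypercube starts drawn from the inner 20% of the bound box;
stage 2 refines the incumbent with Nelder–Mead (tolerance 10⁻¹⁰, max
2000 evaluations), and the better of the two stages is returned.
Bounds are [0, 50] for s-parameters and [0, 20] for Q, Q₁ — generous
relative to nondimensional estimates of order 4–5.  Ties across starts
break by lowest SE, then lexicographically smallest parameter vector,
making results bit-reproducible per seed.  Simulation failures at stiff
parameter corners are scored as SE = 10¹² so the search backs away
rather than aborting.

Q and Q₁ enter estimation only for controls; treatment fits hold them
frozen (returned bit-identical) and report each free parameter's
relative change versus the control, 100·(θ_treat − θ_ctrl)/θ_ctrl.

With 5–7 fit points the four s-parameters are only weakly identifiable:
they trade off along a ridge of near-equal SE.  The package therefore
treats *predictive* recovery (the fitted viability curve) as the
meaningful target; recovering the generator's parameter values
themselves is neither promised nor tested.

The fit-quality summary `sd_error` is defined here as
100·RMS(residual)/mean(experimental); it is scale invariant (identical
in NCI or percent units).  This is this package's convention — the
corresponding published summary statistic has no printed formula, so no
numerical agreement with any external value is claimed.

## Synthetic data

The generator emulates the study layout: a 15-minute RTCA sampling
clock over 72 h with the 5-point fit subset at 24/36/48/60/72 h, and
flow snapshots at 24 h and 72 h.  NCI noise is multiplicative Gaussian
(default σ = 0.03, of the order of replicate scatter in impedance
assays — impedance is roughly proportional to attached cell mass, so
relative noise is the natural law); NCI(0) is pinned to exactly 1 as
the normalization defines it.  Flow snapshots split model viability V
into viable = V(1−f_early), early = V·f_early (default f_early = 0.10),
and the non-viable remainder into late apoptotic (f_late = 0.80) versus
necrotic; jitter is a Dirichlet draw (concentration 200 × base
fractions), which preserves the sum-to-100 constraint by construction.
Estimation consumes the pooled viable + early fraction, on the
rationale that early-apoptotic cells are still adherent and therefore
indistinguishable from viable cells to the impedance readout.  The
dense 15-min trace linearly interpolates the hourly simulation records,
mimicking an instrument clock faster than the model's time step.  The
split-fraction contract requires V ≤ 100, so flow snapshots exist for
treatment-like responses; control fits use the RTCA-only protocol.
Replicate structure is emulated as noise on the mean rather than as
three explicit replicate draws; the fit consumes the mean.

Default ground-truth parameter sets: the control
(s₁ = 1, s₂ = 0.1, s₃ = 0.1, s₄ = 1, Q = 5.32, Q₁ = 4.97 — oxygen
values at a published control estimate for a colorectal line) grows to
≈180% of treatment-time mass by 72 h; the treatment
(s₂ = 0.4, s₃ = 0.25, s₄ = 0) relaxes to ≈70%, a partial cytotoxic
response.  Under these aerobic conditions the oxygen field stays above
0.99, which is exactly the regime in which freezing Q, Q₁ after the
control fit is justified.

What the generator does *not* emulate: instrument drift, well-edge
effects, compensation/spectral overlap in flow cytometry, real
micrograph texture, or cell migration.  Passing tests therefore
demonstrate correctness of the numerics and the estimation machinery
under the stated noise law, not robustness to those real-data
artifacts.

## Sensitivity analysis

One parameter at a time is swept over ±75% of its control value
(15 evenly spaced samples by default, odd so the control itself is
sampled; endpoint behaviour dominates because the response is monotone
in each death parameter, so span = |endpoint difference| to numerical
precision).  The span is max − min of 72-h viability.  Published span
values depend on unpublished raw control estimates, so the analysis
here anchors the qualitative structure — death parameters dominate,
oxygen parameters are negligible under aerobic conditions — not the
printed numbers.

## Problem sizes

Tests and the acceptance script run on 10–25 node grids with 4–8
optimizer starts; these sizes are past the point where the
grid-refinement and oracle-agreement checks show resolution no longer
affects the conclusions, and a full run completes in minutes on one
CPU.  The defaults for standalone use (50×50 grid, 16 starts) are
correspondingly more conservative.

## Known limitations

* No cell migration/advection, 3-D domains, or time-dependent oxygen.
* No uncertainty quantification (bootstrap/profile likelihood); the
  ridge structure of the objective makes per-parameter error bars
  largely meaningless at this data density anyway.
* The fixed-substep RK4 stepper rejects (rather than adapts to) very
  stiff parameter corners; the estimator handles this by penalty.
* Otsu segmentation assumes a roughly bimodal intensity histogram;
  constant images require an explicit threshold.
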