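# Methods

## Model

The population is described by three compartments — proliferating cells P,
reversibly cell-cycle-arrested cells C, and senescent cells S — with linear
kinetics between them:

    dP/dt = r P − f1 F̂ P + f2 C
    dC/dt =       f1 F̂ P − f2 C − f3 C
    dS/dt =                        f3 C

All rates are per day.  Mass exchange is conservative: d(P+C+S)/dt = r P, so
the total changes only through division.  S has no back reaction — senescence
is irreversible by construction.  Population doublings are
PD(t) = log2(total(t)/total(0)), the quantity measured in culture; this
counts all cells in the dish, not only cycling ones.

Assumptions worth stating explicitly: cells neither die nor leave the dish
(no apoptosis/differentiation compartments); rates are time-independent; the
culture is well mixed so a deterministic mean-field description is adequate
for the 1e4–1e6 cells of a real passage series.

## Stress input and stress response

Stress is split into an *input* γ(t) (module `stress`) and a delayed cellular
*response* F(t) that actually gates the P→C flux.  γ(t) is one of: zero, a
rectangular irradiation pulse (amplitude in arbitrary stress units/day,
duration equal to the printed exposure time converted to days), a constant,
or the accumulating form γ = α + βt.  Pulses are handled exactly by
restarting the integrator at the pulse edges; a 27-second exposure would
otherwise be stepped over.

The response obeys

    dF/dt = γ(t) + a F² / (b² + F²) − c F,

saturating positive feedback plus linear decay.  The published description
of this equation is qualitative (bistable, a maximum scale K, fast
up-switch, slow return), so the concrete form above is this package's
design decision; it is the minimal form with the required fixed-point
structure, and the property tests pin down the *contract* rather than the
formula: bistability over a stress window, two saddle-node folds, hysteresis
in a quasi-static sweep, up-switch at least 5× faster than relaxation.

Default shape constants (`default_f_shape`): a = 1.9·K, b = 0.5·K,
c = 2.0/day, K = 1.  The ratio ρ = a/(cb) controls the diagram:

* ρ < 1.54 — globally monostable (no switch);
* 1.54 < ρ < 2 — bistable over an *interior* window of γ (two folds at
  γ > 0); at γ = 0 the only fixed point is F = 0, so after a pulse the
  response relaxes fully back to the healthy state, slowly, through the
  saddle-node ghost;
* ρ ≥ 2 — the high state persists at γ = 0 (the response latches forever).

ρ = 1.9 was chosen because the interior-window regime is the only one
consistent with the documented phenomenology: the response must decay after
the stress ends (low-dose cultures resume growth at their unstressed slope),
and an up-then-down stress sweep must show genuine hysteresis with both
folds at physical (γ ≥ 0) stress levels.  For the default constants the
folds sit at γ ≈ 0.049 and γ ≈ 0.144.

F̂ = F/K normalizes the response so that f1 is a plain rate.  F̂ is *not*
capped at 1: under sustained accumulating stress the upper branch of F grows
roughly linearly with γ, and it is precisely this unbounded gating that lets
the arrest flux eventually overwhelm proliferation.  With a capped response,
every replicative parameter set in the fixture catalog satisfies
r > f1·f3/(f2+f3) at saturation, the population would grow forever and no PD
plateau could exist.  K is therefore the *scale* of the switched-on response
(the high branch at the up-switch), not a hard ceiling under arbitrary
drive.

## Growth termination

A population whose proliferating pool falls below one cell cannot recover.
`simulate` watches the event P < 1 (absolute count, threshold configurable)
and, once it fires, sets the division term to zero permanently while letting
the C→S conversion continue: PD plateaus exactly, S keeps accumulating.

This event is only meaningful on an absolute-count scale.  Generic
simulations default to P(0) = 1e5 cells, where the event is irrelevant under
ordinary protocols.  The irradiation fixtures instead seed 2 cell-equivalents
one day before exposure (concentration-normalized units, the same convention
in which the constant-growth fits start from a single cell).  At that working
point the model reproduces the observed dose dichotomy: a high-dose pulse
pushes the proliferating pool through the single-cell threshold (permanent
plateau), a low-dose pulse does not (growth delayed by about a day, final
slope back within 10% of the unstressed slope).  For replicative runs the
plateau does not need the event: P decays smoothly once F̂ crosses
r(f2+f3)/(f1·f3), and PD flattens because dTotal/dt = rP → 0.

## Numerics

LSODA (stiff-capable) with rtol 1e-8, atol 1e-10; integration restarts at
every protocol discontinuity; the extinction event is located by the
solver's root polishing.  A safety event aborts trajectories whose total
exceeds 1e30 cells (reachable only for absurd trial parameters during
fitting; the fit objective maps such failures to a large finite penalty).
A fixed-step RK4 integrator written independently in the test suite serves
as the integration oracle (agreement to 1e-6 relative); the unstressed model
is also checked against the closed-form exponential.

## Fitting

All fits minimize squared residuals on the PD (log2) scale.  Nonlinear fits
run trust-region-reflective least squares on log-transformed parameters
(positivity for free, decade-spanning rates well scaled), with box bounds
[1e-6, 100]/day for rates and [1e-8, 1] for α, β.  The multi-start design:

1. candidate starts = one data-driven heuristic (r from a constant-growth
   fit to the least-stressed curve, mid-range arrest rates) plus a seeded
   Sobol screen of 128 points drawn log-uniformly from [0.05, 20]/day
   (rates) and [1e-4, 0.1] (stress), ranked by one residual evaluation each;
2. the best candidates are polished until 16 local optimizations have run,
   stopping early if a start reaches residual RMS < 1e-7 PD (an exact fit,
   attainable only on noiseless data);
3. if no exact fit was reached, the best optimum is re-polished with a
   central-difference Jacobian — forward differences stall at the ODE
   solver's noise floor in the shallow valleys this model produces.

Identical seeds and inputs give bit-identical results.  Identifiability is
reported, not assumed: the diagonal curvature of JᵀJ at the optimum flags
flat directions (for an unstressed curve, f1/f2/f3 are correctly reported
as unidentifiable).  Stress-pulse amplitudes are never fitted jointly with
durations — amplitude and f1 are confounded — and a single replicative
curve cannot identify all six parameters, hence the explicit
fit-subset/fixed-subset interface.

## Synthetic data

The generator emulates the study designs, and its defaults are the study
conditions: three-dose irradiation experiments sampled daily for 14 days
(seeded at 2 cell-equivalents, exposure at day 1); replicative cultures
sampled every 2–5 days over 160/300/500-day horizons (WI-38/BJ/MRC-5,
seeded at 1e5 cells) — long enough for each fixture's PD plateau; marker
counts of 100 DAPI-identified cells per replicate, 3 replicates, drawn
binomially around the mapped state fraction (p21 ↔ C+S, SA-β-Gal ↔ S; p16
and SAHF are treated as qualitative and not mapped).  PD noise is additive
Gaussian, default sd 0.25 PD — about 5% of a typical irradiation curve's
span, matching the small-but-significant scatter of biological replicates;
the true experimental noise magnitude is not published, so this default is
a documented assumption.  An optional additive bias on a marker emulates
non-senescence staining (the scenario in which SA-β-Gal rises while the
culture still grows, making its RMSE sit far above the binomial counting
floor √(p(1−p)/(100·replicates))).

What the generator does *not* emulate: per-cell heterogeneity and lineage
structure, passage-discretized (rather than continuous) sampling noise,
marker cross-talk, and counting bias from cell-size differences.  Passing
recovery tests therefore show that the pipeline is correct and that the
printed parameter sets are identifiable from curves *of this shape* — not
that real cultures satisfy the model.

## Recovery studies and problem sizes

The acceptance script refits noiseless synthetic experiments generated from
each published fixture: 45 points (3 conditions × 15) for each irradiation
refit, 81/101/101 points for the WI-38/BJ/MRC-5 replicative refits.  The
noisy-recovery study uses 20 seeded replicates at 0.25 PD noise with 4
multi-start polishes per fit (no central-difference refinement): the growth
rate r is recovered with median relative error well under 10%.  The arrest
rates are *not* reliably recovered under that noise — the likelihood is
nearly flat in f2 (rival minima within ~0.01 PD rms exist already for the
noiseless problem) — and the package treats this as an identifiability
property to be reported rather than a defect to be hidden.

The fate-threshold property check draws random parameter sets
(r ∈ [0.05, 1], f-rates log-uniform in [0.1, 10]), discards sets whose
saturated-response growth rate is within 0.02/day of zero (there the
verdict would be set by the simulation horizon, not the model), and
compares the analytic threshold with a long-horizon simulation at F̂ = 1
(horizon 6/|λ|, clipped to [30, 400] days).

## Known limitations

* The concrete F equation is a stand-in satisfying a qualitative contract;
  fitted (a, b, c) values are not comparable across alternative bistable
  forms, and γ amplitudes are meaningful only relative to the chosen shape.
* The single-cell termination criterion makes high-dose outcomes depend on
  the absolute seeding scale; the 2-cell-equivalent irradiation seeding is a
  modelling working point, not a measured quantity.
* No cell death: protocols harsh enough to kill rather than arrest cells
  are outside the model.
* One well-mixed compartment: no spatial structure, no paracrine feedback
  of senescent cells on their neighbours (the conditioned-medium question),
  no single-cell stochasticity.
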