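# Methods

## The model

`kurafit` simulates resting-state whole-brain phase dynamics with a system of
N delay-coupled, noise-driven Kuramoto oscillators, one per brain region:

    dθ_i/dt = 2π f_i + Σ_j k_ij sin(θ_j(t − τ_ij) − θ_i(t)) + σ η_i(t),

with η_i(t) independent uniform noise on [−1, 1].  Pairwise couplings and
delays are derived from the structural connectome — streamline counts SC and
mean path lengths PL — through two global parameters, the coupling C and the
delay τ (seconds):

    k_ij = SC_ij/⟨SC⟩ · C/N,      τ_ij = PL_ij/⟨PL⟩ · τ,

where ⟨·⟩ denotes the mean over off-diagonal matrix entries (zeros included,
diagonal excluded).  Simulated BOLD is sin(θ_i) downsampled to the fMRI
repetition time TR; simulated functional connectivity (simFC) is the Pearson
correlation matrix of those signals.  The model fit of a parameter point
(C, τ[, σ]) is the Pearson correlation F between the strictly upper
triangles of simFC and the subject's empirical FC; the best achievable F is
the goodness-of-fit.

Reference integration settings are Δt = 0.06 s, TR = 0.72 s, and 3500 s of
retained signal after discarding a 500 s transient.

## Numerical scheme and discrete-time conventions

The delay SDE is integrated with the stochastic Heun predictor–corrector
scheme.  The continuous-time formulation leaves several discrete-time rules
open; the package fixes them as follows (all are unit-tested):

* **Noise scaling.**  The per-step noise increment is σ·√Δt·u with
  u ~ U[−1, 1], drawn once per oscillator per step and reused identically in
  the predictor and the corrector.  This is the Euler–Maruyama-consistent
  convention, so that Var(θ) grows at σ²·Δt/3 per step (uniform variance
  1/3); a Monte-Carlo test verifies the slope to within three standard
  errors.  With zero coupling and zero noise the scheme is exact for the
  constant drift 2π f_i, to accumulated rounding only.
* **Delay discretization.**  τ_ij is rounded to the nearest integer multiple
  of Δt (error ≤ Δt/2); delayed phases are read from a ring buffer of depth
  max d_ij + 1 that stores sin θ and cos θ (the coupling sum needs only
  these, which makes the inner loop transcendental-free per pair).
* **Initial history.**  θ_j(t) for t ≤ 0 is held at the initial phases,
  drawn uniformly on [0, 2π) from the run seed.  The discarded transient
  makes this choice immaterial for stationary FC.
* **Downsampling.**  Samples at t = m·TR are retained, the first at the
  smallest m·TR ≥ transient.  At reference settings this yields
  floor(3500/0.72) = 4861 samples starting at 695·TR.
* **Phase storage.**  Phases are unwrapped; all outputs pass through sines,
  which are wrap-invariant.
* **Feasibility guard.**  The integrator refuses configurations whose
  longest pairwise delay exceeds half the simulated duration; short
  simulations therefore require a correspondingly reduced global-delay
  range.
* **Reproducibility.**  Each simulation consumes one integer seed; initial
  phases are drawn first, then the full (steps × regions) noise array.
  Identical inputs and seed give bitwise identical trajectories and simFC.
  The kernel is JIT-compiled with numba.

## Goal function and seeding

Each goal evaluation runs one simulation and correlates the resulting simFC
with the empirical FC over the strictly upper triangle.  The unit diagonal
is excluded because it is constant and would inflate the correlation.  The
default seed policy draws a fresh child seed per evaluation, making F a
stochastic function of the parameters — the regime the benchmark is about;
a fixed-seed mode makes F deterministic for exact tests and bit-exact
replays.  Child seeds derive from `numpy.random.SeedSequence` over
(master seed, integer key path) and are recorded in run manifests.  A shared
audit counter tracks every goal evaluation.

Note on exactness: re-evaluating the goal at a subject's generating
parameters with the generating seed reproduces the empirical matrix
bit-for-bit, but the Pearson correlation of two identical vectors evaluates
to 1 only within ~1e−16 (square-root rounding); tests assert |F − 1| ≤ 1e−12.

## Grid search

The 2Dim reference grid has 64 equidistant C on [0, 0.945] × 48 equidistant
τ on [0, 94] s with σ fixed at 0.3 (3072 nodes); the 3Dim grid has 48
equidistant C on [0, 0.94] × 22 τ values on [0, 48] s × 81 equidistant σ on
[0, 2] (85 536 nodes).  The τ placement in 3Dim is specified only as denser
near zero; the package uses the quadratic rule τ_m = 48·(m/21)², m = 0…21,
which is strictly increasing with nondecreasing gaps.  The search evaluates
every node exactly once, records the five best nodes (the grid-optima matrix
used by the cost score), supports per-node checkpoint/resume, and draws all
node seeds up front so parallel execution equals serial execution.  A
dry-run mode iterates the nodes and increments the audit counter without
simulating, for sweep-cost accounting.

The cost of a full grid search scales as S·t·p^(Dim−1) for S subjects when a
one-dimensional sweep of p points takes t seconds — the extrapolation
implemented by `estimate_grid_cost` (e.g. t = 100 s, p = 48, Dim = 3 gives
64 h for one subject over 48³ = 110 592 nodes).

## Optimizers

All four methods maximize F over a bounded box — [0, 1] × [0, 100] s for
(C, τ), additionally × [0, 2] for σ — operating internally on the
normalized unit cube and reporting physical coordinates.  Budgets follow
the benchmarking protocol: at most 80 iterations; PSO and CMA-ES stop early
after 50 consecutive iterations without strict improvement of the incumbent
best; Nelder-Mead stops when its longest simplex edge falls below a
normalized tolerance (0.01); BO always runs its full iteration budget,
which excludes the initial design.  Default populations: Dim+1 (NMA
simplex), 60 (PSO), 24 (CMA-ES, μ = 12 parents), 5/10 (BO initial design in
2/3 dimensions).

Method internals not fixed by the protocol are configuration with standard
literature defaults:

* **NMA** — Lagarias coefficients (reflect 1, expand 2, contract 0.5,
  shrink 0.5); initial simplex is a random interior point plus 0.05 axis
  perturbations; candidates are projected onto the box before evaluation.
* **PSO** — constriction-type velocity update with inertia 0.7298 and
  cognitive/social weights 1.49618; positions are clamped to the box with
  the violating velocity component zeroed.
* **CMA-ES** — standard update loop: log-rank selection weights, cumulative
  step-size adaptation, rank-one plus rank-μ covariance update; initial
  mean uniform in the box, initial step 0.3 (normalized); out-of-box samples
  are projected and the projected point is used in the update; covariance
  indefiniteness is repaired by eigenvalue flooring and logged.
* **BO** — Gaussian-process surrogate (Matérn-5/2 plus observation-noise
  term, hyperparameters refit by marginal likelihood each iteration with a
  fallback to the previous fit), expected-improvement acquisition with zero
  exploration margin (the GP posterior uncertainty alone drives
  exploration), maximized by a random candidate sweep followed by bounded
  L-BFGS-B polish.  A positive margin ξ is configurable but stalls EI on
  flat, low-curvature objectives; with a near-zero noise term the posterior
  mean interpolates the observations.

Every optimizer returns the incumbent best (point and fit), per-iteration
best-fit history (nondecreasing by construction), evaluation count and
termination reason.  The replicate protocol runs R_max independent
executions (15 by default, extendable to 24) with distinct child seeds and
assembles the Fit vector, the Points matrix in normalized coordinates, and
a per-run time proxy.

## Evaluation machinery

**Success probability.**  For each subject, r of the R_max available fits
are drawn without replacement (500 draws per r); a draw succeeds if its
maximum reaches 95% of that subject's grid-search best fit.  The cohort
curve is the subject-mean of resample means, with across-subject standard
errors.  Sampling without replacement admits the hypergeometric closed form
1 − C(R_max−m, r)/C(R_max, r), which is monotone in r and serves as the
oracle for the resampler.  Runs-to-level reports the smallest r reaching a
probability level (50%, 80%); an unreached level is charged the full R_max
and flagged.

**Cost score.**  Per subject and method, five nonnegative components are
multiplied: (1) 1 − max Fit; (2) the population standard deviation (1/R_max
convention) of the fits; (3) the time to reach the 80% success level
(runs-to-80% × mean per-run time proxy); (4) the mean pairwise distance of
the solution points (C(R_max, 2) pairs — 105 for R_max = 15); (5) the mean
over solutions of the distance to the nearest of the five grid optima.
The fifth component has two defensible readings; the nearest-grid-point form
is the default and the all-pairs average is available via
`distance_mode="mean"`.  Components are normalized by their maxima over all
subjects × methods (per dimensionality) before the product, which makes the
score invariant to any common rescaling of a component — in particular the
time unit.  Time is therefore a hardware-independent proxy (goal-evaluation
counts) by default.  The per-subject argmin over methods is the
recommendation (ties broken by lower time, then method name, and logged);
the method with the most recommendations is the winner.

## Synthetic cohort

Real inputs to this pipeline are diffusion-MRI connectomes and
multi-session resting-state fMRI.  The generator emulates their relevant
statistics:

* **Connectomes.**  Path lengths from uniformly random 3-D coordinates in a
  cube, with Euclidean distances affinely rescaled into a target range —
  symmetric by construction with triangle-inequality-like geometry.  SC
  weights are log-normal magnitudes times an exponential distance decay
  exp(−PL/λ), λ = half the length-range span, reproducing heavy-tailed,
  distance-dependent weights; the top round(density·N(N−1)/2) pairs are
  kept.
* **BOLD.**  Per-region sinusoids at assigned natural frequencies inside
  the 0.01–0.1 Hz band with random per-session phases, plus Gaussian noise
  that can be given an FC-structured covariance.  Sessions follow the
  4 × 1200-volume, TR = 0.72 s layout.
* **Ground-truth subjects.**  The simulator run at known (C*, τ*, σ*)
  provides a subject's "empirical" FC, giving parameter-recovery fixtures
  with a known optimum.

Feature extraction mirrors the empirical pipeline: per-session linear
detrend, z-score, concatenation; empirical FC is the Pearson correlation of
the concatenated series; natural frequencies are the in-band argmax of the
raw periodogram of the concatenated signal (resolution one bin,
1/(T·TR)).  The raw periodogram — no tapering or averaging — is the
simplest reproducible reading of "maximal spectral peak"; the estimator and
the per-concatenation (rather than per-session) choice are package
decisions.

What the synthetic data does *not* emulate: hemodynamics (no
Balloon–Windkessel forward model), spatially structured measurement noise,
head-motion artifacts, or realistic anatomical topology beyond distance
dependence.  Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted parameters, not empirical validity
of the oscillator model on real cohorts.

## Scaled-down end-to-end study

The bundled study (`kurafit.study.run_study`) exercises the entire pipeline
at desk scale on one CPU: 8 ground-truth subjects with N = 20 regions
(density 0.35), natural frequencies uniform in [0.02, 0.09] Hz, truth at
C* ~ U[0.35, 0.75], τ* ~ U[0, 12] s, σ* = 0.3; simulations of 180 s with an
18 s transient (226 retained TR samples); a 16 × 12 grid on
[0, 0.945] × [0, 30] s and optimizer bounds [0, 1] × [0, 30] s; 5
replicates per method with reduced budgets (25 iterations, stall window 20,
swarm 16, CMA-ES population 12, BO initial design 5).  The delay range is
capped at 30 s because pairwise delays must stay well below the short
simulated duration.  These problem sizes were fixed once as the smallest
configuration in which the grid landscape is informative and every
optimizer can reach it; the full-protocol defaults remain available through
the module interfaces and CLI.

## Known limitations

* The noise-scaling, delay-rounding and initial-history rules above are
  package conventions; other choices would change trajectories (not the
  stationary statistics materially).
* BO refits GP hyperparameters from scratch each iteration; for long runs a
  warm start would be cheaper.
* The grid search parallelizes across nodes only (per-subject parallelism
  is left to the caller).
* Success probabilities at small R_max (e.g. 5 replicates in the bundled
  study) quantize coarsely; the hypergeometric form makes the attainable
  levels explicit.
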