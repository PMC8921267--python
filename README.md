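# kurafit

Validation of dynamical whole-brain models: a delay-coupled stochastic
phase-oscillator simulator on structural connectomes, a functional-
connectivity goodness-of-fit goal function, an exhaustive grid-search
baseline, four derivative-free optimizers (Nelder-Mead, particle swarm,
CMA-ES, Bayesian optimization), and the evaluation machinery to compare
them — success-probability curves, a five-component multiplicative cost
score, per-subject recommendations — exercisable end-to-end on a synthetic
cohort.

## Who this is for

Computational neuroscientists fitting whole-brain network models to
resting-state fMRI face a basic question: tuning the model's global
parameters on a dense grid is reliable but scales as p^Dim simulations and
becomes unfeasible beyond two or three parameters, so which derivative-free
optimizer should replace it, and at what cost in robustness?  `kurafit`
implements the complete benchmarking pipeline for answering that question
on the standard test bed: the Kuramoto model with heterogeneous delays.

## The model and the fitting problem

Each of N brain regions is a phase oscillator

    dθ_i/dt = 2π f_i + Σ_j k_ij sin(θ_j(t − τ_ij) − θ_i(t)) + σ η_i(t)

with coupling strengths and delays built from the structural connectome
(streamline counts SC, path lengths PL) through a global coupling C and a
global delay τ:

    k_ij = SC_ij/⟨SC⟩ · C/N,      τ_ij = PL_ij/⟨PL⟩ · τ.

η_i is uniform noise on [−1, 1] with intensity σ, and f_i are regional
natural frequencies estimated from the 0.01–0.1 Hz spectral peak of the
BOLD signal.  Simulated BOLD is sin(θ_i) downsampled to the fMRI TR;
simulated FC is its Pearson correlation matrix.  The goal function

    F(C, τ[, σ]) = corr(upper triangle of simFC, upper triangle of empFC)

is maximized either on a dense grid (64×48 points in 2Dim, 48×22×81 in
3Dim) or by one of the four optimizers under the benchmarking protocol
(≤ 80 iterations, early stall detection, 15 replicate runs per method).
The integrator is stochastic Heun with Δt = 0.06 s, delays handled by a
sin/cos ring buffer, JIT-compiled with numba.  See `docs/methods.md` for
the full numerical conventions.

## Worked example

Fit a 10-region synthetic ground-truth subject (generated at C = 0.6,
τ = 3 s, σ = 0.3) with a coarse grid and with CMA-ES:

```python
import numpy as np
from kurafit import (CohortConfig, generate_connectome, make_ground_truth_subject,
                     ModelParams, SimSettings, SeedPolicy, make_grid, run_grid_search,
                     OptimizerConfig, run_replicates, make_goal, BoxBounds)

cfg = CohortConfig(n_subjects=1, n_regions=10, density=0.5, master_seed=0)
conn = generate_connectome(cfg, subject_seed=0)
freqs = np.random.default_rng(0).uniform(0.02, 0.09, 10)
sim = SimSettings(duration=120.0, transient=12.0)

truth = ModelParams(0.6, 3.0, 0.3, freqs, duration=sim.duration, transient=sim.transient)
empfc = make_ground_truth_subject(conn, truth, subject_seed=0)

grid = make_grid(2, c_axis=np.linspace(0, 0.945, 8), tau_axis=np.linspace(0, 10, 6))
gs = run_grid_search(conn, empfc, grid, freqs, sim, seed_policy=SeedPolicy(1))
print(f"grid best F = {gs.best_fit:.3f} at C = {gs.best_point[0]:.3f}, tau = {gs.best_point[1]:.1f} s")

bounds = BoxBounds(np.array([0.0, 0.0]), np.array([1.0, 10.0]))
goal = make_goal(conn, empfc, freqs, sim, SeedPolicy(2))
opt = OptimizerConfig.for_method("cmaes", 2, population=8, max_iterations=20, stall_window=20)
rs = run_replicates("cmaes", goal, bounds, opt, n_runs=3, master_seed=3)
print(f"CMA-ES best F over 3 runs = {rs.fits.max():.3f}")
```

prints

```
grid best F = 0.947 at C = 0.540, tau = 4.0 s
CMA-ES best F over 3 runs = 0.989
```

The grid lands on the node nearest the planted parameters; CMA-ES, free of
the lattice, edges closer to the truth (its best point here is C = 0.588,
τ = 3.9 s) and — because every evaluation sees fresh noise — its
best-of-replicates fit can exceed the grid's.  Both read as high similarity
between simulated and "empirical" FC; F = 1 would be a perfect match of the
correlation structure.

## Command line

```sh
kurafit synth --subjects 4 --regions 20 --density 0.35 --seed 1 --out cohort/
kurafit simulate --sc cohort/sub000_sc.tsv --pl cohort/sub000_pl.tsv -c 0.5 -t 2 -x 1 --out sim/
kurafit fit-grid --dim 2 --sc ... --pl ... --empfc ... --frequencies ... --out fit/
kurafit fit-opt --method cmaes --dim 2 --runs 15 --sc ... --out fit/
kurafit evaluate --in fit/ --out eval/ --levels 0.5,0.8
```

Matrices travel as tab-delimited text; every command writes a JSON manifest
(seeds, config, input digests) sufficient to replay a fixed-noise run
bit-exactly.

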