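"""Derivative-free maximizers of the goal function over a bounded box.

Four methods, spanning local deterministic (Nelder-Mead), population-based
stochastic (particle swarm, CMA-ES) and surrogate-based (Bayesian
optimization with a Gaussian-process model) search.  All methods operate
internally on the normalized unit box [0, 1]^Dim and report physical
coordinates; maximization is implemented directly (equivalently, as
minimization of -F).  Default budgets follow the benchmarking protocol:
at most 80 iterations, with early stopping for PSO/CMA-ES after 50
consecutive iterations without strict improvement of the incumbent best,
and a simplex edge-length tolerance for Nelder-Mead.

Population sizes: Dim+1 (NMA simplex), 60 (PSO), 24 (CMA-ES, so mu = 12
parents), 5 (BO initial design in 2Dim) or 10 (3Dim).  PSO velocity
coefficients, the NMA edge tolerance, the BO kernel/acquisition and the
CMA-ES initial step size are configuration with standard literature
defaults, not protocol constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _sp_minimize
from scipy.stats import norm as _norm

from ._seeds import child_seed
from .evaluation import RunSet

__all__ = [
    "BoxBounds",
    "OptimizerConfig",
    "OptimizerRun",
    "nelder_mead",
    "particle_swarm",
    "cmaes",
    "bayesian_opt",
    "run_replicates",
    "default_cma_population",
    "METHODS",
]


def default_cma_population(dim: int) -> int:
    """Literature default population 4 + floor(3*ln(Dim)) (the study used 24)."""
    return 4 + int(math.floor(3.0 * math.log(dim)))


@dataclass
class BoxBounds:
    """Axis-aligned feasible box with unit-box normalization helpers."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @classmethod
    def default(cls, dim: int) -> "BoxBounds":
        """[0,1] x [0,100] for (C, tau), plus [0,2] for sigma when dim == 3."""
        if dim == 2:
            return cls(np.array([0.0, 0.0]), np.array([1.0, 100.0]))
        if dim == 3:
            return cls(np.array([0.0, 0.0, 0.0]), np.array([1.0, 100.0, 2.0]))
        raise ValueError("dim must be 2 or 3")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - 1e-12) and np.all(x <= self.upper + 1e-12))

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)


@dataclass
class OptimizerConfig:
    """Budgets and method hyperparameters.

    ``population`` means: simplex size for NMA, swarm size for PSO,
    offspring count Lambda for CMA-ES, initial-design size for BO.
    """

    method: str
    population: int
    max_iterations: int = 80
    stall_window: int = 50
    nma_edge_tol: float = 0.01
    nma_simplex_scale: float = 0.05
    pso_inertia: float = 0.7298
    pso_cognitive: float = 1.49618
    pso_social: float = 1.49618
    cmaes_sigma0: float = 0.3
    bo_candidates: int = 256
    bo_xi: float = 0.0  # EI exploration margin; GP uncertainty drives exploration
    bo_noise_level: float | None = None  # None -> fitted WhiteKernel
    seed: int | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (1 <= self.stall_window <= self.max_iterations):
            raise ValueError("stall_window must lie in [1, max_iterations]")

    @classmethod
    def for_method(cls, method: str, dim: int, **overrides) -> "OptimizerConfig":
        method = method.lower()
        populations = {"nma": dim + 1, "pso": 60, "cmaes": 24, "bo": 5 if dim == 2 else 10}
        if method not in populations:
            raise ValueError(f"unknown method {method!r}; expected one of {sorted(populations)}")
        cfg = cls(method=method, population=populations[method])
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class OptimizerRun:
    """Outcome of one optimizer execution."""

    method: str
    best_point: np.ndarray  # physical coordinates
    best_point_norm: np.ndarray  # same point on the unit box
    best_fit: float
    n_iterations: int
    n_evaluations: int
    termination_reason: str  # max_iter | stall | simplex_tol
    history: np.ndarray  # per-iteration incumbent best fit (nondecreasing)
    seed: int
    notes: list[str] = field(default_factory=list)


class _Recorder:
    """Wraps the physical-coordinate goal; tracks evaluations and the incumbent."""

    def __init__(self, goal, bounds: BoxBounds):
        self._goal = goal
        self._bounds = bounds
        self.n_evaluations = 0
        self.best_fit = -np.inf
        self.best_u: np.ndarray | None = None

    def __call__(self, u: np.ndarray) -> float:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        fit = float(self._goal(self._bounds.from_unit(u)))
        self.n_evaluations += 1
        if fit > self.best_fit:
            self.best_fit = fit
            self.best_u = u.copy()
        return fit


def _finish(method, rec, bounds, history, n_iter, reason, seed, notes=None) -> OptimizerRun:
    u = rec.best_u if rec.best_u is not None else np.full(bounds.dim, 0.5)
    return OptimizerRun(
        method=method,
        best_point=bounds.from_unit(u),
        best_point_norm=u,
        best_fit=rec.best_fit,
        n_iterations=n_iter,
        n_evaluations=rec.n_evaluations,
        termination_reason=reason,
        history=np.asarray(history, dtype=float),
        seed=seed,
        notes=notes or [],
    )


def nelder_mead(goal, bounds: BoxBounds, config: OptimizerConfig | None = None,
                seed: int = 0) -> OptimizerRun:
    """Nelder-Mead simplex search (Lagarias coefficients) on the unit box.

    Reflection 1, expansion 2, contraction 0.5, shrink 0.5.  The initial
    simplex is a random interior point plus one axis perturbation of 0.05
    per dimension; candidate points are projected onto the box before
    evaluation.  Stops when the longest simplex edge falls below
    ``nma_edge_tol`` (normalized) or after ``max_iterations``.
    """
    if config is None:
        config = OptimizerConfig.for_method("nma", bounds.dim)
    dim = bounds.dim
    rng = np.random.default_rng(seed)
    rec = _Recorder(goal, bounds)
    x0 = rng.uniform(0.05, 0.95, dim)
    simplex = [x0]
    for d in range(dim):
        v = x0.copy()
        v[d] = min(v[d] + config.nma_simplex_scale, 1.0)
        simplex.append(v)
    simplex = np.asarray(simplex)
    fvals = np.array([rec(v) for v in simplex])
    history = [rec.best_fit]
    reason = "max_iter"
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        order = np.argsort(-fvals)  # descending: best first (maximization)
        simplex, fvals = simplex[order], fvals[order]
        edges = max(
            np.linalg.norm(simplex[i] - simplex[j])
            for i in range(dim + 1) for j in range(i + 1, dim + 1)
        )
        if edges < config.nma_edge_tol:
            reason = "simplex_tol"
            n_iter -= 1
            break
        centroid = simplex[:-1].mean(axis=0)
        worst = simplex[-1]
        xr = np.clip(centroid + 1.0 * (centroid - worst), 0.0, 1.0)
        fr = rec(xr)
        if fr > fvals[0]:  # better than the best: try expansion
            xe = np.clip(centroid + 2.0 * (centroid - worst), 0.0, 1.0)
            fe = rec(xe)
            if fe > fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr > fvals[-2]:  # better than second worst: accept reflection
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr > fvals[-1]:  # outside contraction
                xc = np.clip(centroid + 0.5 * (centroid - worst), 0.0, 1.0)
            else:  # inside contraction
                xc = np.clip(centroid - 0.5 * (centroid - worst), 0.0, 1.0)
            fcv = rec(xc)
            if fcv > min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fcv
            else:  # shrink towards the best vertex
                for i in range(1, dim + 1):
                    simplex[i] = np.clip(
                        simplex[0] + 0.5 * (simplex[i] - simplex[0]), 0.0, 1.0
                    )
                    fvals[i] = rec(simplex[i])
        history.append(rec.best_fit)
    return _finish("nma", rec, bounds, history, n_iter, reason, seed)


def particle_swarm(goal, bounds: BoxBounds, config: OptimizerConfig | None = None,
                   seed: int = 0) -> OptimizerRun:
    """Constriction-type PSO: v <- w*v + c1*r1*(pbest-x) + c2*r2*(gbest-x).

    Positions are clamped to the box with the violating velocity component
    zeroed.  Stops at ``max_iterations`` or when the global best has not
    strictly improved for ``stall_window`` consecutive iterations.
    """
    if config is None:
        config = OptimizerConfig.for_method("pso", bounds.dim)
    dim = bounds.dim
    lam = config.population
    rng = np.random.default_rng(seed)
    rec = _Recorder(goal, bounds)
    x = rng.uniform(0.0, 1.0, (lam, dim))
    v = np.zeros((lam, dim))
    f = np.array([rec(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    history = [rec.best_fit]
    last_improve = 0
    reason = "max_iter"
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        gbest = pbest_x[np.argmax(pbest_f)]
        r1 = rng.uniform(0.0, 1.0, (lam, dim))
        r2 = rng.uniform(0.0, 1.0, (lam, dim))
        v = (
            config.pso_inertia * v
            + config.pso_cognitive * r1 * (pbest_x - x)
            + config.pso_social * r2 * (gbest[None, :] - x)
        )
        x = x + v
        out_low, out_high = x < 0.0, x > 1.0
        v[out_low | out_high] = 0.0
        x = np.clip(x, 0.0, 1.0)
        prev_best = rec.best_fit
        f = np.array([rec(xi) for xi in x])
        better = f > pbest_f
        pbest_x[better], pbest_f[better] = x[better], f[better]
        history.append(rec.best_fit)
        if rec.best_fit > prev_best:
            last_improve = n_iter
        if n_iter - last_improve >= config.stall_window:
            reason = "stall"
            break
    return _finish("pso", rec, bounds, history, n_iter, reason, seed)


def cmaes(goal, bounds: BoxBounds, config: OptimizerConfig | None = None,
          seed: int = 0) -> OptimizerRun:
    """Covariance matrix adaptation evolution strategy on the unit box.

    Standard update loop: selection weights w_i ~ ln(mu+1/2) - ln(i) over the
    mu = floor(Lambda/2) best samples, cumulative step-size adaptation, and
    rank-one plus rank-mu covariance updates.  The initial mean is uniform in
    the box with step size ``cmaes_sigma0``; out-of-box samples are projected
    onto the box (the projected point is both evaluated and used in the
    update).  Stops at ``max_iterations`` or on a ``stall_window`` of no
    strict improvement.  Loss of positive definiteness is repaired by
    eigenvalue flooring and logged in the run notes.
    """
    if config is None:
        config = OptimizerConfig.for_method("cmaes", bounds.dim)
    n = bounds.dim
    lam = config.population
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    rng = np.random.default_rng(seed)
    rec = _Recorder(goal, bounds)
    notes: list[str] = []
    xmean = rng.uniform(0.0, 1.0, n)
    sigma = config.cmaes_sigma0
    pc = np.zeros(n)
    ps = np.zeros(n)
    cov = np.eye(n)
    history: list[float] = []
    last_improve = 0
    reason = "max_iter"
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2.0)
        if np.any(evals <= 0):
            floor = 1e-14 * max(1.0, float(evals.max()))
            evals = np.maximum(evals, floor)
            notes.append(f"iteration {n_iter}: covariance repaired by eigenvalue flooring")
        d_sqrt = np.sqrt(evals)
        inv_sqrt_c = evecs @ np.diag(1.0 / d_sqrt) @ evecs.T
        z = rng.standard_normal((lam, n))
        xs = xmean[None, :] + sigma * (z * d_sqrt[None, :]) @ evecs.T
        xs = np.clip(xs, 0.0, 1.0)  # projection repair
        prev_best = rec.best_fit
        fs = np.array([rec(xi) for xi in xs])
        order = np.argsort(-fs)[:mu]
        xold = xmean
        xmean = w @ xs[order]
        y = (xmean - xold) / sigma
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * (inv_sqrt_c @ y)
        hsig = (
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * n_iter)) / chi_n
            < 1.4 + 2.0 / (n + 1)
        )
        pc = (1 - cc) * pc + (math.sqrt(cc * (2 - cc) * mueff) * y if hsig else 0.0)
        artmp = (xs[order] - xold[None, :]) / sigma
        cov = (
            (1 - c1 - cmu) * cov
            + c1 * (np.outer(pc, pc) + (0.0 if hsig else cc * (2 - cc)) * cov)
            + cmu * (artmp.T * w) @ artmp
        )
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1.0))
        sigma = float(min(sigma, 10.0))
        history.append(rec.best_fit)
        # the first generation only establishes the incumbent baseline
        if np.isfinite(prev_best) and rec.best_fit > prev_best:
            last_improve = n_iter
        if n_iter - last_improve >= config.stall_window:
            reason = "stall"
            break
    return _finish("cmaes", rec, bounds, history, n_iter, reason, seed, notes)


def _fit_gp(x, y, noise_level, random_state, prev_kernel=None):
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    if noise_level is None:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=0.2 * np.ones(x.shape[1]), length_scale_bounds=(1e-2, 1e1), nu=2.5
        ) + WhiteKernel(1e-4, (1e-10, 1e-1))
    else:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=0.2 * np.ones(x.shape[1]), length_scale_bounds=(1e-2, 1e1), nu=2.5
        ) + WhiteKernel(noise_level, "fixed")
    if prev_kernel is not None:  # freeze previously fitted hyperparameters
        gp = GaussianProcessRegressor(
            kernel=prev_kernel, normalize_y=True, optimizer=None,
            random_state=random_state,
        )
    else:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=1,
            random_state=random_state,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(x, y)
    return gp


def _expected_improvement(gp, cand: np.ndarray, y_best: float, xi: float) -> np.ndarray:
    mu, sd = gp.predict(cand, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (mu - y_best - xi) / sd
    return (mu - y_best - xi) * _norm.cdf(z) + sd * _norm.pdf(z)


def bayesian_opt(goal, bounds: BoxBounds, config: OptimizerConfig | None = None,
                 seed: int = 0) -> OptimizerRun:
    """Bayesian optimization with a Gaussian-process surrogate.

    Matern-5/2 kernel plus an observation-noise term, hyperparameters refit
    by marginal-likelihood maximization at each iteration (falling back to
    the previous hyperparameters on a degenerate fit); acquisition is
    expected improvement (margin ``bo_xi``, zero by default so the posterior
    uncertainty alone drives exploration), maximized by a random candidate
    sweep followed by bounded local search from the best candidates.  Runs
    exactly ``max_iterations`` acquisition steps after the initial design.
    """
    if config is None:
        config = OptimizerConfig.for_method("bo", bounds.dim)
    dim = bounds.dim
    rng = np.random.default_rng(seed)
    rec = _Recorder(goal, bounds)
    notes: list[str] = []
    x = rng.uniform(0.0, 1.0, (config.population, dim))
    y = np.array([rec(xi) for xi in x])
    history = [rec.best_fit]
    gp = None
    prev_kernel = None
    for n_iter in range(1, config.max_iterations + 1):
        try:
            gp = _fit_gp(x, y, config.bo_noise_level,
                         random_state=child_seed(seed, n_iter) % (2**31), prev_kernel=None)
            prev_kernel = gp.kernel_
        except Exception:  # degenerate fit: reuse previous hyperparameters
            notes.append(f"iteration {n_iter}: GP refit failed, reusing previous kernel")
            gp = _fit_gp(x, y, config.bo_noise_level,
                         random_state=child_seed(seed, n_iter) % (2**31),
                         prev_kernel=prev_kernel)
        y_best = float(y.max())
        cand = rng.uniform(0.0, 1.0, (config.bo_candidates, dim))
        jitter = np.clip(
            x[np.argmax(y)][None, :] + 0.05 * rng.standard_normal((16, dim)), 0.0, 1.0
        )
        cand = np.vstack([cand, jitter])
        ei = _expected_improvement(gp, cand, y_best, config.bo_xi)
        starts = cand[np.argsort(-ei)[:3]]

        def neg_ei(u):
            return -float(_expected_improvement(gp, u[None, :], y_best, config.bo_xi)[0])

        best_u, best_val = starts[0], -np.inf
        for s in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _sp_minimize(neg_ei, s, method="L-BFGS-B",
                                   bounds=[(0.0, 1.0)] * dim)
            if -res.fun > best_val:
                best_val, best_u = -res.fun, np.clip(res.x, 0.0, 1.0)
        fnew = rec(best_u)
        x = np.vstack([x, best_u[None, :]])
        y = np.append(y, fnew)
        history.append(rec.best_fit)
    run = _finish("bo", rec, bounds, history, config.max_iterations, "max_iter", seed, notes)
    run.surrogate = gp  # final fitted surrogate, for inspection
    return run


METHODS = {
    "nma": nelder_mead,
    "pso": particle_swarm,
    "cmaes": cmaes,
    "bo": bayesian_opt,
}


def run_replicates(
    method: str,
    goal,
    bounds: BoxBounds,
    config: OptimizerConfig | None = None,
    n_runs: int = 15,
    master_seed: int = 0,
    subject_id: str | None = None,
    time_unit: float = 1.0,
) -> RunSet:
    """Execute ``n_runs`` independent optimizer runs with distinct child seeds.

    Assembles the replicate protocol's Fit vector and Points matrix
    (normalized coordinates) plus a per-run time proxy (goal evaluations
    times ``time_unit``).
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = OptimizerConfig.for_method(method, bounds.dim)
    runs: list[OptimizerRun] = []
    failures: list[str] = []
    for r in range(n_runs):
        run_seed = child_seed(master_seed, r)
        try:
            runs.append(METHODS[method](goal, bounds, config, seed=run_seed))
        except Exception as exc:  # record and continue; RunSet flags incompleteness
            failures.append(f"run {r} (seed {run_seed}): {exc}")
    if not runs:
        raise RuntimeError(f"all {n_runs} runs of {method} failed: {failures}")
    fits = np.array([run.best_fit for run in runs])
    points = np.vstack([run.best_point_norm for run in runs])
    time_proxy = np.array([run.n_evaluations * time_unit for run in runs])
    return RunSet(
        fits=fits, points=points, time_proxy=time_proxy,
        subject_id=subject_id, method=method, runs=runs, failures=failures,
    )
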