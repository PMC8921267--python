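"""Goal function and exhaustive grid-search baseline.

The model fit of a parameter point (C, tau[, sigma]) is the Pearson
correlation F between the simulated FC at that point and the subject's
empirical FC, computed over the strictly upper triangles of both matrices
(the constant unit diagonal would artificially inflate the correlation and
is excluded).  The grid search evaluates F on a dense lattice and serves as
the approximate ground truth against which the derivative-free optimizers
are benchmarked.

Default grids:

* 2Dim: 64 equidistant couplings C on [0, 0.945] x 48 equidistant delays
  tau on [0, 94] s, noise fixed at sigma = 0.3 (3072 nodes);
* 3Dim: 48 equidistant C on [0, 0.94] x 22 delays on [0, 48] s placed
  quadratically (tau_m = 48*(m/21)^2, denser near zero) x 81 equidistant
  sigma on [0, 2] (85536 nodes).
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._seeds import SeedPolicy
from .fc import FCMatrix
from .model import Connectome, ModelParams, simulate_fc

__all__ = [
    "SimSettings",
    "EvaluationCounter",
    "GoalEvaluation",
    "GridSpec",
    "GridResult",
    "fc_similarity",
    "goal_function",
    "make_goal",
    "make_grid",
    "run_grid_search",
    "DEFAULT_FIXED_SIGMA",
]

DEFAULT_FIXED_SIGMA = 0.3


@dataclass
class SimSettings:
    """Integration and downsampling settings shared by all goal evaluations."""

    dt: float = 0.06
    tr: float = 0.72
    duration: float = 4000.0
    transient: float = 500.0
    fixed_sigma: float = DEFAULT_FIXED_SIGMA  # noise intensity used when dim == 2


class EvaluationCounter:
    """Shared audit counter of goal-function evaluations."""

    def __init__(self) -> None:
        self.n = 0

    def add(self, k: int = 1) -> None:
        self.n += k


@dataclass
class GoalEvaluation:
    fit: float
    point: tuple[float, ...]
    seed: int
    n_sim_seconds: float


def fc_similarity(sim: FCMatrix, emp: FCMatrix) -> float:
    """Pearson correlation of the strictly-upper-triangle entries of two FCs."""
    if sim.n_regions != emp.n_regions:
        raise ValueError(
            f"FC sizes differ: {sim.n_regions} vs {emp.n_regions} regions"
        )
    a = sim.upper_triangle()
    b = emp.upper_triangle()
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance in an FC upper triangle; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _params_from_point(
    point: tuple[float, ...], frequencies: np.ndarray, sim_settings: SimSettings
) -> ModelParams:
    if len(point) == 2:
        c, tau = point
        sigma = sim_settings.fixed_sigma
    elif len(point) == 3:
        c, tau, sigma = point
    else:
        raise ValueError(f"point must have 2 or 3 coordinates, got {len(point)}")
    return ModelParams(
        coupling_c=float(c),
        delay_tau=float(tau),
        noise_sigma=float(sigma),
        frequencies=frequencies,
        dt=sim_settings.dt,
        tr=sim_settings.tr,
        duration=sim_settings.duration,
        transient=sim_settings.transient,
    )


def goal_function(
    connectome: Connectome,
    empfc: FCMatrix,
    point: tuple[float, ...],
    frequencies: np.ndarray,
    sim_settings: SimSettings,
    seed_policy: SeedPolicy,
    counter: EvaluationCounter | None = None,
    bounds=None,
    seed: int | None = None,
) -> GoalEvaluation:
    """Evaluate F(point) = fc_similarity(simFC(point), empFC).

    The noise seed comes from ``seed_policy`` (fresh child seed per
    evaluation by default; fixed-seed mode for deterministic tests) unless an
    explicit ``seed`` override is given.  Every evaluation increments the
    shared audit ``counter`` when one is supplied.  Points outside ``bounds``
    (a BoxBounds, optional) raise: callers must project first.
    """
    if bounds is not None and not bounds.contains(np.asarray(point, dtype=float)):
        raise ValueError(f"point {point} lies outside the feasible box")
    params = _params_from_point(tuple(point), frequencies, sim_settings)
    use_seed = seed_policy.next_seed() if seed is None else int(seed)
    simfc = simulate_fc(connectome, params, use_seed)
    if counter is not None:
        counter.add()
    fit = fc_similarity(simfc, empfc)
    return GoalEvaluation(
        fit=fit, point=tuple(float(x) for x in point), seed=use_seed,
        n_sim_seconds=sim_settings.duration,
    )


def make_goal(
    connectome: Connectome,
    empfc: FCMatrix,
    frequencies: np.ndarray,
    sim_settings: SimSettings,
    seed_policy: SeedPolicy,
    counter: EvaluationCounter | None = None,
    bounds=None,
):
    """Bind the study inputs into a callable ``goal(point) -> fit`` used by optimizers."""

    def goal(point) -> float:
        return goal_function(
            connectome, empfc, tuple(np.asarray(point, dtype=float)),
            frequencies, sim_settings, seed_policy, counter=counter, bounds=bounds,
        ).fit

    return goal


@dataclass
class GridSpec:
    """Axes of the parameter lattice; sigma_axis has one entry when dim == 2."""

    c_axis: np.ndarray
    tau_axis: np.ndarray
    sigma_axis: np.ndarray
    dim: int

    def __post_init__(self):
        self.c_axis = np.asarray(self.c_axis, dtype=float)
        self.tau_axis = np.asarray(self.tau_axis, dtype=float)
        self.sigma_axis = np.asarray(self.sigma_axis, dtype=float)
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        axes = [self.c_axis, self.tau_axis]
        if self.dim == 3:
            axes.append(self.sigma_axis)
        for ax in axes:
            if ax.size < 1 or np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be nonempty and strictly increasing")

    @property
    def n_nodes(self) -> int:
        n = self.c_axis.size * self.tau_axis.size
        if self.dim == 3:
            n *= self.sigma_axis.size
        return n

    def nodes(self):
        """All lattice points, C-major then tau then sigma."""
        if self.dim == 2:
            return [
                (float(c), float(t)) for c, t in itertools.product(self.c_axis, self.tau_axis)
            ]
        return [
            (float(c), float(t), float(s))
            for c, t, s in itertools.product(self.c_axis, self.tau_axis, self.sigma_axis)
        ]


def make_grid(dim: int = 2, c_axis=None, tau_axis=None, sigma_axis=None) -> GridSpec:
    """Default (or overridden) grids for the 2Dim and 3Dim parameter spaces."""
    if dim == 2:
        c = np.linspace(0.0, 0.945, 64) if c_axis is None else np.asarray(c_axis, float)
        t = np.linspace(0.0, 94.0, 48) if tau_axis is None else np.asarray(tau_axis, float)
        s = np.asarray([DEFAULT_FIXED_SIGMA]) if sigma_axis is None else np.asarray(sigma_axis, float)
        return GridSpec(c_axis=c, tau_axis=t, sigma_axis=s, dim=2)
    if dim == 3:
        c = np.linspace(0.0, 0.94, 48) if c_axis is None else np.asarray(c_axis, float)
        if tau_axis is None:
            m = np.arange(22)
            t = 48.0 * (m / 21.0) ** 2  # denser for small delays
        else:
            t = np.asarray(tau_axis, float)
        s = np.linspace(0.0, 2.0, 81) if sigma_axis is None else np.asarray(sigma_axis, float)
        return GridSpec(c_axis=c, tau_axis=t, sigma_axis=s, dim=3)
    raise ValueError(f"dim must be 2 or 3, got {dim}")


@dataclass
class GridResult:
    fits: np.ndarray
    points: list[tuple[float, ...]]
    best_point: tuple[float, ...]
    best_fit: float
    top_points: list[tuple[tuple[float, ...], float]]  # 5 best (point, fit), descending
    n_evaluations: int
    seeds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_point": self.best_point,
                "best_fit": self.best_fit,
                "top_points": [{"point": p, "fit": f} for p, f in self.top_points],
                "n_evaluations": self.n_evaluations,
                "seeds": self.seeds,
            },
            indent=2,
        )


def _load_checkpoint(path: str) -> dict[int, tuple[float, int]]:
    done: dict[int, tuple[float, int]] = {}
    if path and os.path.exists(path):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                done[int(rec["index"])] = (float(rec["fit"]), int(rec["seed"]))
    return done


def run_grid_search(
    connectome: Connectome | None,
    empfc: FCMatrix | None,
    grid: GridSpec,
    frequencies: np.ndarray | None = None,
    sim_settings: SimSettings | None = None,
    seed_policy: SeedPolicy | None = None,
    counter: EvaluationCounter | None = None,
    dry_run: bool = False,
    checkpoint: str | None = None,
    n_jobs: int = 1,
    goal=None,
) -> GridResult:
    """Evaluate the goal function at every grid node exactly once.

    ``dry_run=True`` skips the simulations but still iterates the nodes and
    increments the audit counter, for sweep-size accounting.  With a
    ``checkpoint`` path, one JSON record per completed node is appended and
    resuming skips completed nodes.  Node seeds are drawn up front from the
    seed policy, so parallel execution (``n_jobs``) gives results identical
    to a serial run.  A deterministic surrogate ``goal(point) -> fit``
    callable may replace the simulator-backed goal function.
    """
    points = grid.nodes()
    n = len(points)
    if dry_run:
        cnt = counter if counter is not None else EvaluationCounter()
        for _ in range(n):
            cnt.add()
        fits = np.zeros(n)
        order = list(range(min(5, n)))
        return GridResult(
            fits=fits, points=points, best_point=points[0], best_fit=0.0,
            top_points=[(points[i], 0.0) for i in order], n_evaluations=n, seeds=[],
        )
    if goal is None and (
        connectome is None or empfc is None or frequencies is None or sim_settings is None
    ):
        raise ValueError("non-dry-run grid search needs connectome, empfc, frequencies, sim_settings")
    if seed_policy is None:
        seed_policy = SeedPolicy(0, "fresh")
    seeds = [seed_policy.next_seed() for _ in range(n)]
    done = _load_checkpoint(checkpoint) if checkpoint else {}
    fits = np.full(n, np.nan)
    for idx, (f, s) in done.items():
        if idx < n:
            fits[idx] = f
            seeds[idx] = s
    todo = [i for i in range(n) if not np.isfinite(fits[i])]

    def _eval(i: int) -> float:
        if goal is not None:
            return float(goal(points[i]))
        ev = goal_function(
            connectome, empfc, points[i], frequencies, sim_settings,
            seed_policy, counter=None, seed=seeds[i],
        )
        return ev.fit

    ckpt_fh = open(checkpoint, "a") if checkpoint else None
    try:
        if n_jobs != 1 and len(todo) > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=n_jobs)(delayed(_eval)(i) for i in todo)
            for i, f in zip(todo, results):
                fits[i] = f
                if ckpt_fh:
                    ckpt_fh.write(json.dumps({"index": i, "fit": f, "seed": seeds[i]}) + "\n")
                    ckpt_fh.flush()
        else:
            for i in todo:
                fits[i] = _eval(i)
                if ckpt_fh:
                    ckpt_fh.write(json.dumps({"index": i, "fit": fits[i], "seed": seeds[i]}) + "\n")
                    ckpt_fh.flush()
    finally:
        if ckpt_fh:
            ckpt_fh.close()
    if counter is not None:
        counter.add(len(todo))
    order = np.argsort(-fits, kind="stable")
    top = [(points[i], float(fits[i])) for i in order[: min(5, n)]]
    best = order[0]
    return GridResult(
        fits=fits, points=points, best_point=points[best], best_fit=float(fits[best]),
        top_points=top, n_evaluations=n, seeds=seeds,
    )
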