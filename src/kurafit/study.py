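"""Scaled-down end-to-end benchmarking study on a synthetic cohort.

This module wires the full pipeline together at desk scale: generate a
cohort of ground-truth subjects (connectome + simulated-FC-as-empirical-FC
at known parameters), run the 2Dim grid-search baseline and replicate runs
of all four optimizers against each subject, and evaluate the outcome down
to the per-subject cost scores, recommendations and the winner.

Default study conditions (chosen once; see the methods note):

* 8 subjects, N = 20 regions, connectome density 0.35;
* natural frequencies uniform in [0.02, 0.09] Hz, inside the resting-state
  band;
* ground truth at C* ~ U[0.35, 0.75], tau* ~ U[0, 12] s, sigma* = 0.3;
* simulations of 180 s with an 18 s transient (dt = 0.06 s, TR = 0.72 s,
  226 retained samples), fresh noise per goal evaluation;
* a 16 x 12 grid on [0, 0.945] x [0, 30] s and optimizer bounds
  [0, 1] x [0, 30] s — with 180-s simulations the global delay is capped at
  30 s so that pairwise delays stay well below the simulated duration;
* scaled optimizer budgets: 25 iterations, stall window 20, swarm 16,
  CMA-ES population 12, BO initial design 5, 5 replicates per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import SeedFactory, SeedPolicy
from .cohort import CohortConfig, generate_connectome, make_ground_truth_subject
from .evaluation import (
    CostMatrix,
    GridTop,
    Recommendations,
    RunSet,
    SuccessCurve,
    aggregate_costs,
    cost_components,
    recommend,
    runs_for_level,
    success_curve,
)
from .fc import FCMatrix
from .fit import (
    EvaluationCounter,
    GridResult,
    SimSettings,
    make_goal,
    make_grid,
    run_grid_search,
)
from .model import Connectome, ModelParams
from .optimizers import BoxBounds, OptimizerConfig, run_replicates

__all__ = ["StudyConfig", "SubjectResult", "StudyResult", "run_study", "study_summary"]

METHOD_NAMES = ("nma", "pso", "cmaes", "bo")


@dataclass
class StudyConfig:
    n_subjects: int = 8
    n_regions: int = 20
    density: float = 0.35
    length_range: tuple[float, float] = (10.0, 120.0)
    freq_band: tuple[float, float] = (0.02, 0.09)
    truth_c_range: tuple[float, float] = (0.35, 0.75)
    truth_tau_range: tuple[float, float] = (0.0, 12.0)
    sigma: float = 0.3
    sim: SimSettings = field(
        default_factory=lambda: SimSettings(duration=180.0, transient=18.0, fixed_sigma=0.3)
    )
    grid_shape: tuple[int, int] = (16, 12)
    c_max: float = 0.945
    tau_max: float = 30.0
    n_replicates: int = 5
    max_iterations: int = 25
    stall_window: int = 20
    populations: dict = field(
        default_factory=lambda: {"nma": 3, "pso": 16, "cmaes": 12, "bo": 5}
    )
    success_threshold: float = 0.95
    n_resamples: int = 500
    levels: tuple[float, ...] = (0.5, 0.8)


@dataclass
class SubjectResult:
    subject_id: str
    connectome: Connectome
    frequencies: np.ndarray
    truth_point: tuple[float, float]
    empfc: FCMatrix
    grid_result: GridResult
    grid_top: GridTop
    runsets: dict[str, RunSet]


@dataclass
class StudyResult:
    config: StudyConfig
    seed: int
    subjects: list[SubjectResult]
    curves: dict[str, SuccessCurve]
    runs_to_level: dict[str, dict[float, tuple[int, bool]]]
    costs: CostMatrix
    recommendations: Recommendations
    n_goal_evaluations: int


def _bounds(config: StudyConfig) -> BoxBounds:
    return BoxBounds(np.array([0.0, 0.0]), np.array([1.0, config.tau_max]))


def _run_subject(config: StudyConfig, sf: SeedFactory, s: int,
                 counter: EvaluationCounter) -> SubjectResult:
    cohort_cfg = CohortConfig(
        n_subjects=config.n_subjects, n_regions=config.n_regions,
        density=config.density, length_range=config.length_range,
        master_seed=sf.master_seed,
    )
    conn = generate_connectome(cohort_cfg, sf.child(s, 0))
    rng = np.random.default_rng(sf.child(s, 1))
    freqs = rng.uniform(*config.freq_band, config.n_regions)
    c_star = float(rng.uniform(*config.truth_c_range))
    tau_star = float(rng.uniform(*config.truth_tau_range))
    truth_params = ModelParams(
        coupling_c=c_star, delay_tau=tau_star, noise_sigma=config.sigma,
        frequencies=freqs, dt=config.sim.dt, tr=config.sim.tr,
        duration=config.sim.duration, transient=config.sim.transient,
    )
    empfc = make_ground_truth_subject(conn, truth_params, sf.child(s, 2))

    grid = make_grid(
        2,
        c_axis=np.linspace(0.0, config.c_max, config.grid_shape[0]),
        tau_axis=np.linspace(0.0, config.tau_max, config.grid_shape[1]),
    )
    grid_result = run_grid_search(
        conn, empfc, grid, freqs, config.sim,
        seed_policy=SeedPolicy(sf.child(s, 3), "fresh"), counter=counter,
    )
    bounds = _bounds(config)
    grid_top = GridTop(
        points=np.vstack([bounds.to_unit(np.asarray(p)) for p, _ in grid_result.top_points]),
        fits=np.array([f for _, f in grid_result.top_points]),
        best_fit=grid_result.best_fit,
    )
    runsets: dict[str, RunSet] = {}
    for mi, method in enumerate(METHOD_NAMES):
        goal = make_goal(
            conn, empfc, freqs, config.sim,
            SeedPolicy(sf.child(s, 10 + mi), "fresh"), counter=counter,
        )
        opt_cfg = OptimizerConfig.for_method(
            method, bounds.dim,
            population=config.populations[method],
            max_iterations=config.max_iterations,
            stall_window=config.stall_window,
        )
        runsets[method] = run_replicates(
            method, goal, bounds, config=opt_cfg,
            n_runs=config.n_replicates, master_seed=sf.child(s, 20 + mi),
            subject_id=f"sub{s:02d}",
        )
    return SubjectResult(
        subject_id=f"sub{s:02d}", connectome=conn, frequencies=freqs,
        truth_point=(c_star, tau_star), empfc=empfc,
        grid_result=grid_result, grid_top=grid_top, runsets=runsets,
    )


def run_study(seed: int, config: StudyConfig | None = None) -> StudyResult:
    """Execute the full pipeline and evaluation for a synthetic cohort."""
    if config is None:
        config = StudyConfig()
    sf = SeedFactory(seed)
    counter = EvaluationCounter()
    subjects = [
        _run_subject(config, sf, s, counter) for s in range(config.n_subjects)
    ]
    grid_bests = [sub.grid_result.best_fit for sub in subjects]
    curves: dict[str, SuccessCurve] = {}
    runs_to_level: dict[str, dict[float, tuple[int, bool]]] = {}
    breakdowns = {}
    for mi, method in enumerate(METHOD_NAMES):
        fits = [sub.runsets[method].fits for sub in subjects]
        curves[method] = success_curve(
            fits, grid_bests, threshold_fraction=config.success_threshold,
            n_resamples=config.n_resamples, seed=sf.child(900 + mi),
        )
        runs_to_level[method] = {
            lvl: runs_for_level(curves[method], lvl) for lvl in config.levels
        }
        n80, _reached = runs_to_level[method][0.8] if 0.8 in config.levels else (
            runs_for_level(curves[method], 0.8)
        )
        for sub in subjects:
            rs = sub.runsets[method]
            time_for_80 = n80 * float(rs.time_proxy.mean())
            breakdowns[(sub.subject_id, method)] = cost_components(
                rs, sub.grid_top, time_for_80
            )
    costs = aggregate_costs(breakdowns)
    recs = recommend(costs)
    return StudyResult(
        config=config, seed=seed, subjects=subjects, curves=curves,
        runs_to_level=runs_to_level, costs=costs, recommendations=recs,
        n_goal_evaluations=counter.n,
    )


def study_summary(result: StudyResult) -> dict:
    """Headline numbers of a study run, for reports and serialization."""
    grid_bests = np.array([s.grid_result.best_fit for s in result.subjects])
    summary: dict = {
        "n_subjects": len(result.subjects),
        "n_goal_evaluations": result.n_goal_evaluations,
        "grid_best_fit_mean": float(grid_bests.mean()),
        "winner": result.recommendations.winner,
        "recommendation_tally": dict(result.recommendations.tally),
    }
    thr = result.config.success_threshold
    for method in METHOD_NAMES:
        best = np.array([s.runsets[method].fits.max() for s in result.subjects])
        summary[f"{method}_best_fit_mean"] = float(best.mean())
        summary[f"{method}_success_fraction"] = float(
            np.mean(best >= thr * grid_bests)
        )
        summary[f"{method}_runs_to_80"] = result.runs_to_level[method][0.8][0]
    return summary
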