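"""Optimizer comparison machinery.

Given R_max replicate runs per subject and method (the Fit vector and the
Points matrix of optimal parameters in normalized coordinates) and the top-5
grid-search nodes per subject, this module computes:

* success probabilities: the cohort-averaged chance that at least one of R
  randomly drawn runs reaches ``threshold_fraction`` (default 95%) of the
  grid-search best fit, estimated by resampling without replacement (500
  draws per R by default).  Because draws are without replacement, the
  probability has the hypergeometric closed form
  1 - C(R_max - m, R)/C(R_max, R) with m passing runs, used as an oracle.
* runs-to-level: the smallest R whose success probability reaches a given
  level (50% and 80% in the protocol); R_max with a "not reached" flag
  otherwise.
* the five-component multiplicative cost score per subject and method:
  (1 - max Fit) * population-SD(Fit) * Time * mean pairwise distance of the
  solution points * mean distance to the nearest of the 5 grid optima, each
  component normalized by its maximum over all subjects and methods before
  the product is taken.  Lower is better; the per-subject argmin is the
  recommended method and the method with the most recommendations is the
  winner.
* the grid-cost extrapolation S * t * p^(Dim-1) for a cohort of S subjects,
  t seconds per one-dimensional sweep of p points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "RunSet",
    "GridTop",
    "SuccessCurve",
    "CostBreakdown",
    "CostMatrix",
    "Recommendations",
    "success_probability_exact",
    "success_probability",
    "success_curve",
    "runs_for_level",
    "cost_components",
    "aggregate_costs",
    "recommend",
    "estimate_grid_cost",
]

COMPONENTS = ("fit", "sd", "time", "spread", "dist")


@dataclass
class RunSet:
    """Replicate-protocol results for one subject and method."""

    fits: np.ndarray  # (R_max,)
    points: np.ndarray  # (R_max, dim), normalized to [0, 1]^dim
    time_proxy: np.ndarray  # (R_max,) nonnegative per-run cost
    subject_id: str | None = None
    method: str | None = None
    runs: list = field(default_factory=list, repr=False)
    failures: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.fits = np.asarray(self.fits, dtype=float)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.time_proxy = np.asarray(self.time_proxy, dtype=float)
        if self.fits.ndim != 1 or self.points.shape[0] != self.fits.shape[0]:
            raise ValueError("fits length must equal the number of point rows")
        if self.time_proxy.shape != self.fits.shape:
            raise ValueError("time_proxy must have one entry per run")
        if np.any(self.points < -1e-9) or np.any(self.points > 1 + 1e-9):
            raise ValueError("points must be normalized to [0, 1]^dim")
        if np.any(self.time_proxy < 0):
            raise ValueError("time_proxy entries must be nonnegative")

    @property
    def r_max(self) -> int:
        return self.fits.shape[0]


@dataclass
class GridTop:
    """Top grid-search nodes (normalized coordinates) for one subject."""

    points: np.ndarray  # (<=5, dim)
    fits: np.ndarray
    best_fit: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.fits = np.asarray(self.fits, dtype=float)
        if self.points.shape[0] != self.fits.shape[0]:
            raise ValueError("one fit per grid point required")
        if np.any(np.diff(self.fits) > 1e-12):
            raise ValueError("grid top points must be in descending fit order")


@dataclass
class SuccessCurve:
    r_values: np.ndarray
    probabilities: np.ndarray
    standard_errors: np.ndarray
    threshold_fraction: float = 0.95
    n_resamples: int = 500


def success_probability_exact(m: int, r_max: int, r: int) -> float:
    """Closed form for draws without replacement: 1 - C(R_max-m, r)/C(R_max, r)."""
    if not (1 <= r <= r_max):
        raise ValueError(f"r must lie in [1, {r_max}], got {r}")
    if not (0 <= m <= r_max):
        raise ValueError("m must lie in [0, r_max]")
    return 1.0 - comb(r_max - m, r) / comb(r_max, r)


def _passing_count(fits: np.ndarray, grid_best: float, threshold_fraction: float) -> int:
    return int(np.sum(fits >= threshold_fraction * grid_best))


def success_probability(
    fits_per_subject: list[np.ndarray],
    grid_best_per_subject: list[float],
    r: int,
    threshold_fraction: float = 0.95,
    n_resamples: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Resampled success probability for a fixed number of runs ``r``.

    Per subject, ``r`` fits are drawn without replacement ``n_resamples``
    times; a draw succeeds when its maximum reaches
    ``threshold_fraction * grid_best``.  Returns the subject-mean of the
    resample-mean success rates and its standard error across subjects.
    """
    if len(fits_per_subject) != len(grid_best_per_subject):
        raise ValueError("need one grid best value per subject")
    rng = np.random.default_rng(seed)
    rates = []
    for fits, gbest in zip(fits_per_subject, grid_best_per_subject):
        fits = np.asarray(fits, dtype=float)
        r_max = fits.shape[0]
        if not (1 <= r <= r_max):
            raise ValueError(f"r={r} exceeds the {r_max} available runs")
        if gbest <= 0:
            raise ValueError("grid best fit must be positive")
        thr = threshold_fraction * gbest
        passing = fits >= thr
        successes = 0
        for _ in range(n_resamples):
            idx = rng.choice(r_max, size=r, replace=False)
            successes += bool(passing[idx].any())
        rates.append(successes / n_resamples)
    rates = np.asarray(rates)
    se = rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0
    return float(rates.mean()), float(se)


def success_curve(
    fits_per_subject: list[np.ndarray],
    grid_best_per_subject: list[float],
    r_values: np.ndarray | None = None,
    threshold_fraction: float = 0.95,
    n_resamples: int = 500,
    seed: int = 0,
) -> SuccessCurve:
    """Success probability as a function of the number of runs R = 1..R_max."""
    r_max = min(np.asarray(f).shape[0] for f in fits_per_subject)
    if r_values is None:
        r_values = np.arange(1, r_max + 1)
    r_values = np.asarray(r_values, dtype=int)
    probs, ses = [], []
    for i, r in enumerate(r_values):
        p, se = success_probability(
            fits_per_subject, grid_best_per_subject, int(r),
            threshold_fraction, n_resamples, seed=seed + i,
        )
        probs.append(p)
        ses.append(se)
    return SuccessCurve(
        r_values=r_values, probabilities=np.asarray(probs),
        standard_errors=np.asarray(ses), threshold_fraction=threshold_fraction,
        n_resamples=n_resamples,
    )


def runs_for_level(curve: SuccessCurve, level: float) -> tuple[int, bool]:
    """Smallest R whose probability reaches ``level``; (R_max, False) if never.

    The convention for an unreached level is to charge the full R_max runs.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if curve.r_values.size == 0:
        raise ValueError("empty success curve")
    hits = np.nonzero(curve.probabilities >= level)[0]
    if hits.size:
        return int(curve.r_values[hits[0]]), True
    return int(curve.r_values[-1]), False


@dataclass
class CostBreakdown:
    """The five unnormalized multiplicative cost components for one cell."""

    comp_fit: float  # 1 - max Fit
    comp_sd: float  # population SD of Fit
    comp_time: float  # time to reach the 80% success level
    comp_spread: float  # mean pairwise distance of the solution points
    comp_dist: float  # mean distance of solutions to the grid optima
    normalized: dict[str, float] | None = None
    psi: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "fit": self.comp_fit, "sd": self.comp_sd, "time": self.comp_time,
            "spread": self.comp_spread, "dist": self.comp_dist,
        }


def cost_components(
    runset: RunSet, gridtop: GridTop, time_for_80: float,
    distance_mode: str = "min",
) -> CostBreakdown:
    """Unnormalized cost components from one subject's replicates.

    ``distance_mode="min"`` (default) scores each solution by its distance
    to the nearest of the grid optima; ``"mean"`` averages over all
    solution-gridpoint pairs instead (the alternative reading of the
    component's definition).
    """
    r = runset.r_max
    if r < 2:
        raise ValueError("solution spread needs at least 2 runs")
    if distance_mode not in ("min", "mean"):
        raise ValueError("distance_mode must be 'min' or 'mean'")
    if time_for_80 < 0:
        raise ValueError("time must be nonnegative")
    fits = runset.fits
    comp_fit = float(1.0 - fits.max())
    comp_sd = float(np.sqrt(np.mean((fits - fits.mean()) ** 2)))  # population SD (1/R)
    diffs = runset.points[:, None, :] - runset.points[None, :, :]
    dmat = np.sqrt((diffs**2).sum(axis=2))
    iu = np.triu_indices(r, k=1)
    comp_spread = float(dmat[iu].mean())  # C(R,2) pairs, e.g. 105 for R=15
    gd = np.sqrt(
        ((runset.points[:, None, :] - gridtop.points[None, :, :]) ** 2).sum(axis=2)
    )
    comp_dist = float(gd.min(axis=1).mean() if distance_mode == "min" else gd.mean())
    return CostBreakdown(
        comp_fit=comp_fit, comp_sd=comp_sd, comp_time=float(time_for_80),
        comp_spread=comp_spread, comp_dist=comp_dist,
    )


@dataclass
class CostMatrix:
    subjects: list[str]
    methods: list[str]
    psi: np.ndarray  # (subjects, methods)
    normalized: dict[str, np.ndarray]
    maxima: dict[str, float]
    raw_time: np.ndarray  # (subjects, methods), for recommendation tie-breaks
    notes: list[str] = field(default_factory=list)


def aggregate_costs(breakdowns: dict[tuple[str, str], CostBreakdown]) -> CostMatrix:
    """Normalize components by their maxima over all subjects x methods; psi = product.

    An all-zero component is left at zero for every cell (and logged) rather
    than dividing by zero.
    """
    subjects = sorted({s for s, _ in breakdowns})
    methods = sorted({m for _, m in breakdowns})
    for s in subjects:
        for m in methods:
            if (s, m) not in breakdowns:
                raise ValueError(f"missing cost breakdown for subject {s!r}, method {m!r}")
    notes: list[str] = []
    raw = {
        c: np.array([[breakdowns[(s, m)].as_dict()[c] for m in methods] for s in subjects])
        for c in COMPONENTS
    }
    normalized: dict[str, np.ndarray] = {}
    maxima: dict[str, float] = {}
    for c in COMPONENTS:
        mx = float(raw[c].max())
        maxima[c] = mx
        if mx == 0.0:
            normalized[c] = np.zeros_like(raw[c])
            notes.append(f"component {c!r} is zero for all cells; left at zero")
        else:
            normalized[c] = raw[c] / mx
    psi = np.ones_like(raw["fit"])
    for c in COMPONENTS:
        psi = psi * normalized[c]
    for i, s in enumerate(subjects):
        for j, m in enumerate(methods):
            bd = breakdowns[(s, m)]
            bd.normalized = {c: float(normalized[c][i, j]) for c in COMPONENTS}
            bd.psi = float(psi[i, j])
    return CostMatrix(
        subjects=subjects, methods=methods, psi=psi, normalized=normalized,
        maxima=maxima, raw_time=raw["time"], notes=notes,
    )


@dataclass
class Recommendations:
    per_subject: dict[str, str]
    tally: dict[str, int]
    winner: str
    tie_notes: list[str] = field(default_factory=list)


def recommend(costs: CostMatrix) -> Recommendations:
    """Per-subject argmin of psi; ties broken by lower time, then method name."""
    per_subject: dict[str, str] = {}
    tally = {m: 0 for m in costs.methods}
    tie_notes: list[str] = []
    for i, s in enumerate(costs.subjects):
        row = costs.psi[i]
        best = row.min()
        cand = [j for j in range(len(costs.methods)) if row[j] == best]
        if len(cand) > 1:
            times = costs.raw_time[i, cand]
            cand = [j for j, t in zip(cand, times) if t == times.min()]
            if len(cand) > 1:
                cand = sorted(cand, key=lambda j: costs.methods[j])
            tie_notes.append(
                f"subject {s}: psi tie resolved to {costs.methods[cand[0]]}"
            )
        choice = costs.methods[cand[0]]
        per_subject[s] = choice
        tally[choice] += 1
    winner = max(costs.methods, key=lambda m: (tally[m], m))
    return Recommendations(
        per_subject=per_subject, tally=tally, winner=winner, tie_notes=tie_notes
    )


def estimate_grid_cost(
    t_per_sweep: float, p: int, dim: int, s_subjects: int = 1
) -> float:
    """Grid-search cost extrapolation S * t * p^(Dim-1), in hours.

    ``t_per_sweep`` is the wall time in seconds for a one-dimensional sweep
    of ``p`` parameter points; a Dim-dimensional sweep repeats it p^(Dim-1)
    times, and a cohort of S subjects multiplies the total by S.
    """
    if t_per_sweep <= 0 or p <= 0 or dim < 1 or s_subjects <= 0:
        raise ValueError("all inputs must be positive (dim >= 1)")
    return s_subjects * t_per_sweep * p ** (dim - 1) / 3600.0
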