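"""Delay-coupled stochastic phase-oscillator model on a structural connectome.

Each brain region i is a phase oscillator

    dtheta_i/dt = 2*pi*f_i + sum_j k_ij * sin(theta_j(t - tau_ij) - theta_i(t))
                  + sigma * eta_i(t),

with pairwise coupling strengths and delays derived from the structural
connectivity (streamline counts, SC) and path lengths (PL):

    k_ij   = SC_ij / <SC> * C / N,
    tau_ij = PL_ij / <PL> * tau,

where <.> is the mean over off-diagonal matrix entries (zeros included) and
C, tau are the global coupling and delay parameters.  eta_i(t) is independent
uniform noise on [-1, 1].  The system is integrated with the stochastic Heun
(predictor-corrector) scheme; delays are handled through a ring buffer of
phase history discretized to integer multiples of the step dt.  Simulated
BOLD is sin(theta_i) downsampled to the fMRI repetition time, and simulated
FC is the Pearson correlation matrix of those signals.

Discrete-time conventions (the continuous-time formulation leaves them open):

* Noise increment per oscillator per step is ``sigma*sqrt(dt)*u`` with
  ``u ~ U[-1, 1]``, drawn once per step and reused in predictor and
  corrector (Euler-Maruyama-consistent scaling, so the uniform variance 1/3
  gives a phase-variance growth rate of sigma^2*dt/3 per step).
* Delays are rounded to the nearest integer step, ``d_ij = round(tau_ij/dt)``
  (error at most dt/2); no interpolation.
* History for t <= 0 is held constant at the initial phases, which are drawn
  uniformly on [0, 2*pi).  The discarded transient makes this choice
  immaterial for stationary FC.
* Phases are stored unwrapped (no modulo); only sines of phases or of phase
  differences enter the output, which are wrap-invariant.
* Downsampling retains integration samples at times t = m*TR; the first
  retained sample is the smallest m*TR >= transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fc import FCMatrix, correlation_fc

__all__ = [
    "Connectome",
    "ModelParams",
    "CouplingSpec",
    "PhaseTrajectory",
    "build_coupling",
    "heun_integrate",
    "phases_to_bold",
    "bold_to_fc",
    "simulate_fc",
]


@dataclass
class Connectome:
    """Structural connectome: streamline counts (sc) and path lengths (pl)."""

    sc: np.ndarray
    pl: np.ndarray

    def __post_init__(self):
        self.sc = np.asarray(self.sc, dtype=float)
        self.pl = np.asarray(self.pl, dtype=float)
        for name, m in (("sc", self.sc), ("pl", self.pl)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0.0):
                raise ValueError(f"{name} must have a zero diagonal")
            if np.any(m < 0.0):
                raise ValueError(f"{name} must be nonnegative")
        if self.sc.shape != self.pl.shape:
            raise ValueError("sc and pl must have the same shape")
        if self.n_regions < 2:
            raise ValueError("a connectome needs at least 2 regions")
        off = ~np.eye(self.n_regions, dtype=bool)
        if np.any((self.sc[off] > 0) & (self.pl[off] <= 0)):
            raise ValueError("pl must be strictly positive wherever sc > 0")

    @property
    def n_regions(self) -> int:
        return self.sc.shape[0]


@dataclass
class ModelParams:
    """Global model parameters and integration settings.

    coupling_c and noise_sigma are dimensionless, delay_tau is in seconds,
    frequencies are the regional natural frequencies f_i in Hz.
    """

    coupling_c: float
    delay_tau: float
    noise_sigma: float
    frequencies: np.ndarray
    dt: float = 0.06
    tr: float = 0.72
    duration: float = 4000.0
    transient: float = 500.0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coupling_c < 0 or self.delay_tau < 0 or self.noise_sigma < 0:
            raise ValueError("coupling_c, delay_tau and noise_sigma must be >= 0")
        if np.any(self.frequencies <= 0):
            raise ValueError("all natural frequencies must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ratio = self.tr / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"tr={self.tr} must be an integer multiple of dt={self.dt}")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the transient")

    @property
    def n_regions(self) -> int:
        return self.frequencies.shape[0]


@dataclass
class CouplingSpec:
    """Pairwise coupling strengths k_ij and integer step delays d_ij."""

    k: np.ndarray
    delay_steps: np.ndarray

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        self.delay_steps = np.asarray(self.delay_steps, dtype=np.int64)
        if self.k.shape != self.delay_steps.shape or self.k.ndim != 2:
            raise ValueError("k and delay_steps must be square matrices of equal shape")
        if np.any(np.diag(self.k) != 0.0):
            raise ValueError("k must have a zero diagonal")
        if np.any(self.delay_steps < 0):
            raise ValueError("delay steps must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.k.shape[0]

    @property
    def max_delay_steps(self) -> int:
        return int(self.delay_steps.max()) if self.delay_steps.size else 0


@dataclass
class PhaseTrajectory:
    """Unwrapped phases at the downsampled (TR) rate; t0 = time of first sample."""

    theta: np.ndarray
    tr: float
    t0: float = field(default=0.0)

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.n_samples)


def _offdiag_mean(m: np.ndarray) -> float:
    n = m.shape[0]
    return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def build_coupling(
    connectome: Connectome, coupling_c: float, delay_tau: float, dt: float
) -> CouplingSpec:
    """Construct k_ij = SC_ij/<SC> * C/N and d_ij = round(PL_ij/<PL> * tau / dt)."""
    if coupling_c < 0 or delay_tau < 0:
        raise ValueError("coupling_c and delay_tau must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = connectome.n_regions
    sc_mean = _offdiag_mean(connectome.sc)
    if sc_mean == 0.0:
        raise ValueError("mean structural connectivity is zero (empty connectome)")
    k = connectome.sc / sc_mean * (coupling_c / n)
    if delay_tau > 0:
        pl_mean = _offdiag_mean(connectome.pl)
        if pl_mean == 0.0:
            raise ValueError("mean path length is zero but delay_tau > 0")
        tau_ij = connectome.pl / pl_mean * delay_tau
        d = np.rint(tau_ij / dt).astype(np.int64)
    else:
        d = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(d, 0)
    return CouplingSpec(k=k, delay_steps=d)


@njit(cache=False)
def _heun_loop(theta0, omega, k, dsteps, sig_sqdt, dt, n_steps, noise, keep, out):  # pragma: no cover - jit
    n = theta0.shape[0]
    dmax = 0
    for i in range(n):
        for j in range(n):
            if dsteps[i, j] > dmax:
                dmax = dsteps[i, j]
    nh = dmax + 1
    sin_h = np.empty((nh, n))
    cos_h = np.empty((nh, n))
    for h in range(nh):
        for j in range(n):
            sin_h[h, j] = np.sin(theta0[j])
            cos_h[h, j] = np.cos(theta0[j])
    theta = theta0.copy()
    a1 = np.empty(n)
    pred = np.empty(n)
    sp = np.empty(n)
    cp = np.empty(n)
    n_keep = keep.shape[0]
    ki = 0
    if ki < n_keep and keep[ki] == 0:
        for j in range(n):
            out[ki, j] = theta[j]
        ki += 1
    for s in range(n_steps):
        # predictor: drift at time t = s*dt
        for i in range(n):
            acc_s = 0.0
            acc_c = 0.0
            for j in range(n):
                kij = k[i, j]
                if kij != 0.0:
                    hs = (s - dsteps[i, j]) % nh
                    acc_s += kij * sin_h[hs, j]
                    acc_c += kij * cos_h[hs, j]
            a1[i] = omega[i] + np.cos(theta[i]) * acc_s - np.sin(theta[i]) * acc_c
        for i in range(n):
            pred[i] = theta[i] + dt * a1[i] + sig_sqdt * noise[s, i]
            sp[i] = np.sin(pred[i])
            cp[i] = np.cos(pred[i])
        # corrector: drift at time t+dt using predicted state and shifted history
        for i in range(n):
            acc_s = 0.0
            acc_c = 0.0
            for j in range(n):
                kij = k[i, j]
                if kij != 0.0:
                    dij = dsteps[i, j]
                    if dij == 0:
                        acc_s += kij * sp[j]
                        acc_c += kij * cp[j]
                    else:
                        hs = (s + 1 - dij) % nh
                        acc_s += kij * sin_h[hs, j]
                        acc_c += kij * cos_h[hs, j]
            a2 = omega[i] + cp[i] * acc_s - sp[i] * acc_c
            theta[i] = theta[i] + 0.5 * dt * (a1[i] + a2) + sig_sqdt * noise[s, i]
        slot = (s + 1) % nh
        for j in range(n):
            if not np.isfinite(theta[j]):
                return s + 1
            sin_h[slot, j] = np.sin(theta[j])
            cos_h[slot, j] = np.cos(theta[j])
        if ki < n_keep and keep[ki] == s + 1:
            for j in range(n):
                out[ki, j] = theta[j]
            ki += 1
    return -1


def _keep_indices(params: ModelParams) -> np.ndarray:
    stride = int(round(params.tr / params.dt))
    m0 = int(np.ceil(params.transient / params.tr - 1e-9))
    m_max = int(np.floor(params.duration / params.tr + 1e-9))
    return stride * np.arange(m0, m_max + 1, dtype=np.int64)


def heun_integrate(spec: CouplingSpec, params: ModelParams, seed: int) -> PhaseTrajectory:
    """Integrate the delay SDE with the stochastic Heun scheme.

    Bitwise reproducible for a given seed: initial phases are drawn first
    (uniform on [0, 2*pi)), then the full (n_steps, N) noise array
    (uniform on [-1, 1], time-major rows, region columns) when sigma > 0.
    """
    if spec.n_regions != params.n_regions:
        raise ValueError(
            f"coupling is for {spec.n_regions} regions, params for {params.n_regions}"
        )
    n_steps = int(round(params.duration / params.dt))
    max_delay_s = spec.max_delay_steps * params.dt
    if max_delay_s > 0.5 * params.duration:
        raise ValueError(
            f"maximal delay {max_delay_s:.1f} s exceeds half the duration {params.duration:.1f} s"
        )
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, spec.n_regions)
    if params.noise_sigma > 0:
        noise = rng.uniform(-1.0, 1.0, (n_steps, spec.n_regions))
    else:
        noise = np.zeros((n_steps, spec.n_regions))
    keep = _keep_indices(params)
    out = np.empty((keep.shape[0], spec.n_regions))
    omega = 2.0 * np.pi * params.frequencies
    bad = _heun_loop(
        theta0,
        omega,
        spec.k,
        spec.delay_steps,
        params.noise_sigma * np.sqrt(params.dt),
        params.dt,
        n_steps,
        noise,
        keep,
        out,
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite phase encountered at integration step {bad}")
    m0 = int(np.ceil(params.transient / params.tr - 1e-9))
    return PhaseTrajectory(theta=out, tr=params.tr, t0=m0 * params.tr)


def phases_to_bold(traj: PhaseTrajectory) -> np.ndarray:
    """Simulated BOLD: elementwise sine of the retained phases (values in [-1, 1])."""
    return np.sin(traj.theta)


def bold_to_fc(bold: np.ndarray, region_ids: list[str] | None = None) -> FCMatrix:
    """Simulated FC: Pearson correlations across all pairs of BOLD time series."""
    return correlation_fc(bold, region_ids=region_ids)


def simulate_fc(connectome: Connectome, params: ModelParams, seed: int) -> FCMatrix:
    """Convenience pipeline: coupling -> Heun integration -> BOLD -> simFC."""
    spec = build_coupling(connectome, params.coupling_c, params.delay_tau, params.dt)
    traj = heun_integrate(spec, params, seed)
    return bold_to_fc(phases_to_bold(traj))
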