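"""Synthetic cohort generation and empirical-feature extraction.

Real studies of this kind build the model on diffusion-MRI connectomes and
validate it against resting-state fMRI.  Neither is redistributable, so this
module generates surrogates with the statistical structure the fitting
pipeline assumes:

* connectomes with symmetric, nonnegative, zero-diagonal streamline counts
  whose weights are heavy-tailed (log-normal) and decay with inter-region
  distance, plus strictly positive path lengths from random 3-D region
  coordinates;
* regional BOLD sessions whose spectral peaks fall at assigned natural
  frequencies inside the 0.01-0.1 Hz resting-state band, with optional
  FC-structured correlated noise, organized as multiple sessions of fixed
  length at a fixed repetition time (TR);
* ground-truth subjects: the phase-oscillator model run at known parameters
  (C*, tau*, sigma*), whose simulated FC plays the role of that subject's
  empirical FC in parameter-recovery experiments.

It also re-implements the two empirical-feature extractors the fitting
pipeline needs: natural-frequency estimation from in-band spectral peaks and
empirical-FC computation from detrended, z-scored, concatenated sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.distance import pdist, squareform

from ._seeds import child_seed
from .fc import FCMatrix, correlation_fc
from .model import Connectome, ModelParams, simulate_fc

__all__ = [
    "CohortConfig",
    "BoldSessionSet",
    "generate_connectome",
    "generate_bold_sessions",
    "make_ground_truth_subject",
    "estimate_natural_frequencies",
    "compute_empirical_fc",
    "subject_seed_for",
]


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the multi-session resting-state structure the pipeline
    was designed for: four sessions of 1200 volumes at TR = 0.72 s.
    """

    n_subjects: int
    n_regions: int
    density: float = 0.35
    weight_scale: float = 1.0
    length_range: tuple[float, float] = (10.0, 160.0)
    tr: float = 0.72
    volumes_per_session: int = 1200
    n_sessions: int = 4
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_regions < 1:
            raise ValueError("n_subjects and n_regions must be >= 1")
        if not (0.0 < self.density <= 1.0):
            raise ValueError(f"density must lie in (0, 1], got {self.density}")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")
        lo, hi = self.length_range
        if not (0 < lo < hi):
            raise ValueError(f"length_range must satisfy 0 < min < max, got {self.length_range}")
        if self.tr <= 0 or self.volumes_per_session < 1 or self.n_sessions < 1:
            raise ValueError("tr must be positive and session counts >= 1")


@dataclass
class BoldSessionSet:
    """A subject's BOLD recordings: list of T x N (time x region) sessions."""

    sessions: list[np.ndarray]
    tr: float
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sessions = [np.asarray(s, dtype=float) for s in self.sessions]
        if not self.sessions:
            raise ValueError("need at least one session")
        n = self.sessions[0].shape[1]
        for s in self.sessions:
            if s.ndim != 2 or s.shape[1] != n:
                raise ValueError("all sessions must be T x N with the same N")
            if not np.all(np.isfinite(s)):
                raise ValueError("sessions must not contain missing/non-finite values")
        if not self.region_ids:
            self.region_ids = [f"region{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match region count")

    @property
    def n_regions(self) -> int:
        return self.sessions[0].shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


def generate_connectome(config: CohortConfig, subject_seed: int) -> Connectome:
    """Random structural connectome with distance-dependent, heavy-tailed weights.

    Path lengths come from uniformly random 3-D region coordinates whose
    Euclidean distances are rescaled affinely into ``length_range`` (this
    guarantees symmetry and a triangle-inequality-like geometry).  Candidate
    weights are log-normal magnitudes times an exponential distance decay
    exp(-PL/lambda) with lambda = half the length-range span; the top
    round(density * N*(N-1)/2) pairs by weight are kept, the rest zeroed.
    """
    if config.n_regions < 2:
        raise ValueError("generate_connectome needs n_regions >= 2")
    n = config.n_regions
    rng = np.random.default_rng(subject_seed)
    coords = rng.uniform(0.0, 1.0, (n, 3))
    dist = squareform(pdist(coords))
    lo, hi = config.length_range
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    if d.max() == d.min():  # degenerate geometry; spread uniformly
        pl_u = np.full_like(d, 0.5 * (lo + hi))
    else:
        pl_u = lo + (d - d.min()) / (d.max() - d.min()) * (hi - lo)
    pl = np.zeros((n, n))
    pl[iu] = pl_u
    pl = pl + pl.T

    lam = 0.5 * (hi - lo)
    weights = rng.lognormal(mean=0.0, sigma=config.weight_scale, size=pl_u.shape)
    weights *= np.exp(-pl_u / lam)
    n_pairs = n * (n - 1) // 2
    n_keep = int(np.floor(config.density * n_pairs + 0.5))
    n_keep = max(1, min(n_pairs, n_keep))
    order = np.argsort(weights)[::-1]
    sc_u = np.zeros_like(weights)
    sc_u[order[:n_keep]] = weights[order[:n_keep]]
    sc = np.zeros((n, n))
    sc[iu] = sc_u
    sc = sc + sc.T
    return Connectome(sc=sc, pl=pl)


def generate_bold_sessions(
    config: CohortConfig,
    frequencies: np.ndarray,
    coupling_fc: FCMatrix | None,
    subject_seed: int,
    noise_scale: float = 0.5,
) -> BoldSessionSet:
    """Synthetic BOLD: per-region sinusoids at assigned frequencies plus noise.

    Region i's signal is sin(2*pi*f_i*t + phi) with an independent random
    phase per (session, region), plus Gaussian noise of standard deviation
    ``noise_scale``.  When ``coupling_fc`` is given, the noise is drawn from
    a multivariate normal with that correlation matrix, inducing the
    requested inter-regional correlation structure; identity (or None) gives
    mutually independent regions.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    nyq = 0.5 / config.tr
    if np.any(frequencies <= 0) or np.any(frequencies >= nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq:.4f}) Hz (below Nyquist)")
    n = frequencies.shape[0]
    if coupling_fc is not None and coupling_fc.n_regions != n:
        raise ValueError("coupling_fc size does not match number of frequencies")
    rng = np.random.default_rng(subject_seed)
    t = np.arange(config.volumes_per_session) * config.tr
    if coupling_fc is not None and noise_scale > 0:
        cov = coupling_fc.values + 1e-9 * np.eye(n)  # jitter for Cholesky
        chol = np.linalg.cholesky(cov)
    else:
        chol = None
    sessions = []
    for _ in range(config.n_sessions):
        phases = rng.uniform(0.0, 2.0 * np.pi, n)
        x = np.sin(2.0 * np.pi * t[:, None] * frequencies[None, :] + phases[None, :])
        if noise_scale > 0:
            eps = rng.standard_normal((config.volumes_per_session, n))
            if chol is not None:
                eps = eps @ chol.T
            x = x + noise_scale * eps
        sessions.append(x)
    return BoldSessionSet(sessions=sessions, tr=config.tr)


def make_ground_truth_subject(
    connectome: Connectome, params: ModelParams, subject_seed: int
) -> FCMatrix:
    """Simulated FC at known parameters, used as a subject's 'empirical' FC.

    By construction, re-evaluating the goal function at the same parameters
    with the same (fixed) noise seed reproduces this matrix and yields a
    goal value of 1.
    """
    return simulate_fc(connectome, params, subject_seed)


def _detrend_zscore_concat(bold: BoldSessionSet) -> np.ndarray:
    """Per-session linear detrend, then z-score, then concatenate over time."""
    parts = []
    for s_idx, sess in enumerate(bold.sessions):
        det = sp_signal.detrend(sess, axis=0, type="linear")
        sd = det.std(axis=0)
        # a constant (or purely linear) signal leaves only rounding residue
        tol = 1e-12 * max(1.0, float(np.abs(sess).max()))
        bad = np.nonzero(sd <= tol)[0]
        if bad.size:
            raise ValueError(
                f"region {bold.region_ids[bad[0]]} has constant signal in session {s_idx}"
            )
        parts.append((det - det.mean(axis=0)) / sd)
    return np.concatenate(parts, axis=0)


def estimate_natural_frequencies(
    bold: BoldSessionSet, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Regional natural frequencies from the maximal in-band spectral peak.

    Uses the raw periodogram of the linearly detrended, z-scored,
    concatenated signal; the returned frequency for each region is the
    frequency-bin argmax of the power spectrum restricted to ``band``.
    Resolution is one spectral bin, 1/(T_total*TR).
    """
    low, high = band
    nyq = bold.nyquist
    if not (0 < low < high <= nyq + 1e-12):
        raise ValueError(f"band must satisfy 0 < low < high <= Nyquist ({nyq:.4f} Hz)")
    x = _detrend_zscore_concat(bold)
    freqs, power = sp_signal.periodogram(x, fs=1.0 / bold.tr, axis=0, detrend=False)
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency bins after discretization")
    band_freqs = freqs[mask]
    return band_freqs[np.argmax(power[mask, :], axis=0)]


def compute_empirical_fc(bold: BoldSessionSet) -> FCMatrix:
    """Empirical FC: Pearson correlation of detrended, z-scored, concatenated sessions."""
    x = _detrend_zscore_concat(bold)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points in total per region")
    return correlation_fc(x, region_ids=list(bold.region_ids))


def subject_seed_for(config: CohortConfig, subject: int, purpose: int) -> int:
    """Documented child-seed scheme: (master_seed, subject, purpose) -> seed."""
    return child_seed(config.master_seed, subject, purpose)
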