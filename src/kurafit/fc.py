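"""Functional-connectivity matrices.

An FC matrix is the N x N Pearson-correlation matrix of N regional BOLD time
series: symmetric, unit diagonal, entries in [-1, 1].  Both empirical FC
(from measured/synthetic BOLD) and simulated FC (from model output) use this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FCMatrix", "correlation_fc"]


@dataclass
class FCMatrix:
    """N x N functional-connectivity (Pearson correlation) matrix."""

    values: np.ndarray
    region_ids: list[str] | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix must have unit diagonal")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-10:
            raise ValueError("FC entries must lie in [-1, 1]")
        if self.region_ids is not None and len(self.region_ids) != v.shape[0]:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries as a flat vector (diagonal excluded)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


def correlation_fc(bold: np.ndarray, region_ids: list[str] | None = None) -> FCMatrix:
    """Pearson-correlation FC of a T x N time-by-region matrix.

    Raises on constant (zero-variance) columns, naming the offending region.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2:
        raise ValueError("BOLD array must be 2-D (time x region)")
    t, n = bold.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = bold.std(axis=0)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        name = region_ids[bad[0]] if region_ids is not None else str(bad[0])
        raise ValueError(f"region {name} has constant signal (zero variance)")
    r = np.corrcoef(bold, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, region_ids=region_ids)
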