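"""Deterministic child-seed derivation.

Every stochastic operation in the package receives an explicit integer seed.
Child seeds are derived from a master seed plus an integer key path through
``numpy.random.SeedSequence`` so that (master_seed, key) -> child seed is a
pure function, independent of call order.  All seeds stay below 2**31.
"""

from __future__ import annotations

import numpy as np

_SEED_MOD = 2**31


def child_seed(master_seed: int, *key: int) -> int:
    """Derive a deterministic child seed from a master seed and a key path."""
    ss = np.random.SeedSequence([int(master_seed) % _SEED_MOD, *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % _SEED_MOD)


class SeedFactory:
    """Counter-free seed spawner: one child per (purpose...) integer key."""

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed) % _SEED_MOD

    def child(self, *key: int) -> int:
        return child_seed(self.master_seed, *key)


class SeedPolicy:
    """Seed source for goal-function evaluations.

    mode="fresh"  (default): every evaluation draws a new child seed from an
        internal counter, so repeated evaluations at the same parameter point
        see different noise realizations — the stochastic goal of the study.
    mode="fixed": every evaluation reuses ``master_seed`` itself, making the
        goal a deterministic function of the parameter point (used for exact
        self-match and reproducibility tests).
    """

    MODES = ("fresh", "fixed")

    def __init__(self, master_seed: int, mode: str = "fresh"):
        if mode not in self.MODES:
            raise ValueError(f"unknown seed-policy mode {mode!r}; expected one of {self.MODES}")
        self.master_seed = int(master_seed) % _SEED_MOD
        self.mode = mode
        self._counter = 0
        self.issued: list[int] = []

    def next_seed(self) -> int:
        if self.mode == "fixed":
            seed = self.master_seed
        else:
            seed = child_seed(self.master_seed, self._counter)
            self._counter += 1
        self.issued.append(seed)
        return seed
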