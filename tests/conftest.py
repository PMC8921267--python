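import numpy as np
import pytest

from kurafit.cohort import CohortConfig, generate_connectome
from kurafit.model import Connectome


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    """A dense 6-region connectome used by fast simulator tests."""
    cfg = CohortConfig(n_subjects=1, n_regions=6, density=1.0, master_seed=42)
    return generate_connectome(cfg, subject_seed=42)


@pytest.fixture(scope="session")
def study_connectome() -> Connectome:
    """A 20-region connectome at the scaled-study conditions."""
    cfg = CohortConfig(n_subjects=1, n_regions=20, density=0.35, master_seed=7)
    return generate_connectome(cfg, subject_seed=7)


def ring_connectome(n: int) -> Connectome:
    """All-to-all unit connectome with unit path lengths (hand-checkable)."""
    sc = np.ones((n, n)) - np.eye(n)
    pl = np.ones((n, n)) - np.eye(n)
    return Connectome(sc=sc, pl=pl)
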