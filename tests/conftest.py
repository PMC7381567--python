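import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from tropholink import CommunitySimConfig, DissimilarityMatrix, simulate_community


@pytest.fixture(scope="session")
def small_bundle():
    """A 15-species two-site community with trait-coupled diets."""
    return simulate_community(CommunitySimConfig(n_species=15, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_distance_matrix(n, rng, labels=None, kind="generic"):
    """Random Euclidean-ish distance matrix helper (no ties in practice)."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    labels = labels or [f"s{i}" for i in range(n)]
    return DissimilarityMatrix(d, labels, kind=kind)
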