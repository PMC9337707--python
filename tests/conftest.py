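import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def random_psd_corr(rng):
    """Factory for random positive-definite correlation matrices."""

    def make(J, strength=1.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        A = r.standard_normal((J, J + 5)) * strength
        S = A @ A.T + 0.1 * np.eye(J)
        dd = np.sqrt(np.diag(S))
        return S / np.outer(dd, dd)

    return make


@pytest.fixture
def small_dataset():
    """One small simulated study with strong-LD blocks and 2 causal SNPs."""
    from finemapss.simulate import SimScenario, simulate_dataset

    return simulate_dataset(
        SimScenario(n_study=600, n_panel=400, J=50, n_causal=2, pve=0.3, seed=7)
    )
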