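import itertools

import numpy as np
import pytest

from degenlib.dataset import TirDataset


@pytest.fixture
def l1_dataset():
    """The minimal single-position dataset used throughout the docs."""
    return TirDataset(entries={"A": 1.0, "C": 2.0, "G": 3.0, "T": 4.0})


def make_random_dataset(length: int, seed: int, label: str = "") -> TirDataset:
    """Complete 4^L table with lognormal TIRs (plain RNG, independent of
    the package's synthetic generator)."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(p) for p in itertools.product("ACGT", repeat=length)]
    tirs = rng.lognormal(mean=2.0, sigma=1.0, size=len(seqs))
    return TirDataset(entries=dict(zip(seqs, tirs.tolist())), label=label)


@pytest.fixture
def random_dataset():
    return make_random_dataset
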