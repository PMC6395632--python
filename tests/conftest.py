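import numpy as np
import pytest

from snopred import LabeledDataset, PeptideWindow, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions: 500+500 windows, seed 1."""
    return simulate_dataset(500, 500, t=10, seed=1)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dataset(60, 60, t=10, seed=7)


@pytest.fixture
def toy_dataset():
    """Four hand-written 5-mer windows (t=2), two per class."""
    return LabeledDataset(
        [
            PeptideWindow("AKCMA", label=1),
            PeptideWindow("GKCMG", label=1),
            PeptideWindow("AGCAA", label=0),
            PeptideWindow("GACAG", label=0),
        ]
    )
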