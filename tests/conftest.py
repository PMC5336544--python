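import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dermapk import DiffusionParams


@pytest.fixture
def params() -> DiffusionParams:
    """A mid-transient parameter set: DL2 * 6 h = 0.3, typical SC thickness."""
    return DiffusionParams(K=3.0, DL2=0.05, Cveh=100.0, L=15.0)


@pytest.fixture
def uniform_intervals():
    """Twelve equal relative-depth slabs covering the whole SC."""
    edges = np.linspace(0.0, 1.0, 13)
    return list(zip(edges[:-1], edges[1:]))
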