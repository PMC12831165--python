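import numpy as np
import pytest

from quantalci.synthetic_data import gen_toy_structure
from quantalci.trajectory_features import Trajectory


@pytest.fixture(scope="session")
def toy_pdb_text() -> str:
    return gen_toy_structure(inter_chain_gap=4.4, terminal_separation=19.9)


@pytest.fixture
def triangle() -> Trajectory:
    """Symmetric triangular pulse: rises 0->10 over t=0..5, falls back by t=10."""
    t = np.arange(11.0)
    v = 10.0 - 2.0 * np.abs(t - 5.0)
    return Trajectory(times=t, values=v)
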