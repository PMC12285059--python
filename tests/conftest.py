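import numpy as np
import pytest

from stealthmx import ExperimentDesign


def make_random_design(rng: np.random.Generator, s_max: int = 8) -> ExperimentDesign:
    """Random valid design: s in [1, s_max], Dirichlet fractions, a in [0,1]."""
    s = int(rng.integers(1, s_max + 1))
    r = rng.dirichlet(np.ones(s))
    a = rng.uniform(0.0, 1.0, size=s)
    lam = float(rng.uniform(0.05, 2.0))
    return ExperimentDesign(r=r, a=a, lam=lam)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
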