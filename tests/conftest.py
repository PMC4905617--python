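import warnings

import numpy as np
import pytest

from codivar import ModelSpec, MultiBlock, scenario1, scenario2
from codivar.exceptions import ConvergenceWarning


@pytest.fixture(autouse=True)
def _silence_convergence_warnings():
    # Scenario-2 JIVE legitimately stalls in a tiny limit cycle and warns;
    # tests that care about warnings catch them explicitly.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160606)


@pytest.fixture(scope="session")
def s1():
    """Scenario-1 data + truth (abundant common variation), fixed seed."""
    return scenario1(seed=11)


@pytest.fixture(scope="session")
def s2():
    """Scenario-2 data + truth (weak common variation), fixed seed."""
    return scenario2(seed=11)


@pytest.fixture(scope="session")
def spec111():
    return ModelSpec(n_common=1, n_distinct=(1, 1))


@pytest.fixture(scope="session")
def spec122():
    return ModelSpec(n_common=1, n_distinct=(2, 2))


@pytest.fixture(scope="session")
def noise_blocks():
    """Two pure-noise blocks sharing the object mode, preprocessed."""
    g = np.random.default_rng(7)
    return MultiBlock.from_arrays(
        g.standard_normal((70, 100)), g.standard_normal((70, 50))
    ).preprocessed()


def abs_corr(u, v):
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    return abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
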