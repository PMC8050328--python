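import numpy as np
import pytest

import reecsim as rs


@pytest.fixture(scope="session")
def oxygen():
    return rs.OXYGEN


@pytest.fixture(scope="session")
def consumers():
    return rs.DEFAULT_CONSUMERS


@pytest.fixture(scope="session")
def geom():
    return rs.ChamberGeometry()


@pytest.fixture(scope="session")
def steady_oxygen(oxygen, consumers, geom):
    """Converged steady oxygen profile under the default chamber conditions."""
    profile, converged = rs.solve_steady_state(oxygen, consumers, geom)
    assert converged
    return profile


@pytest.fixture(scope="session")
def steady_oxygen_quarter(oxygen, consumers, geom):
    """Steady profile with 4-fold lower per-cell consumption."""
    sp = oxygen.with_amax(oxygen.A_max / 4)
    profile, converged = rs.solve_steady_state(sp, consumers, geom)
    assert converged
    return profile


def make_profile(mfi, bin_width=50.0, sem=None, n=None):
    """Convenience: a RadialProfile from a plain value list."""
    mfi = np.asarray(mfi, dtype=float)
    edges = bin_width * np.arange(mfi.size + 1)
    if sem is None:
        sem = np.zeros_like(mfi)
    if n is None:
        n = np.ones(mfi.size, dtype=int)
    return rs.RadialProfile(edges, mfi, np.asarray(sem, float), np.asarray(n))
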