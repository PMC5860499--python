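import numpy as np
import pandas as pd
import pytest

import longtmle as lt


@pytest.fixture(scope="session")
def toy1():
    return lt.discrete_toy_dgp(1)


@pytest.fixture(scope="session")
def toy2():
    return lt.discrete_toy_dgp(2)


@pytest.fixture(scope="session")
def toy3():
    return lt.discrete_toy_dgp(3)


@pytest.fixture(scope="session")
def toy2_panel(toy2):
    return toy2.sample(2000, seed=20)


@pytest.fixture(scope="session")
def toy3_panel(toy3):
    return toy3.sample(2000, seed=30)


@pytest.fixture(scope="session")
def chip_panel():
    """Default synthetic study cohort at the applied study's sample size."""
    return lt.simulate_chip_like(lt.DGPSpec(), n=706, seed=1)


@pytest.fixture(scope="session")
def never_feed():
    return lt.static_regime([0] * 7, "never_feed")


@pytest.fixture(scope="session")
def feed_from_day3():
    return lt.static_regime([0, 0, 1, 1, 1, 1, 1], "feed_from_day_3")


def tiny_panel(Y, M, A=None, l0=None):
    """Hand-built panel with a single binary baseline covariate.

    ``Y`` is (n, T+1); ``M`` is (n, T); ``A`` defaults to all zeros; the
    time-varying covariate is constant at its baseline value.
    """
    Y = np.asarray(Y)
    n, T_plus_1 = Y.shape
    T = T_plus_1 - 1
    A = np.zeros((n, T_plus_1)) if A is None else np.asarray(A)
    l0 = np.zeros(n) if l0 is None else np.asarray(l0)
    tv = {"l": np.repeat(l0[:, None], T, axis=1)} if T >= 1 else None
    return lt.PanelData.from_arrays(
        pd.DataFrame({"l": l0}), A, Y, np.asarray(M) if T >= 1 else None, tv
    )
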