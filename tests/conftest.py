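"""Shared fixtures: exact radial distributions are expensive (seconds to
a minute per chain length), so they are computed once per session."""

import numpy as np
import pytest

from wlcbuckle.greens import radial_green


@pytest.fixture(scope="session")
def rg_by_N():
    cache = {}

    def get(N: float):
        if N not in cache:
            cache[N] = radial_green(N)
        return cache[N]

    return get


@pytest.fixture(scope="session")
def rg025(rg_by_N):
    return rg_by_N(0.25)


@pytest.fixture(scope="session")
def rg1(rg_by_N):
    return rg_by_N(1.0)


@pytest.fixture(scope="session")
def rg2(rg_by_N):
    return rg_by_N(2.0)
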