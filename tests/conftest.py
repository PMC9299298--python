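import math

import numpy as np
import pytest

from cadclust import KineticParams, PeriodicDomain


@pytest.fixture
def dom() -> PeriodicDomain:
    return PeriodicDomain(1000.0, 1000.0)


@pytest.fixture
def params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def inert_params() -> KineticParams:
    """No reactions, no actin: pure diffusion."""
    return KineticParams(
        kass_trans=0.0, kdis_trans=0.0, kass_cis=0.0, kdis_cis=0.0,
        kass_cad_actin=0.0, kdis_cad_actin=0.0, actin_conc=0.0,
        binding_fraction=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def union_find_partition(n: int, edges) -> list:
    """Independent union-find oracle for connected components."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted([sorted(g) for g in groups.values()])
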