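"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything with plain loops and
indicator functions — no code shared with the package's vectorised paths —
so agreement is a genuine cross-check.
"""

import itertools
import math

import numpy as np
import pytest

from cratherm.model import ExperimentalState, ModelSpec, ParameterSet


def brute_force_energy(params: ParameterSet, occupancy) -> float:
    """Term-by-term energy sum over all units and pairs."""
    n = params.n_sites
    q = list(params.q_site) + [params.q_promoter]
    total = 0.0
    for i in range(n + 1):
        total += occupancy[i] * q[i]
        for j in range(i + 1, n + 1):
            if j == n:
                w = params.omega_site_pol[i]
            else:
                w = params.omega_site_site[i, j]
            total += occupancy[i] * occupancy[j] * w
    return total


def brute_force_p_rnapii(params: ParameterSet, exper: ExperimentalState, spec: ModelSpec) -> float:
    """Partition sum by explicit enumeration of all 2^(n+1) occupancies."""
    n = spec.n_sites
    active = exper.active_sites(n)
    num = den = 0.0
    for occ in itertools.product((0, 1), repeat=n + 1):
        admissible = all(occ[i] == 0 for i in range(n) if i not in active)
        if not admissible:
            continue
        w = math.exp(-brute_force_energy(params, occ) / spec.rt)
        den += w
        if occ[n] == 1:
            num += w
    return num / den


def random_params(rng: np.random.Generator, n_sites: int, lo=-5.0, hi=5.0) -> ParameterSet:
    spec = ModelSpec(n_sites)
    return ParameterSet.from_vector(rng.uniform(lo, hi, size=spec.n_parameters), n_sites)


def all_experimental_states(n_sites: int, mode: str = "activation"):
    for size in range(n_sites + 1):
        for combo in itertools.combinations(range(n_sites), size):
            yield ExperimentalState(frozenset(combo), mode)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spec3():
    return ModelSpec(3)
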