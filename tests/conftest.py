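"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's structured shortcuts:
``brute_lambda`` builds the edge correlation matrix with a literal
four-index loop over edge pairs, and dense numpy factorisations provide
reference inverses, determinants and likelihoods.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fcdiff import EdgeIndexMap

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def set_partitions(V: int) -> list[tuple[int, ...]]:
    """All set partitions of ``range(V)`` as canonical label tuples
    (restricted growth strings)."""
    parts: list[tuple[int, ...]] = []

    def rec(prefix: list[int]) -> None:
        if len(prefix) == V:
            parts.append(tuple(prefix))
            return
        top = max(prefix) if prefix else -1
        for k in range(top + 2):
            rec(prefix + [k])

    rec([])
    return parts


def brute_lambda(omega, rho0: float, rho_k, emap: EdgeIndexMap) -> np.ndarray:
    """Literal four-index construction of the edge correlation matrix."""
    pairs = emap.pairs
    E = emap.E
    L = np.zeros((E, E))
    for e, (i, j) in enumerate(pairs):
        for f, (a, b) in enumerate(pairs):
            if e == f:
                L[e, f] = 1.0
            elif omega[i] == omega[j] == omega[a] == omega[b]:
                L[e, f] = rho_k[omega[i]]
            else:
                L[e, f] = rho0
    return L


def dense_loglik(H: np.ndarray, N: int, L: np.ndarray) -> float:
    """Reference ``-N/2 (log|L| + tr(H L^{-1}))`` via dense factorisation."""
    sign, logdet = np.linalg.slogdet(L)
    assert sign > 0, "oracle called on a non-PD matrix"
    return -0.5 * N * (logdet + float(np.trace(H @ np.linalg.inv(L))))


def random_valid_state(rng: np.random.Generator, V: int):
    """A random partition with correlation factors inside the PD region."""
    while True:
        K = int(rng.integers(1, min(4, V)))
        omega = rng.integers(0, K, size=V)
        rho0 = float(rng.uniform(0.0, 0.25))
        rho_k = rng.uniform(rho0 + 0.01, 0.85, size=int(omega.max()) + 1)
        emap = EdgeIndexMap(V)
        L = brute_lambda(omega, rho0, rho_k, emap)
        if np.linalg.eigvalsh(L).min() > 1e-8:
            return omega, rho0, rho_k, emap, L


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
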