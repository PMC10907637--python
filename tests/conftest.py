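"""Shared fixtures and oracle helpers for the test suite.

The ``brute_*`` helpers are deliberately independent re-implementations of
the diversity/overlap formulas as plain Python loops; the package's
vectorized code is checked against them, never the other way round.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tcrep import Repertoire, SimulationConfig


def make_rep(counts: dict[str, int], sample_id: str = "s", **meta) -> Repertoire:
    return Repertoire.from_counts(counts, sample_id=sample_id, **meta)


def random_counts(rng: np.random.Generator, n_max: int = 50) -> dict[str, int]:
    """A random clonotype count table with 1..n_max clones."""
    n = int(rng.integers(1, n_max + 1))
    keys = [f"C{i:04d}F" for i in range(n)]
    counts = rng.integers(1, 200, size=n)
    return dict(zip(keys, counts.tolist()))


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no numpy reductions)

def brute_entropy_bits(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts)


def brute_clonality(counts) -> float:
    n = len(counts)
    if n == 1:
        return 1.0
    total = sum(counts)
    acc = sum((c / total) * math.log2(c / total) for c in counts)
    return 1.0 + acc / math.log2(n)


def brute_simpson(counts) -> float:
    total = sum(counts)
    return sum((c / total) ** 2 for c in counts)


def brute_moi(x: dict[str, int], y: dict[str, int]) -> float:
    """Morisita overlap evaluated naively over the key union."""
    nx, ny = sum(x.values()), sum(y.values())
    union = set(x) | set(y)
    cross = sum(x.get(k, 0) * y.get(k, 0) for k in union)
    dx = sum((c / nx) ** 2 for c in x.values())
    dy = sum((c / ny) ** 2 for c in y.values())
    return 2.0 * cross / ((dx + dy) * nx * ny)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_928)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A desk-scale cohort configuration for fast end-to-end tests."""
    return SimulationConfig(
        n_subjects=4,
        unique_clonotypes_per_sample=400,
        total_templates_per_sample=4_000,
        public_pool_size=600,
        seed=11,
    )
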