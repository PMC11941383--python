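"""Shared fixtures and the independent brute-force outranking oracle.

The oracle deliberately avoids the package's vectorized engine: plain Python
triple loops, ``math.exp``, and a literal transcription of the flow
definitions, so that agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
import pytest

from fpromethee import (
    GeneratorConfig,
    LinguisticTerm,
    PreferenceFunctionSpec,
    generate_matrix,
    paper_fixture,
)

# --- independent oracle ----------------------------------------------------


def oracle_sample_std(values: Sequence[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def oracle_gaussian(d: float, s: float) -> float:
    if d <= 0 or s == 0:
        return 0.0
    return 1.0 - math.exp(-(d * d) / (2.0 * s * s))


def oracle_flows(
    grid: Sequence[Sequence[float]],
    weights: Sequence[float],
    directions: Sequence[str],
    spreads: Sequence[float] = None,
) -> Tuple[List[float], List[float], List[float], List[List[float]]]:
    """Literal pi / Phi+ / Phi- / Phi_net with gaussian preferences.

    Spreads default to the per-column sample standard deviation (the
    engine's 'auto' rule, recomputed here independently).
    """
    n, k = len(grid), len(grid[0])
    if spreads is None:
        spreads = [oracle_sample_std([grid[i][j] for i in range(n)]) for j in range(k)]
    pi = [[0.0] * n for _ in range(n)]
    for t in range(n):
        for t2 in range(n):
            if t == t2:
                continue
            total = 0.0
            for j in range(k):
                d = grid[t][j] - grid[t2][j]
                if directions[j] == "minimize":
                    d = -d
                total += weights[j] * oracle_gaussian(d, spreads[j])
            pi[t][t2] = total
    phi_plus = [sum(pi[t][t2] for t2 in range(n) if t2 != t) / (n - 1) for t in range(n)]
    phi_minus = [sum(pi[t2][t] for t2 in range(n) if t2 != t) / (n - 1) for t in range(n)]
    phi_net = [phi_plus[t] - phi_minus[t] for t in range(n)]
    return phi_plus, phi_minus, phi_net, pi


# --- random engine-level problems ------------------------------------------


def random_problem(rng: np.random.Generator, n_max: int = 8, k_max: int = 6):
    """A random resolved grid with weights, gaussian-auto specs, directions."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    grid = rng.normal(loc=rng.uniform(-5, 5), scale=rng.uniform(0.5, 5), size=(n, k))
    weights = rng.uniform(0.1, 1.0, size=k)
    weights /= weights.sum()
    directions = [str(rng.choice(["maximize", "minimize"])) for _ in range(k)]
    specs = [PreferenceFunctionSpec(kind="gaussian", s="auto") for _ in range(k)]
    return grid, weights, specs, directions


# --- fixtures ---------------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_matrix():
    return paper_fixture()


@pytest.fixture()
def small_matrix():
    """A small deterministic generated matrix for fast unit tests."""
    return generate_matrix(GeneratorConfig(
        n_alternatives=6,
        weight_distribution={
            LinguisticTerm.VERY_HIGH: 2,
            LinguisticTerm.HIGH: 2,
            LinguisticTerm.MODERATE: 1,
        },
        fraction_linguistic_cells=0.4,
        n_minimize=2,
        seed=7,
    ))
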