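"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results through different code
paths than the package (exhaustive recursion for alignment scores,
expm-based grid search for distances, nested loops for octants) so that
agreement is informative.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from scipy.linalg import expm

AA20 = "ARNDCQEGHILKMFPSTWYV"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_global_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Exhaustive three-state recursion for the optimal global score."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "start" else NEG
        best = NEG
        if state == "M" and i > 0 and j > 0:
            sub = float(_BLOSUM62[a[i - 1], b[j - 1]])
            best = max(f(i - 1, j - 1, s) for s in ("M", "X", "Y", "start")) + sub
        elif state == "X" and i > 0:
            best = max(
                f(i - 1, j, "X") - gap_extend,
                max(f(i - 1, j, s) for s in ("M", "Y", "start")) - gap_open - gap_extend,
            )
        elif state == "Y" and j > 0:
            best = max(
                f(i, j - 1, "Y") - gap_extend,
                max(f(i, j - 1, s) for s in ("M", "X", "start")) - gap_open - gap_extend,
            )
        return best

    return max(f(len(a), len(b), s) for s in ("M", "X", "Y"))


def oracle_grid_distance(a: str, b: str, alpha: float = 1.0, k: int = 4,
                         d_lo: float = 0.0, d_hi: float = 2.0, n_grid: int = 2001) -> float:
    """Grid-search ML distance using expm (independent of the optimizer)."""
    from lbdtandem.molclock import pairwise_deletion_counts
    from lbdtandem.substitution import GammaModel, jtt_frequencies, jtt_rate_matrix

    counts, _ = pairwise_deletion_counts(a, b)
    gamma = GammaModel(alpha=alpha, k=k)
    q = jtt_rate_matrix()
    pi = jtt_frequencies()
    mask = counts > 0
    grid = np.linspace(d_lo, d_hi, n_grid)
    best_d, best_ll = grid[0], -np.inf
    for d in grid:
        mix = sum(
            w * expm(q * (d * r)) for r, w in zip(gamma.rates, gamma.weights)
        )
        with np.errstate(divide="ignore"):
            logp = np.log(pi[:, None] * mix)
        if np.any(np.isneginf(logp[mask])):
            continue
        ll = float((counts[mask] * logp[mask]).sum())
        if ll > best_ll:
            best_ll, best_d = ll, float(d)
    return best_d


def oracle_octant_count(ligand_coords, ca, radius: float = 5.0) -> int:
    """Per-octant nested-loop count (independent of the package oracle)."""
    seen = []
    for atom in ligand_coords:
        d = [float(atom[m]) - float(ca[m]) for m in range(3)]
        if (d[0] ** 2 + d[1] ** 2 + d[2] ** 2) ** 0.5 > radius:
            continue
        key = 0
        for m in range(3):
            if d[m] >= 0:
                key |= 1 << m
        if key not in seen:
            seen.append(key)
    return len(seen)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))
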