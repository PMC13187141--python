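"""Amino-acid substitution model machinery.

Provides the JTT reversible rate matrix (calibrated to one expected
substitution per site per unit branch length), discrete-gamma rate
heterogeneity, and transition-probability matrices.  Shared by the
sequence simulator and the distance estimator so that parameter-recovery
tests are well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._jtt_data import JTT_ALPHABET, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

AA_ALPHABET = JTT_ALPHABET
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_STATES = 20


def _build_exchangeability() -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    vals = iter(JTT_LOWER_TRIANGLE)
    # column-major lower triangle: (1,0),(2,0),...,(19,0),(2,1),...
    for j in range(N_STATES - 1):
        for i in range(j + 1, N_STATES):
            v = next(vals)
            s[i, j] = v
            s[j, i] = v
    return s


def jtt_frequencies() -> np.ndarray:
    """Stationary amino-acid frequencies of the JTT model (sum to 1)."""
    pi = np.asarray(JTT_FREQUENCIES, dtype=float)
    return pi / pi.sum()


def jtt_rate_matrix() -> np.ndarray:
    """JTT instantaneous rate matrix Q, scaled to unit expected rate.

    Q[i, j] (i != j) is the rate from state i to state j; rows sum to
    zero and -sum_i pi_i Q[i, i] == 1, so branch length equals expected
    substitutions per site.
    """
    pi = jtt_frequencies()
    s = _build_exchangeability()
    q = s * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


@dataclass(frozen=True)
class _Eigen:
    """Spectral decomposition of a reversible Q via pi-symmetrization."""

    eigvals: np.ndarray
    right: np.ndarray   # D^{-1/2} U
    left: np.ndarray    # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        p = (self.right * np.exp(self.eigvals * t)) @ self.left
        # clip tiny negative round-off and renormalize rows
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@lru_cache(maxsize=1)
def jtt_eigen() -> _Eigen:
    pi = jtt_frequencies()
    q = jtt_rate_matrix()
    d_half = np.sqrt(pi)
    b = (q * d_half[:, None]) / d_half[None, :]
    b = 0.5 * (b + b.T)
    w, u = np.linalg.eigh(b)
    right = u / d_half[:, None]
    left = u.T * d_half[None, :]
    return _Eigen(eigvals=w, right=right, left=left)


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the calibrated JTT rate matrix."""
    return jtt_eigen().transition_matrix(t)


@dataclass(frozen=True)
class GammaModel:
    """Discrete-gamma across-site rate heterogeneity.

    ``alpha`` is the gamma shape (mean fixed at 1); ``k`` the number of
    equiprobable categories.  Category rates are the medians of the
    category quantile bins, renormalized so their weighted mean is
    exactly 1.  ``alpha=None`` (or ``inf``) means rate homogeneity.
    """

    alpha: float | None = 1.0
    k: int = 4
    rates: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.alpha is not None and not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.alpha is None or np.isinf(self.alpha):
            rates = np.ones(1)
            weights = np.ones(1)
        else:
            probs = (2 * np.arange(self.k) + 1) / (2 * self.k)
            rates = _gamma_dist.ppf(probs, a=self.alpha, scale=1.0 / self.alpha)
            weights = np.full(self.k, 1.0 / self.k)
            rates = rates / (rates * weights).sum()
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)

    @property
    def n_categories(self) -> int:
        return len(self.rates)


def encode_sequence(seq: str) -> np.ndarray:
    """Map an amino-acid string to JTT state indices (-1 for gap/X/other)."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(ch, -1)
    return out


def decode_sequence(states: np.ndarray) -> str:
    return "".join(AA_ALPHABET[s] for s in states)
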