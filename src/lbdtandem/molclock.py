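"""Pairwise ML amino-acid distances and molecular-clock rate estimation.

Distances are maximum-likelihood under the JTT substitution model with
discrete-gamma rate heterogeneity; gaps and unknown residues are handled
by pairwise deletion.  Bootstrap variances come from site resampling.
Clade rates are slopes of a weighted regression of distances on species
divergence times (through the origin by default: a clock forces d -> 0
as T -> 0), and the duplication-specific quantity is the intra-protein
copy distance divided by the clade rate.

Note on units: distance / rate has units of time (Myr).  Both that
literal quantity and a dimensionless relative rate (available when a
duplication age is supplied) are reported; no interpretation is forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .substitution import GammaModel, encode_sequence, jtt_eigen, jtt_frequencies

D_MAX_DEFAULT = 10.0
OPT_TOL = 1e-6


class DistanceError(ValueError):
    pass


def pairwise_deletion_counts(a: str, b: str) -> tuple[np.ndarray, int]:
    """20x20 site-pattern count matrix over mutually ungapped columns.

    Columns where either sequence carries a gap, X, or any non-canonical
    letter are deleted.
    """
    if len(a) != len(b):
        raise DistanceError(
            f"sequences must be aligned to equal length ({len(a)} != {len(b)})"
        )
    sa = encode_sequence(a)
    sb = encode_sequence(b)
    usable = (sa >= 0) & (sb >= 0)
    n_sites = int(usable.sum())
    if n_sites == 0:
        raise DistanceError("no usable columns after pairwise deletion")
    counts = np.zeros((20, 20))
    np.add.at(counts, (sa[usable], sb[usable]), 1.0)
    return counts, n_sites


def _neg_log_likelihood(d: float, counts: np.ndarray, gamma: GammaModel) -> float:
    eig = jtt_eigen()
    pi = jtt_frequencies()
    mix = np.zeros((20, 20))
    for rate, weight in zip(gamma.rates, gamma.weights):
        mix += weight * eig.transition_matrix(d * rate)
    with np.errstate(divide="ignore"):
        logp = np.log(pi[:, None] * mix)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return np.inf
    return float(-(counts[mask] * logp[mask]).sum())


@dataclass(frozen=True)
class DistanceEstimate:
    pair: tuple[str, str]
    d: float
    variance: float | None
    n_sites: int
    n_boot: int = 0
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("distance must be >= 0")
        if self.variance is not None and self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def _optimize_distance(counts: np.ndarray, gamma: GammaModel, d_max: float) -> float:
    if np.allclose(counts, np.diag(np.diag(counts))):
        return 0.0
    res = minimize_scalar(
        _neg_log_likelihood,
        bounds=(0.0, d_max),
        args=(counts, gamma),
        method="bounded",
        options={"xatol": OPT_TOL},
    )
    if not res.success:
        raise DistanceError(f"distance optimization failed: {res.message}")
    return float(res.x)


def jtt_distance(
    a: str,
    b: str,
    gamma: GammaModel | None = None,
    pair: tuple[str, str] = ("a", "b"),
    d_max: float = D_MAX_DEFAULT,
) -> DistanceEstimate:
    """ML JTT+gamma distance (substitutions/site) between two sequences."""
    gamma = gamma or GammaModel()
    counts, n_sites = pairwise_deletion_counts(a, b)
    d = _optimize_distance(counts, gamma, d_max)
    return DistanceEstimate(
        pair=pair,
        d=d,
        variance=None,
        n_sites=n_sites,
        saturated=d > 0.99 * d_max,
    )


def bootstrap_variance(
    a: str,
    b: str,
    gamma: GammaModel | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    d_max: float = D_MAX_DEFAULT,
) -> float:
    """Variance of the distance over site-resampled bootstrap replicates.

    Site resampling is implemented as a multinomial redraw of the
    site-pattern counts, which is equivalent to resampling columns.
    """
    gamma = gamma or GammaModel()
    counts, n_sites = pairwise_deletion_counts(a, b)
    if np.allclose(counts, np.diag(np.diag(counts))):
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = (counts / n_sites).ravel()
    reps = np.empty(n_boot)
    for i in range(n_boot):
        resampled = rng.multinomial(n_sites, probs).reshape(20, 20).astype(float)
        reps[i] = _optimize_distance(resampled, gamma, d_max)
    return float(np.var(reps, ddof=1))


def estimate_with_variance(
    a: str,
    b: str,
    gamma: GammaModel | None = None,
    pair: tuple[str, str] = ("a", "b"),
    n_boot: int = 1000,
    seed: int = 0,
    d_max: float = D_MAX_DEFAULT,
) -> DistanceEstimate:
    est = jtt_distance(a, b, gamma, pair=pair, d_max=d_max)
    var = bootstrap_variance(a, b, gamma, n_boot=n_boot, seed=seed, d_max=d_max)
    return DistanceEstimate(
        pair=pair,
        d=est.d,
        variance=var,
        n_sites=est.n_sites,
        n_boot=n_boot,
        saturated=est.saturated,
    )


@dataclass(frozen=True)
class ClockFit:
    clade_id: str
    r: float
    se_r: float
    weighting: str
    n_pairs: int
    through_origin: bool = True
    intercept: float = 0.0
    residuals: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not np.isfinite(self.r):
            raise ValueError("fitted rate must be finite")


def _lookup_times(
    estimates: Sequence[DistanceEstimate],
    times: pd.DataFrame | Mapping[tuple[str, str], float],
) -> np.ndarray:
    if isinstance(times, pd.DataFrame):
        table: dict[tuple[str, str], float] = {}
        for _, row in times.iterrows():
            table[(str(row["taxon_a"]), str(row["taxon_b"]))] = float(row["time_mya"])
    else:
        table = {k: float(v) for k, v in times.items()}
    out = np.empty(len(estimates))
    for i, est in enumerate(estimates):
        a, b = est.pair
        t = table.get((a, b), table.get((b, a)))
        if t is None:
            raise ValueError(f"no divergence time for pair ({a!r}, {b!r})")
        out[i] = t
    return out


def _weights(estimates: Sequence[DistanceEstimate], weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(len(estimates))
    if weighting != "inverse-variance":
        raise ValueError(f"weighting must be 'inverse-variance' or 'uniform', got {weighting!r}")
    variances = np.array(
        [np.nan if e.variance is None else e.variance for e in estimates]
    )
    if np.any(np.isnan(variances)):
        raise ValueError("inverse-variance weighting needs bootstrap variances on every pair")
    w = np.empty(len(variances))
    positive = variances > 0
    if not positive.any():
        return np.ones(len(variances))
    w[positive] = 1.0 / variances[positive]
    # zero-variance pairs get the largest finite weight present
    w[~positive] = w[positive].max()
    return w


def fit_clock(
    estimates: Sequence[DistanceEstimate],
    times: pd.DataFrame | Mapping[tuple[str, str], float],
    weighting: str = "inverse-variance",
    through_origin: bool = True,
    clade_id: str = "clade",
) -> ClockFit:
    """Weighted regression of distances on divergence times; slope = rate.

    With inverse-variance weighting the slope standard error is the
    known-weights (generalized least squares) one; with uniform weights
    it is residual-based.
    """
    if len(estimates) < 1:
        raise ValueError("need at least one distance estimate")
    if not through_origin and len(estimates) < 2:
        raise ValueError("free-intercept fit needs >= 2 pairs")
    t = _lookup_times(estimates, times)
    d = np.array([e.d for e in estimates])
    w = _weights(estimates, weighting)

    if through_origin:
        swtt = float((w * t * t).sum())
        r = float((w * t * d).sum() / swtt)
        intercept = 0.0
        resid = d - r * t
        if weighting == "inverse-variance":
            se = float(np.sqrt(1.0 / swtt))
        else:
            dof = len(d) - 1
            se = float(np.sqrt((w * resid**2).sum() / dof / swtt)) if dof > 0 else float("nan")
    else:
        x = np.column_stack([np.ones_like(t), t])
        xtwx = x.T @ (w[:, None] * x)
        beta = np.linalg.solve(xtwx, x.T @ (w * d))
        intercept, r = float(beta[0]), float(beta[1])
        resid = d - x @ beta
        cov = np.linalg.inv(xtwx)
        if weighting == "inverse-variance":
            se = float(np.sqrt(cov[1, 1]))
        else:
            dof = len(d) - 2
            s2 = (w * resid**2).sum() / dof if dof > 0 else float("nan")
            se = float(np.sqrt(s2 * cov[1, 1]))

    return ClockFit(
        clade_id=clade_id,
        r=r,
        se_r=se,
        weighting=weighting,
        n_pairs=len(estimates),
        through_origin=through_origin,
        intercept=intercept,
        residuals=tuple(float(x) for x in resid),
    )


@dataclass(frozen=True)
class DuplicationRate:
    """Duplication-specific quantities for one focal protein.

    ``r_dup = d_dup / r_clade`` (units: Myr — see module docstring);
    ``relative_rate = d_dup / (r_clade * t_dup)`` is dimensionless and
    equals 1 for a duplication evolving exactly at the clade clock.
    """

    focal_id: str
    d_dup: float
    r_clade: float
    r_dup: float
    t_dup: float | None = None
    relative_rate: float | None = None

    def __post_init__(self) -> None:
        if self.r_dup < 0:
            raise ValueError("r_dup must be >= 0")


def duplication_rate(
    d_dup: DistanceEstimate,
    clock: ClockFit,
    t_dup: float | None = None,
    focal_id: str = "focal",
) -> DuplicationRate:
    if clock.r <= 0:
        raise ValueError(f"clade rate must be > 0 for r_dup, got {clock.r}")
    if t_dup is not None and t_dup <= 0:
        raise ValueError(f"duplication age must be > 0, got {t_dup}")
    r_dup = d_dup.d / clock.r
    rel = None if t_dup is None else d_dup.d / (clock.r * t_dup)
    return DuplicationRate(
        focal_id=focal_id,
        d_dup=d_dup.d,
        r_clade=clock.r,
        r_dup=r_dup,
        t_dup=t_dup,
        relative_rate=rel,
    )


def distances_to_tsv(estimates: Sequence[DistanceEstimate]) -> str:
    lines = ["taxon_a\ttaxon_b\td\tvariance\tn_sites\tn_boot\tsaturated"]
    for e in estimates:
        var = "" if e.variance is None else f"{e.variance:.8g}"
        lines.append(
            f"{e.pair[0]}\t{e.pair[1]}\t{e.d:.8g}\t{var}\t{e.n_sites}\t"
            f"{e.n_boot}\t{int(e.saturated)}"
        )
    return "\n".join(lines) + "\n"
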