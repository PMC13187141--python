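"""Clock-evolving clade simulator with a controllable internal duplication.

Topology is a star centered on a focal taxon: the focal sequence is the
center, and every other taxon evolves independently from it along a path
of expected length ``r_true * T_i`` substitutions/site, where ``T_i`` is
the focal-to-taxon divergence time.  Under additivity this makes the
expected path length of EVERY taxon pair equal ``r_true * T(a, b)`` with
``T(focal, i) = T_i`` and ``T(i, j) = T_i + T_j``.

Rate convention (documented because it is easy to get wrong): ``r_true``
is defined on the PAIRWISE path, ``d = r * T``; per lineage the rate is
``r/2`` when the pair time is split symmetrically.  The divergence table
emitted here is already on the pairwise-path convention, so regressing
distances on it recovers ``r_true`` as the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..seqio_domains.records import ProteinRecord
from ..substitution import (
    GammaModel,
    decode_sequence,
    jtt_eigen,
    jtt_frequencies,
)


@dataclass(frozen=True)
class CladeSimSpec:
    """Parameters for one clade simulation.

    ``divergence_times`` are focal-to-taxon times in Myr, one per
    non-focal taxon (``n_taxa - 1`` values).  ``dup_taxon`` (focal by
    default) carries two domain copies separated by an expected path of
    ``d_dup_true`` substitutions/site.
    """

    n_taxa: int
    divergence_times: tuple[float, ...]
    r_true: float
    seq_length: int
    gamma_alpha: float | None = 1.0
    dup_taxon: str | None = None
    d_dup_true: float | None = None
    seed: int = 0
    gamma_k: int = 4

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError(f"n_taxa must be >= 2, got {self.n_taxa}")
        if len(self.divergence_times) != self.n_taxa - 1:
            raise ValueError(
                f"divergence_times must have n_taxa - 1 = {self.n_taxa - 1} "
                f"entries, got {len(self.divergence_times)}"
            )
        if any(t <= 0 for t in self.divergence_times):
            raise ValueError("divergence_times must all be > 0")
        if self.r_true < 0:
            raise ValueError(f"r_true must be >= 0, got {self.r_true}")
        if self.seq_length < 1:
            raise ValueError(f"seq_length must be >= 1, got {self.seq_length}")
        if self.gamma_alpha is not None and not (self.gamma_alpha > 0):
            raise ValueError(f"gamma_alpha must be > 0, got {self.gamma_alpha}")
        if self.d_dup_true is not None and self.d_dup_true < 0:
            raise ValueError(f"d_dup_true must be >= 0, got {self.d_dup_true}")
        if self.dup_taxon is not None and self.dup_taxon not in self.taxa:
            raise ValueError(f"dup_taxon {self.dup_taxon!r} not among taxa {self.taxa}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(f"t{i}" for i in range(self.n_taxa))

    @property
    def focal(self) -> str:
        return "t0"

    @property
    def effective_dup_taxon(self) -> str | None:
        if self.d_dup_true is None:
            return None
        return self.dup_taxon or self.focal


@dataclass(frozen=True)
class CladeSimResult:
    records: tuple[ProteinRecord, ...]
    dup_records: tuple[ProteinRecord, ...]  # the two copies, when simulated
    divergence_table: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)


def evolve_states(
    parent: np.ndarray,
    path_length: float,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve each site along ``path_length`` scaled by its site rate."""
    if path_length < 0:
        raise ValueError("path_length must be >= 0")
    child = parent.copy()
    if path_length == 0:
        return child
    eig = jtt_eigen()
    for rate in np.unique(site_rates):
        idx = np.flatnonzero(site_rates == rate)
        if rate == 0:
            continue
        p = eig.transition_matrix(path_length * rate)
        cum = np.cumsum(p[parent[idx]], axis=1)
        u = rng.random(len(idx))
        child[idx] = np.minimum((cum < u[:, None]).sum(axis=1), p.shape[1] - 1)
    return child


def simulate_clade(spec: CladeSimSpec) -> CladeSimResult:
    """Generate clade sequences, the divergence table, and ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    gamma = GammaModel(alpha=spec.gamma_alpha, k=spec.gamma_k)
    pi = jtt_frequencies()

    categories = rng.integers(0, gamma.n_categories, size=spec.seq_length)
    site_rates = gamma.rates[categories]

    root = rng.choice(20, size=spec.seq_length, p=pi)
    taxa = spec.taxa
    times = dict(zip(taxa[1:], spec.divergence_times))

    seqs: dict[str, np.ndarray] = {spec.focal: root}
    for taxon in taxa[1:]:
        seqs[taxon] = evolve_states(root, spec.r_true * times[taxon], site_rates, rng)

    dup_taxon = spec.effective_dup_taxon
    dup_records: tuple[ProteinRecord, ...] = ()
    if dup_taxon is not None:
        copy1 = seqs[dup_taxon]
        copy2 = evolve_states(copy1, spec.d_dup_true, site_rates, rng)
        dup_records = (
            ProteinRecord(id=f"{dup_taxon}_lbd_out", sequence=decode_sequence(copy2),
                          species=dup_taxon),
            ProteinRecord(id=f"{dup_taxon}_lbd_in", sequence=decode_sequence(copy1),
                          species=dup_taxon),
        )

    records = tuple(
        ProteinRecord(id=taxon, sequence=decode_sequence(seqs[taxon]), species=taxon)
        for taxon in taxa
    )

    rows = []
    expected: dict[tuple[str, str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            t = times[b] if a == spec.focal else times[a] + times[b]
            rows.append({"taxon_a": a, "taxon_b": b, "time_mya": float(t)})
            expected[(a, b)] = spec.r_true * t
    table = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "time_mya"])

    truth = {
        "r_true": spec.r_true,
        "expected_path_lengths": expected,
        "dup_taxon": dup_taxon,
        "d_dup_true": spec.d_dup_true,
        "site_rate_categories": categories,
        "site_rates": site_rates,
    }
    return CladeSimResult(
        records=records,
        dup_records=dup_records,
        divergence_table=table,
        truth=truth,
    )


def write_divergence_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_divergence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"taxon_a", "taxon_b", "time_mya"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"divergence table missing column(s): {sorted(missing)}")
    return df
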