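"""Synthetic receptor gene models with an optional duplicated exon pair.

The protein is laid out as::

    [signal] [domain (exon pair E2+E3)] [linker] [domain' (E2'+E3')] [tail]

so the inter-domain linker sits at the junction of the first copy's
second exon and the duplicated copy's first exon.  The CDS is a reverse
translation on a synthetic contig; translation consistency is an
invariant checked at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

# one deterministic codon per amino acid (no wobble randomness needed)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class Exon:
    """CDS coordinates, 0-based half-open, on the synthetic contig."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneModelFixture:
    contig: str
    exons: tuple[Exon, ...]
    protein: str
    domain_bounds: tuple[tuple[int, int], ...]  # 0-based half-open on protein
    expected_linker_length: int | None

    def __post_init__(self) -> None:
        cds = "".join(self.contig[e.start:e.end] for e in self.exons)
        translated = str(Seq(cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if translated != self.protein:
            raise ValueError("translated CDS does not match protein sequence")


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(_AA[i] for i in rng.integers(0, 20, size=n))


def make_gene_model(
    two_lbd: bool = True,
    linker_len: int = 20,
    seed: int = 0,
    domain_len: int = 100,
    intron_len: int = 60,
) -> GeneModelFixture:
    """Build a gene-model fixture with known domain/linker layout.

    With ``two_lbd`` the second domain is an exact duplicate of the
    first (an exon-pair duplication); ``linker_len`` residues separate
    the two domains on the protein.
    """
    if linker_len < 0:
        raise ValueError(f"linker_len must be >= 0, got {linker_len}")
    if domain_len < 2 or domain_len % 2:
        raise ValueError(f"domain_len must be even and >= 2, got {domain_len}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    signal = _random_protein(12, rng)
    domain = _random_protein(domain_len, rng)
    linker = _random_protein(linker_len, rng)
    tail = _random_protein(30, rng)

    if two_lbd:
        protein = signal + domain + linker + domain + tail
        dom1 = (len(signal), len(signal) + domain_len)
        dom2_start = dom1[1] + linker_len
        bounds = (dom1, (dom2_start, dom2_start + domain_len))
        expected = linker_len
    else:
        protein = signal + domain + tail
        bounds = ((len(signal), len(signal) + domain_len),)
        expected = None

    # exon layout on the protein: E1 = signal; each domain copy split in
    # half over an exon pair; the linker rides at the tail of the first
    # copy's second exon (the E3/E2' junction); final exon = tail + stop
    half = domain_len // 2
    protein_chunks = [("E1", signal), ("E2", domain[:half])]
    if two_lbd:
        protein_chunks += [
            ("E3", domain[half:] + linker),
            ("E2p", domain[:half]),
            ("E3p", domain[half:]),
        ]
    else:
        protein_chunks.append(("E3", domain[half:]))
    protein_chunks.append(("E4", tail))

    contig_parts: list[str] = []
    exons: list[Exon] = []
    pos = 0
    intron = "GT" + "A" * (intron_len - 4) + "AG"
    for i, (name, chunk) in enumerate(protein_chunks):
        cds = "".join(_CODON[aa] for aa in chunk)
        if i == len(protein_chunks) - 1:
            cds += "TAA"
        exons.append(Exon(name=name, start=pos, end=pos + len(cds)))
        contig_parts.append(cds)
        pos += len(cds)
        if i < len(protein_chunks) - 1:
            contig_parts.append(intron)
            pos += len(intron)

    return GeneModelFixture(
        contig="".join(contig_parts),
        exons=tuple(exons),
        protein=protein,
        domain_bounds=bounds,
        expected_linker_length=expected,
    )
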