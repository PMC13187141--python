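"""Protein records and FASTA round-tripping.

A thin line-tracking FASTA reader is used instead of Bio.SeqIO so that
malformed input can be reported with the offending line number; writing
delegates to plain text (two-line records, no wrapping surprises).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP_CHAR = "-"


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species/clade provenance tags."""

    id: str
    sequence: str
    species: str = ""
    clade: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        # gaps tolerated at the record level; read_fasta is strict by default
        validate_sequence(self.sequence, allow_gaps=True, context=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(seq: str, *, allow_gaps: bool = False, context: str = "") -> None:
    allowed = VALID_RESIDUES | {GAP_CHAR} if allow_gaps else VALID_RESIDUES
    bad = set(seq.upper()) - allowed
    if bad:
        where = f" in {context!r}" if context else ""
        raise ValueError(
            f"invalid residue letter(s) {sorted(bad)}{where}; "
            f"allowed: 20 canonical amino acids plus X"
            + (" and '-'" if allow_gaps else "")
        )


def _parse_header(line: str) -> tuple[str, str, str]:
    """Header grammar: ``>id [species=...] [clade=...] free text``."""
    body = line[1:].strip()
    if not body:
        raise ValueError("empty FASTA header")
    parts = body.split()
    rec_id = parts[0]
    species = clade = ""
    for tok in parts[1:]:
        if tok.startswith("species="):
            species = tok[len("species="):]
        elif tok.startswith("clade="):
            clade = tok[len("clade="):]
    return rec_id, species, clade


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinRecord]:
    """Parse a protein FASTA file into validated records.

    Raises :class:`FastaParseError` with a line number on structural
    problems and on alphabet violations.
    """
    records: list[ProteinRecord] = []
    header: tuple[str, str, str] | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_number: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {header[0]!r} has no sequence", header_line)
        try:
            validate_sequence(seq, allow_gaps=allow_gaps, context=header[0])
        except ValueError as exc:
            raise FastaParseError(str(exc), line_number) from exc
        records.append(
            ProteinRecord(
                id=header[0],
                sequence=seq.upper(),
                species=header[1],
                clade=header[2],
            )
        )

    with open(path) as fh:
        n = 0
        for n, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(n - 1)
                try:
                    header = _parse_header(line)
                except ValueError as exc:
                    raise FastaParseError(str(exc), n) from exc
                header_line = n
                chunks = []
            else:
                if header is None:
                    raise FastaParseError("sequence data before first header", n)
                chunks.append(line)
        flush(n)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tags = []
            if rec.species:
                tags.append(f"species={rec.species}")
            if rec.clade:
                tags.append(f"clade={rec.clade}")
            suffix = (" " + " ".join(tags)) if tags else ""
            fh.write(f">{rec.id}{suffix}\n{rec.sequence}\n")
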