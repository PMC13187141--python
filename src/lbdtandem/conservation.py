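"""Intra-protein domain identity profiles and epitope retention scoring.

Percent identity uses mutually ungapped columns as the denominator by
default (pairwise-deletion style, consistent with the distance module);
the full-alignment-length denominator is available behind a flag since
published percentages rarely state their convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .seqio_domains.align import AlignParams, align_global
from .seqio_domains.domains import DomainAnnotation
from .seqio_domains.records import ProteinRecord


def identity_pct(
    a: str,
    b: str,
    params: AlignParams | None = None,
    denominator: str = "ungapped",
) -> float:
    """Percent identity between two sequences after global alignment.

    ``denominator='ungapped'`` counts only columns where both sequences
    carry a residue; ``'full'`` uses the whole alignment length.  The
    two inputs are aligned in a canonical order so the result is exactly
    symmetric.  Rounding is left to presentation.
    """
    if denominator not in ("ungapped", "full"):
        raise ValueError(f"denominator must be 'ungapped' or 'full', got {denominator!r}")
    a, b = a.upper(), b.upper()
    if not a.replace("-", "") or not b.replace("-", ""):
        raise ValueError("identity undefined: empty sequence after de-gapping")
    x, y = sorted((a.replace("-", ""), b.replace("-", "")))
    aln = align_global(x, y, params)
    matches = 0
    both = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                matches += 1
    denom = both if denominator == "ungapped" else aln.length
    if denom == 0:
        raise ValueError("identity undefined: no comparable columns")
    return 100.0 * matches / denom


@dataclass(frozen=True)
class IdentityProfile:
    """Per-domain identity relative to the membrane-proximal (in) copy."""

    protein_id: str
    reference_label: str
    values: Mapping[str, float]  # label -> percent identity vs LBD-in

    def __post_init__(self) -> None:
        ref = self.values.get(self.reference_label)
        if ref is None or abs(ref - 100.0) > 1e-9:
            raise ValueError("reference domain must be present at exactly 100%")
        for label, v in self.values.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"identity out of range for {label}: {v}")


def identity_profile(
    protein: ProteinRecord,
    annotations: Sequence[DomainAnnotation],
    params: AlignParams | None = None,
) -> IdentityProfile:
    """Identity of every annotated domain copy against the ``in`` copy."""
    if len(annotations) < 2:
        raise ValueError(
            "identity profile needs >= 2 domain annotations "
            f"(protein {protein.id!r} has {len(annotations)}); nothing to compare"
        )
    by_label = {a.label: a for a in annotations}
    if "in" not in by_label:
        raise ValueError("no annotation labeled 'in'")
    ref = by_label["in"]
    ref_seq = protein.sequence[ref.start:ref.end]
    values: dict[str, float] = {}
    for a in sorted(annotations, key=lambda x: x.start):
        if a.label == "in":
            values["in"] = 100.0
        else:
            values[a.label] = identity_pct(
                protein.sequence[a.start:a.end], ref_seq, params
            )
    return IdentityProfile(protein_id=protein.id, reference_label="in", values=values)


@dataclass(frozen=True)
class EpitopeSpec:
    """Ligand-contact positions on a reference domain, grouped by site.

    Positions are 1-based on the (ungapped) reference domain sequence.
    """

    reference_id: str
    groups: Mapping[str, tuple[int, ...]]
    contact_types: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for group, positions in self.groups.items():
            for p in positions:
                if p < 1:
                    raise ValueError(f"group {group!r}: positions are 1-based, got {p}")
                if p in seen:
                    raise ValueError(f"duplicate epitope position {p}")
                seen.add(p)
        for p, ctype in self.contact_types.items():
            if ctype not in ("polar", "hydrophobic"):
                raise ValueError(f"position {p}: contact type must be polar|hydrophobic")

    def all_positions(self) -> tuple[int, ...]:
        return tuple(p for ps in self.groups.values() for p in ps)


def read_epitope_spec(path: str | Path, reference_id: str = "") -> EpitopeSpec:
    """Load a TSV epitope spec (columns: group, ref_pos_1based, contact_type)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"group", "ref_pos_1based"}
    if not required <= set(df.columns):
        raise ValueError(f"epitope spec needs columns {sorted(required)}")
    groups: dict[str, list[int]] = {}
    contact_types: dict[int, str] = {}
    for _, row in df.iterrows():
        pos = int(row["ref_pos_1based"])
        groups.setdefault(str(row["group"]), []).append(pos)
        if "contact_type" in df.columns and pd.notna(row.get("contact_type")):
            contact_types[pos] = str(row["contact_type"])
    return EpitopeSpec(
        reference_id=reference_id or str(Path(path).stem),
        groups={g: tuple(ps) for g, ps in groups.items()},
        contact_types=contact_types,
    )


@dataclass(frozen=True)
class RetentionScore:
    target_id: str
    group: str
    retained_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.retained_count <= self.total_count):
            raise ValueError("retained count out of range")

    @property
    def fraction(self) -> float:
        return self.retained_count / self.total_count

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def epitope_retention(
    target_lbd: str,
    reference_lbd: str,
    spec: EpitopeSpec,
    mode: str = "strict",
    params: AlignParams | None = None,
    target_id: str = "target",
) -> list[RetentionScore]:
    """Score how many reference contact positions the target retains.

    ``strict`` requires the identical residue; ``similar`` accepts any
    positive-scoring BLOSUM62 substitution.  A position aligned to a gap
    is never retained.
    """
    if mode not in ("strict", "similar"):
        raise ValueError(f"mode must be 'strict' or 'similar', got {mode!r}")
    reference_lbd = reference_lbd.upper().replace("-", "")
    target_lbd = target_lbd.upper().replace("-", "")
    max_pos = max(spec.all_positions(), default=0)
    if max_pos > len(reference_lbd):
        raise ValueError(
            f"epitope position {max_pos} exceeds reference length {len(reference_lbd)}"
        )
    params = params or AlignParams()
    aln = align_global(reference_lbd, target_lbd, params)
    # map 1-based reference positions to target residues (None when gapped)
    ref_to_target: dict[int, str | None] = {}
    ref_pos = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            ref_pos += 1
            ref_to_target[ref_pos] = cb if cb != "-" else None

    lookup = params.score_lookup()
    scores = []
    for group, positions in spec.groups.items():
        retained = 0
        for pos in positions:
            tgt = ref_to_target.get(pos)
            if tgt is None:
                continue
            ref_res = reference_lbd[pos - 1]
            if mode == "strict":
                retained += tgt == ref_res
            else:
                retained += (tgt == ref_res) or lookup[(ref_res, tgt)] > 0
        scores.append(
            RetentionScore(
                target_id=target_id,
                group=group,
                retained_count=retained,
                total_count=len(positions),
            )
        )
    return scores


def retention_to_tsv(scores: Sequence[RetentionScore]) -> str:
    lines = ["target\tgroup\tretained\ttotal\tfraction"]
    for s in scores:
        lines.append(
            f"{s.target_id}\t{s.group}\t{s.retained_count}\t{s.total_count}\t"
            f"{s.fraction:.6g}"
        )
    return "\n".join(lines) + "\n"
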