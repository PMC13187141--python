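"""Tandem LBD annotation by iterative local alignment with masking.

A reference domain is scanned against the target protein with
Smith-Waterman; after each accepted hit the hit span is removed from the
search space and the scan repeats on the remaining unmasked segments,
which guarantees termination and non-overlapping annotations.  Hits are
labeled by N-to-C order: the most C-terminal (membrane-proximal) copy is
``in``, the most N-terminal is ``out``, and middle copies are ``mid``
(``mid1..midN`` when there are more than three copies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .align import AlignParams, align_local
from .records import ProteinRecord

MIN_REFERENCE_LENGTH = 30


@dataclass(frozen=True)
class DetectionParams:
    """Knobs for tandem-domain detection.

    ``min_score_frac`` — accept threshold as a fraction of the reference
    self-alignment score; ``min_len_frac`` — minimum hit span on the
    protein as a fraction of the reference length.
    """

    align: AlignParams = AlignParams()
    min_score_frac: float = 0.4
    min_len_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_score_frac <= 1):
            raise ValueError(f"min_score_frac must be in (0, 1], got {self.min_score_frac}")
        if not (0 < self.min_len_frac <= 1):
            raise ValueError(f"min_len_frac must be in (0, 1], got {self.min_len_frac}")


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain occurrence; coordinates are 0-based half-open internally."""

    protein_id: str
    start: int
    end: int
    order_index: int
    label: str
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


def self_score(sequence: str, params: AlignParams) -> float:
    lookup = params.score_lookup()
    return float(sum(lookup[(c, c)] for c in sequence.upper()))


def _labels_for(n: int) -> list[str]:
    if n == 1:
        return ["in"]
    if n == 2:
        return ["out", "in"]
    if n == 3:
        return ["out", "mid", "in"]
    return ["out"] + [f"mid{i}" for i in range(1, n - 1)] + ["in"]


def detect_tandem_domains(
    protein: ProteinRecord,
    reference_lbd: str,
    params: DetectionParams | None = None,
) -> list[DomainAnnotation]:
    """Annotate every tandem copy of ``reference_lbd`` on ``protein``.

    Returns annotations sorted N to C with labels assigned by position;
    an empty list when nothing scores above threshold.
    """
    params = params or DetectionParams()
    reference_lbd = reference_lbd.upper().replace("-", "")
    if len(reference_lbd) < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference LBD must be >= {MIN_REFERENCE_LENGTH} residues, "
            f"got {len(reference_lbd)}"
        )
    threshold = params.min_score_frac * self_score(reference_lbd, params.align)
    min_hit_len = int(params.min_len_frac * len(reference_lbd))

    seq = protein.sequence
    segments: list[tuple[int, int]] = [(0, len(seq))]
    hits: list[tuple[int, int, float]] = []

    while True:
        best = None
        best_seg = None
        for seg in segments:
            lo, hi = seg
            if hi - lo < min_hit_len:
                continue
            hit = align_local(reference_lbd, seq[lo:hi], params.align)
            if hit is None:
                continue
            span = hit.b_end - hit.b_start
            if hit.score < threshold or span < min_hit_len:
                continue
            if best is None or hit.score > best.score:
                best = hit
                best_seg = seg
        if best is None:
            break
        lo, hi = best_seg
        hits.append((lo + best.b_start, lo + best.b_end, best.score))
        segments.remove(best_seg)
        if best.b_start > 0:
            segments.append((lo, lo + best.b_start))
        if lo + best.b_end < hi:
            segments.append((lo + best.b_end, hi))

    hits.sort(key=lambda h: h[0])
    labels = _labels_for(len(hits))
    return [
        DomainAnnotation(
            protein_id=protein.id,
            start=s,
            end=e,
            order_index=i + 1,
            label=labels[i],
            score=score,
        )
        for i, (s, e, score) in enumerate(hits)
    ]


@dataclass(frozen=True)
class LinkerResult:
    """Residue counts strictly between adjacent domain copies."""

    lengths: tuple[int, ...]
    status: str = "ok"

    @property
    def present(self) -> bool:
        return bool(self.lengths)

    @property
    def value(self) -> int | None:
        """The single inter-domain gap for a two-copy protein."""
        return self.lengths[0] if self.lengths else None


def linker_length_from_domains(annotations: Sequence[DomainAnnotation]) -> LinkerResult:
    """Inter-domain linker lengths for each adjacent pair of annotations.

    With fewer than two annotations the linker is absent and the status
    explains why (no error is raised).
    """
    if len(annotations) < 2:
        return LinkerResult(
            lengths=(),
            status=f"absent: need >= 2 domain annotations, have {len(annotations)}",
        )
    ordered = sorted(annotations, key=lambda a: a.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping annotations: [{prev.start}, {prev.end}) and "
                f"[{nxt.start}, {nxt.end})"
            )
    gaps = tuple(nxt.start - prev.end for prev, nxt in zip(ordered, ordered[1:]))
    return LinkerResult(lengths=gaps)


def annotations_to_tsv(annotations: Sequence[DomainAnnotation]) -> str:
    """Serialize annotations with 1-based inclusive coordinates."""
    lines = ["protein_id\tstart_1based\tend_1based\torder\tlabel\tscore"]
    for a in annotations:
        lines.append(
            f"{a.protein_id}\t{a.start_1based}\t{a.end_1based}\t"
            f"{a.order_index}\t{a.label}\t{a.score:g}"
        )
    return "\n".join(lines) + "\n"


def relabel(annotations: Sequence[DomainAnnotation]) -> list[DomainAnnotation]:
    """Re-sort N to C and reassign order indices and positional labels."""
    ordered = sorted(annotations, key=lambda a: a.start)
    labels = _labels_for(len(ordered))
    return [
        replace(a, order_index=i + 1, label=labels[i])
        for i, a in enumerate(ordered)
    ]
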