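"""Pairwise alignment with affine gap penalties (Gotoh three-state DP).

Conventions
-----------
* A gap of length L costs ``gap_open + L * gap_extend`` (opening charge
  plus a per-residue extension charge, i.e. the BLAST -11/-1 style when
  open=10, extend=1).
* Tie-breaking is deterministic: diagonal (match state) is preferred
  over an up-gap (gap in sequence b), which is preferred over a
  left-gap (gap in sequence a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .records import validate_sequence

_NEG = -1e30

# traceback states
_M, _X, _Y, _START = 0, 1, 2, 3


@dataclass(frozen=True)
class AlignParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def score_lookup(self) -> dict[tuple[str, str], float]:
        return _load_matrix(self.matrix_name)


_MATRIX_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def _load_matrix(name: str) -> dict[tuple[str, str], float]:
    if name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(name)
        lookup: dict[tuple[str, str], float] = {}
        for a in mat.alphabet:
            for b in mat.alphabet:
                lookup[(a, b)] = float(mat[a, b])
        _MATRIX_CACHE[name] = lookup
    return _MATRIX_CACHE[name]


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment: equal-length gapped strings plus its score."""

    aligned_a: str
    aligned_b: str
    score: float
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def _score_fn(params: AlignParams):
    lookup = params.score_lookup()

    def s(a: str, b: str) -> float:
        try:
            return lookup[(a, b)]
        except KeyError:
            raise ValueError(
                f"residue pair ({a!r}, {b!r}) not scored by {params.matrix_name}"
            ) from None

    return s


def align_global(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal Needleman-Wunsch alignment under affine gap penalties."""
    params = params or AlignParams()
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    validate_sequence(a, context="a")
    validate_sequence(b, context="b")
    s = _score_fn(params)
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    mm = np.full((n + 1, m + 1), _NEG)
    xx = np.full((n + 1, m + 1), _NEG)  # gap in b (consume a, "up")
    yy = np.full((n + 1, m + 1), _NEG)  # gap in a ("left")
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    mm[0, 0] = 0.0
    for i in range(1, n + 1):
        xx[i, 0] = -go - ge * i
        ptr[_X, i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        yy[0, j] = -go - ge * j
        ptr[_Y, 0, j] = _M if j == 1 else _Y

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # match state: predecessor priority M > X > Y
            cands = (mm[i - 1, j - 1], xx[i - 1, j - 1], yy[i - 1, j - 1])
            k = int(np.argmax(cands))
            mm[i, j] = cands[k] + s(ai, b[j - 1])
            ptr[_M, i, j] = k

            cands = (mm[i - 1, j] - go - ge, xx[i - 1, j] - ge, yy[i - 1, j] - go - ge)
            k = int(np.argmax(cands))
            xx[i, j] = cands[k]
            ptr[_X, i, j] = k

            cands = (mm[i, j - 1] - go - ge, xx[i, j - 1] - go - ge, yy[i, j - 1] - ge)
            k = int(np.argmax(cands))
            yy[i, j] = cands[k]
            ptr[_Y, i, j] = k

    finals = (mm[n, m], xx[n, m], yy[n, m])
    state = int(np.argmax(finals))
    score = finals[state]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev

    return AlignmentResult(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        params=params,
    )


@dataclass(frozen=True)
class LocalHit:
    """A Smith-Waterman hit with 0-based half-open spans on both inputs."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str


def align_local(a: str, b: str, params: AlignParams | None = None) -> LocalHit | None:
    """Best local (Smith-Waterman) alignment; None if no positive score."""
    params = params or AlignParams()
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    s = _score_fn(params)
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    mm = np.zeros((n + 1, m + 1))
    xx = np.full((n + 1, m + 1), _NEG)
    yy = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    best = 0.0
    best_ij = (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # a zero-score prefix is dropped: predecessors count only if > 0
            cands = (mm[i - 1, j - 1], xx[i - 1, j - 1], yy[i - 1, j - 1])
            k = int(np.argmax(cands))
            if cands[k] > 0:
                mm[i, j] = cands[k] + s(ai, b[j - 1])
                ptr[_M, i, j] = k
            else:
                mm[i, j] = s(ai, b[j - 1])
                ptr[_M, i, j] = _START
            if mm[i, j] < 0:
                mm[i, j] = 0.0
                ptr[_M, i, j] = _START

            cands = (mm[i - 1, j] - go - ge, xx[i - 1, j] - ge, yy[i - 1, j] - go - ge)
            k = int(np.argmax(cands))
            xx[i, j] = cands[k]
            ptr[_X, i, j] = k

            cands = (mm[i, j - 1] - go - ge, xx[i, j - 1] - go - ge, yy[i, j - 1] - ge)
            k = int(np.argmax(cands))
            yy[i, j] = cands[k]
            ptr[_Y, i, j] = k

            if mm[i, j] > best:
                best = mm[i, j]
                best_ij = (i, j)

    if best <= 0:
        return None

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = best_ij
    a_end, b_end = i, j
    state = _M
    while True:
        prev = int(ptr[state, i, j])
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if prev == _START:
            break
        state = prev

    return LocalHit(
        score=float(best),
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
    )
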