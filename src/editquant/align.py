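"""Semi-global read-to-amplicon alignment.

Each read is aligned end-to-end against its reference amplicon ("fitting"
alignment: the read is fully consumed, unaligned reference overhangs on
either side are free).  Affine gap scoring, defaults chosen so that one clean
indel near the cut site outscores a scatter of mismatches:

    match +1, mismatch -4, gap open -6, gap extend -1
    (a gap of length L costs 6 + L)

All equal-scoring indel placements are normalised to the leftmost (lowest
reference coordinate) placement, so downstream window rules are
deterministic.  The scoring-matrix fill runs under numba; the traceback and
segment bookkeeping are plain Python.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .amplicon import AmpliconReference, revcomp

MATCH = 1.0
MISMATCH = -4.0
GAP_OPEN = -6.0
GAP_EXTEND = -1.0

_NEG = -1e18

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class InvalidReadError(ValueError):
    """A read that cannot be aligned; ``code`` is a machine-readable reason."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class Segment:
    """One alignment run.

    ``op`` is '=' (match), 'X' (mismatch), 'I' (insertion: consumes read
    only; ``ref_start`` is the inter-base reference coordinate) or 'D'
    (deletion: consumes reference only).
    """

    op: str
    length: int
    ref_start: int
    read_start: int


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    read_seq: str
    segments: tuple[Segment, ...]
    score: float
    reverse_complemented: bool = False

    @property
    def ref_start(self) -> int:
        return self.segments[0].ref_start

    @property
    def ref_end(self) -> int:
        last = self.segments[-1]
        return last.ref_start + (last.length if last.op in "=XD" else 0)

    def cigar(self) -> str:
        return "".join(f"{s.length}{s.op}" for s in self.segments)

    def indel_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.op in "ID"]

    def has_indel(self) -> bool:
        return any(s.op in "ID" for s in self.segments)

    def read_base_at_ref(self, ref_pos: int) -> str | None:
        """Read base aligned to a reference position; None if deleted or
        outside the aligned span."""
        for s in self.segments:
            if s.op in "=X" and s.ref_start <= ref_pos < s.ref_start + s.length:
                return self.read_seq[s.read_start + (ref_pos - s.ref_start)]
            if s.op == "D" and s.ref_start <= ref_pos < s.ref_start + s.length:
                return None
        return None

def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise InvalidReadError(
            "non_acgtn", f"read contains non-ACGTN character {exc.args[0]!r}"
        ) from None


@njit(cache=True)
def _fill(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.shape[0]
    m = ref.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for j in range(m + 1):
        M[0, j] = 0.0  # free leading reference gap: start anywhere
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(m + 1):
            # insertion (consumes read base i-1)
            best = M[i - 1, j] + gap_open + gap_extend
            p = 0
            v = X[i - 1, j] + gap_extend
            if v > best:
                best = v
                p = 1
            v = Y[i - 1, j] + gap_open + gap_extend
            if v > best:
                best = v
                p = 2
            X[i, j] = best
            pX[i, j] = p
            if j > 0:
                # diagonal
                best = M[i - 1, j - 1]
                p = 0
                if X[i - 1, j - 1] > best:
                    best = X[i - 1, j - 1]
                    p = 1
                if Y[i - 1, j - 1] > best:
                    best = Y[i - 1, j - 1]
                    p = 2
                rj = ref[j - 1]
                s = match if (ri == rj and ri < 4) else mismatch
                M[i, j] = best + s
                pM[i, j] = p
                # deletion (consumes reference base j-1)
                best = M[i, j - 1] + gap_open + gap_extend
                p = 0
                v = Y[i, j - 1] + gap_extend
                if v > best:
                    best = v
                    p = 2
                v = X[i, j - 1] + gap_open + gap_extend
                if v > best:
                    best = v
                    p = 1
                Y[i, j] = best
                pY[i, j] = p
    return M, X, Y, pM, pX, pY


def _traceback(read_s: str, ref_s: str, M, X, Y, pM, pX, pY) -> tuple[list[str], int, float]:
    """Return per-column ops (read order), alignment ref start, and score."""
    n, m = len(read_s), len(ref_s)
    # end state: best over ref columns; prefer diagonal state, then leftmost j
    best = _NEG
    state, jend = 0, m
    for j in range(m + 1):
        for st, mat in ((0, M), (1, X), (2, Y)):
            if mat[n, j] > best + 1e-12:
                best = mat[n, j]
                state, jend = st, j
    ops: list[str] = []
    i, j, st = n, jend, state
    while i > 0 or (st != 0 and j > 0):
        if st == 0:
            if i == 0:
                break
            ops.append("=" if read_s[i - 1] == ref_s[j - 1] and read_s[i - 1] != "N" else "X")
            st = pM[i, j]
            i -= 1
            j -= 1
        elif st == 1:
            ops.append("I")
            st = pX[i, j]
            i -= 1
        else:
            ops.append("D")
            st = pY[i, j]
            j -= 1
    ops.reverse()
    return ops, j, best


def _segments_from_ops(ops: list[str], ref_start: int) -> tuple[Segment, ...]:
    segs: list[Segment] = []
    ref_pos, read_pos = ref_start, 0
    for op in ops:
        if segs and segs[-1].op == op:
            last = segs[-1]
            segs[-1] = Segment(op, last.length + 1, last.ref_start, last.read_start)
        else:
            segs.append(Segment(op, 1, ref_pos, read_pos))
        if op in "=XD":
            ref_pos += 1
        if op in "=XI":
            read_pos += 1
    return tuple(segs)


def align_semiglobal(
    read: str,
    ref: AmpliconReference | str,
    read_id: str = "read",
    orientation: str = "forward",
    min_read_len: int = 25,
) -> AlignedRead:
    """Align a read to its amplicon.

    ``orientation`` is 'forward', 'reverse' (reverse-complement the read
    first) or 'auto' (align both and keep the better score; ties keep
    forward).  Indels in the result are always left-aligned.  ``ref`` may be
    a bare reference string when no annotation is needed.
    """
    ref_seq = ref if isinstance(ref, str) else ref.sequence
    read = read.upper()
    if len(read) < min_read_len:
        raise InvalidReadError(
            "too_short", f"read length {len(read)} < {min_read_len}"
        )
    if orientation not in ("forward", "reverse", "auto"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "forward" and len(read) <= len(ref_seq) and read == ref_seq[: len(read)]:
        # exact 5'-anchored read: the all-match alignment attains the score
        # ceiling, no DP needed
        _encode(read)
        return AlignedRead(
            read_id=read_id,
            read_seq=read,
            segments=(Segment("=", len(read), 0, 0),),
            score=float(len(read)) * MATCH,
        )
    ref_codes = _encode(ref_seq)
    candidates = []
    orients = {"forward": [False], "reverse": [True], "auto": [False, True]}[orientation]
    for rc in orients:
        seq = revcomp(read) if rc else read
        codes = _encode(seq)
        M, X, Y, pM, pX, pY = _fill(codes, ref_codes, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
        ops, start, score = _traceback(seq, ref_seq, M, X, Y, pM, pX, pY)
        candidates.append((score, rc, seq, ops, start))
    score, rc, seq, ops, start = max(candidates, key=lambda c: (c[0], not c[1]))
    aligned = AlignedRead(
        read_id=read_id,
        read_seq=seq,
        segments=_segments_from_ops(ops, start),
        score=score,
        reverse_complemented=rc,
    )
    return left_align_indels(aligned, ref_seq)


# -- left alignment ----------------------------------------------------------


def alignment_columns(a: AlignedRead, ref_seq: str) -> list[tuple[str, str]]:
    """Per-column (ref char | '-', read char | '-') representation."""
    cols: list[tuple[str, str]] = []
    for s in a.segments:
        for k in range(s.length):
            if s.op in "=X":
                cols.append((ref_seq[s.ref_start + k], a.read_seq[s.read_start + k]))
            elif s.op == "I":
                cols.append(("-", a.read_seq[s.read_start + k]))
            else:
                cols.append((ref_seq[s.ref_start + k], "-"))
    return cols


def _columns_to_segments(cols: list[tuple[str, str]], ref_start: int) -> tuple[Segment, ...]:
    ops = []
    for rc, qc in cols:
        if rc == "-":
            ops.append("I")
        elif qc == "-":
            ops.append("D")
        else:
            ops.append("=" if rc == qc and rc != "N" else "X")
    return _segments_from_ops(ops, ref_start)


def left_align_indels(a: AlignedRead, ref: AmpliconReference | str) -> AlignedRead:
    """Shift every indel to its minimal reference coordinate among
    sequence-equivalent placements.  Idempotent; only shifts across matching
    context, so the reconstructed read is unchanged."""
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    cols = alignment_columns(a, ref_seq)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(cols):
            rc, qc = cols[i]
            if rc == "-" or qc == "-":
                # locate the full gap run [i, j)
                is_ins = rc == "-"
                j = i
                if is_ins:
                    while j < len(cols) and cols[j][0] == "-":
                        j += 1
                else:
                    while j < len(cols) and cols[j][1] == "-" and cols[j][0] != "-":
                        j += 1
                if i > 0:
                    prc, pqc = cols[i - 1]
                    if prc != "-" and pqc != "-" and prc == pqc:
                        if is_ins:
                            # inserted run read chars; last must equal prc
                            if cols[j - 1][1] == prc:
                                run = [cols[k][1] for k in range(i, j)]
                                new_run = [pqc] + run[:-1]
                                for k, ch in enumerate(new_run):
                                    cols[i - 1 + k] = ("-", ch)
                                cols[j - 1] = (prc, run[-1])
                                changed = True
                                i = max(i - 2, 0)
                                continue
                        else:
                            if cols[j - 1][0] == prc:
                                run = [cols[k][0] for k in range(i, j)]
                                new_run = [prc] + run[:-1]
                                for k, ch in enumerate(new_run):
                                    cols[i - 1 + k] = (ch, "-")
                                # the read base pqc now aligns to run[-1] == prc
                                cols[j - 1] = (run[-1], pqc)
                                changed = True
                                i = max(i - 2, 0)
                                continue
                i = j
            else:
                i += 1
    return AlignedRead(
        read_id=a.read_id,
        read_seq=a.read_seq,
        segments=_columns_to_segments(cols, a.ref_start),
        score=a.score,
        reverse_complemented=a.reverse_complemented,
    )


def reconstruct_read(a: AlignedRead, ref: AmpliconReference | str) -> str:
    """Apply the alignment's segments to the reference; must equal the read."""
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    out = []
    for s in a.segments:
        if s.op == "=":
            out.append(ref_seq[s.ref_start : s.ref_start + s.length])
        elif s.op in "XI":
            out.append(a.read_seq[s.read_start : s.read_start + s.length])
    return "".join(out)


def prefix_identity(
    a: AlignedRead,
    ref: AmpliconReference,
    prefix_len: int = 20,
    min_frac: float = 0.75,
) -> bool:
    """Read filter: at least ``min_frac`` of the first ``prefix_len``
    reference bases must be covered by exact matches.  Mismatched,
    deletion-covered and unaligned prefix positions all count as unmatched."""
    needed = math.ceil(min_frac * prefix_len - 1e-9)
    matched = 0
    for s in a.segments:
        if s.op != "=":
            continue
        lo = max(s.ref_start, 0)
        hi = min(s.ref_start + s.length, prefix_len)
        if hi > lo:
            matched += hi - lo
    return matched >= needed
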