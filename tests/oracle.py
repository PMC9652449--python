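"""Independent alignment-score oracle: exhaustive recursion with memoisation
over (read consumed, ref consumed, previous op), scoring alignments directly
from their op sequences.  Shares no code with the production DP."""

from functools import lru_cache

NEG = float("-inf")


def oracle_score(
    read: str,
    ref: str,
    match: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Best semi-global score: read fully consumed, reference end-gaps free,
    affine gaps (a gap of length L costs -(gap_open + L*gap_extend))."""
    n, m = len(read), len(ref)

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int, prev: str) -> float:
        if i == n:
            return 0.0  # trailing reference overhang is free
        out = NEG
        if j < m:
            s = match if read[i] == ref[j] and read[i] != "N" else mismatch
            out = max(out, s + best_from(i + 1, j + 1, "M"))
            cost = gap_extend if prev == "D" else gap_open + gap_extend
            out = max(out, cost + best_from(i, j + 1, "D"))
        cost = gap_extend if prev == "I" else gap_open + gap_extend
        out = max(out, cost + best_from(i + 1, j, "I"))
        return out

    result = max(best_from(0, j, "-") for j in range(m + 1))
    best_from.cache_clear()
    return result


def enumerate_score(read: str, ref: str, **kw) -> float:
    """True brute force for tiny inputs: enumerate every op sequence."""
    match = kw.get("match", 1.0)
    mismatch = kw.get("mismatch", -4.0)
    gap_open = kw.get("gap_open", -6.0)
    gap_extend = kw.get("gap_extend", -1.0)
    n, m = len(read), len(ref)
    best = [NEG]

    def walk(i, j, prev, score):
        if i == n:
            best[0] = max(best[0], score)  # rest of ref free
            return
        if j < m:
            s = match if read[i] == ref[j] else mismatch
            walk(i + 1, j + 1, "M", score + s)
            c = gap_extend if prev == "D" else gap_open + gap_extend
            walk(i, j + 1, "D", score + c)
        c = gap_extend if prev == "I" else gap_open + gap_extend
        walk(i + 1, j, "I", score + c)

    for j0 in range(m + 1):
        walk(0, j0, "-", 0.0)
    return best[0]
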