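"""Affine-gap local alignment (Smith-Waterman) and gapless diagonal scoring.

The row recurrence is vectorised with numpy using a prefix-max formulation
of the horizontal-gap state, which is exact whenever the gap-open penalty
is at least as costly as gap-extend (asserted): chaining two adjacent
horizontal gaps can then never beat one longer gap, so the gap state can
be derived from the pre-gap row values in a single accumulate pass.

Conventions: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(both negative); alignment coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = np.iinfo(np.int32).min // 4


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be at least as penalising as gap_extend")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    aligned_pairs: int  # matched + mismatched columns (excludes gaps)


def sw_align(query: np.ndarray, ref: np.ndarray, scoring: Scoring = Scoring()) -> LocalAlignment:
    """Best local alignment of ``query`` against ``ref`` (base-code arrays)."""
    n, m = len(query), len(ref)
    if n == 0 or m == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0)
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    H0 = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    cols = np.arange(m + 1, dtype=np.int64)

    for i in range(1, n + 1):
        s = np.where(ref == query[i - 1], ma, mi).astype(np.int32)
        F[i] = np.maximum(H[i - 1] + go, F[i - 1] + ge)
        diag = H[i - 1, :-1] + s
        H0[i, 1:] = np.maximum.reduce([np.zeros(m, np.int32), diag, F[i, 1:]])
        # horizontal gaps: E[j] = max_{k<j} H0[k] + go + (j-1-k)*ge
        a = H0[i].astype(np.int64) - cols * ge
        pref = np.maximum.accumulate(a)
        E[i, 1:] = (pref[:-1] + go + (cols[1:] - 1) * ge).astype(np.int32)
        H[i] = np.maximum(H0[i], E[i])

    flat = int(np.argmax(H))
    imax, jmax = divmod(flat, m + 1)
    score = int(H[imax, jmax])
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0)
    qs, rs_, aligned = _traceback(query, ref, H, H0, E, F, scoring, imax, jmax)
    return LocalAlignment(score, qs, imax, rs_, jmax, aligned)


def _traceback(query, ref, H, H0, E, F, scoring, i, j):
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    aligned = 0
    state = "H"
    while True:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            state = "H0" if v == H0[i, j] else "E"
        elif state == "H0":
            v = H0[i, j]
            if v == 0:
                break
            s = ma if query[i - 1] == ref[j - 1] else mi
            if v == H[i - 1, j - 1] + s:
                aligned += 1
                i -= 1
                j -= 1
                state = "H"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == H0[i, j - 1] + go:
                j -= 1
                state = "H0"
            else:
                j -= 1  # extend: E[i, j] == E[i, j-1] + ge
        else:  # F
            if F[i, j] == H[i - 1, j] + go:
                i -= 1
                state = "H"
            else:
                i -= 1  # extend: F[i, j] == F[i-1, j] + ge
    return i, j, aligned


@dataclass(frozen=True)
class GaplessHit:
    score: int
    query_start: int
    query_end: int
    ref_start: int


def best_gapless(
    query: np.ndarray, ref: np.ndarray, diag: int, scoring: Scoring = Scoring()
) -> GaplessHit | None:
    """Best-scoring gapless segment along one diagonal (Kadane).

    ``diag`` is ref_pos - query_pos.  Returns None when the diagonal does
    not intersect the matrix or scores nowhere positive.
    """
    n, m = len(query), len(ref)
    lo = max(0, -diag)
    hi = min(n, m - diag)
    if hi <= lo:
        return None
    seg = np.where(query[lo:hi] == ref[lo + diag : hi + diag], scoring.match, scoring.mismatch)
    cs = np.concatenate(([0], np.cumsum(seg)))
    runmin = np.minimum.accumulate(cs)
    gains = cs[1:] - runmin[:-1]
    end = int(np.argmax(gains))
    score = int(gains[end])
    if score <= 0:
        return None
    start = int(np.argmax(cs[: end + 1] == runmin[end]))
    return GaplessHit(
        score=score,
        query_start=lo + start,
        query_end=lo + end + 1,
        ref_start=lo + start + diag,
    )
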