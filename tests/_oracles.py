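"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and the
textbook recurrences (Gotoh three-state local alignment, exhaustive
suffix/window scans) so it shares no code path with the package.
"""

NEG = float("-inf")


def sw_score_oracle(query: str, ref: str, match=1, mismatch=-1, go=-2, ge=-1) -> int:
    """Best local-alignment score; gap of length L costs go + (L-1)*ge."""
    n, m = len(query), len(ref)
    best = 0
    h_prev = [0] * (m + 1)
    e_prev = None  # E is per-cell within a row
    f_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        f_cur = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] + go, e + ge)
            f_cur[j] = max(h_prev[j] + go, f_prev[j] + ge)
            s = match if query[i - 1] == ref[j - 1] else mismatch
            h_cur[j] = max(0, h_prev[j - 1] + s, e, f_cur[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, f_prev = h_cur, f_cur
    return best


_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def assign_oracle(seq1: str, seq2: str, panel, min_score_frac=0.6, **scoring) -> str | None:
    """Exhaustive paired-end assignment: best sum-of-mates Smith-Waterman
    score over all references and both orientation combos, lexicographic
    accession tie-break, None below the score-fraction threshold."""
    best_score, best_acc = NEG, None
    max_attainable = len(seq1) + len(seq2)
    for rec in sorted(panel, key=lambda r: r.accession):
        for ma, mb in ((seq1, _rc(seq2)), (_rc(seq1), seq2)):
            score = sw_score_oracle(ma, rec.sequence, **scoring) + sw_score_oracle(
                mb, rec.sequence, **scoring
            )
            if score > best_score:
                best_score, best_acc = score, rec.accession
    if best_score < min_score_frac * max_attainable:
        return None
    return best_acc


def adapter_cut_oracle(read: str, adapters, k: int) -> int:
    """Leftmost position whose k-mer equals any adapter k-mer (else len)."""
    kmers = {a[i : i + k] for a in adapters for i in range(len(a) - k + 1)}
    for pos in range(len(read) - k + 1):
        if read[pos : pos + k] in kmers:
            return pos
    return len(read)


def mott_cut_oracle(quals: str, threshold: int) -> int:
    """Exhaustive scan over all right-end cut points: maximise the removed
    suffix penalty sum(threshold - Q), ties keep the longer read, no trim
    unless the best penalty is positive."""
    q = [ord(c) - 33 for c in quals]
    n = len(q)
    best_cut, best_score = n, 0
    for cut in range(n, -1, -1):
        score = sum(threshold - qi for qi in q[cut:])
        if score > best_score:
            best_score, best_cut = score, cut
    return best_cut
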