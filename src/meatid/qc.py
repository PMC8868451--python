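"""Pre-alignment read QC: adapter trimming, quality trimming, length filter.

Semantics mirror common amplicon practice with k-mer right-trimming
(``ktrim=r``-style): the leftmost read position whose k-mer exactly matches
any adapter k-mer triggers removal of everything from that position to the
3' end.  Quality trimming is the Mott-style cumulative algorithm applied to
the right end only.  Pairs are always kept in sync: if either mate falls
below the length floor the whole pair is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import UNIVERSAL_16S
from .seq import revcomp
from .simulate import ReadSet

#: Adapter sequences as they appear by read-through: the reverse complement
#: of the Nextera tails of the default primer pair.
DEFAULT_ADAPTERS: tuple[str, ...] = (
    revcomp(UNIVERSAL_16S.reverse_tail).upper(),
    revcomp(UNIVERSAL_16S.forward_tail).upper(),
)


@dataclass(frozen=True)
class QCParams:
    adapter_kmer: int = 21
    min_kmer_hits: int = 1
    trim_quality: int = 20
    min_length: int = 50
    adapters: tuple[str, ...] = DEFAULT_ADAPTERS

    def __post_init__(self) -> None:
        if self.adapter_kmer < 1 or self.min_kmer_hits < 1:
            raise ValueError("adapter_kmer and min_kmer_hits must be >= 1")
        if self.trim_quality < 0 or self.min_length < 0:
            raise ValueError("thresholds must be non-negative")
        if self.adapters and self.adapter_kmer > min(len(a) for a in self.adapters):
            raise ValueError("adapter_kmer longer than the shortest adapter")


@dataclass(frozen=True)
class QCReport:
    pairs_before: int
    pairs_after: int

    @property
    def fraction_retained(self) -> float:
        return self.pairs_after / self.pairs_before if self.pairs_before else 1.0


def _adapter_kmers(params: QCParams) -> list[str]:
    kmers: list[str] = []
    seen: set[str] = set()
    for adapter in params.adapters:
        a = adapter.upper()
        for i in range(len(a) - params.adapter_kmer + 1):
            km = a[i : i + params.adapter_kmer]
            if km not in seen:
                seen.add(km)
                kmers.append(km)
    return kmers


def _adapter_cut(seq: str, kmers: list[str], min_hits: int) -> int:
    """Index from which to trim, or len(seq) when no adapter evidence."""
    if min_hits == 1:
        best = len(seq)
        for km in kmers:
            pos = seq.find(km)
            if pos != -1 and pos < best:
                best = pos
        return best
    hits: set[int] = set()
    for km in kmers:
        pos = seq.find(km)
        while pos != -1:
            hits.add(pos)
            pos = seq.find(km, pos + 1)
    if len(hits) >= min_hits:
        return min(hits)
    return len(seq)


def trim_adapters(readset: ReadSet, params: QCParams = QCParams()) -> ReadSet:
    if not params.adapters:
        raise ValueError("adapters must be non-empty")
    kmers = _adapter_kmers(params)
    out = ReadSet(readset.sample_id, list(readset.ids), truth=list(readset.truth))
    for seqs, quals, oseqs, oquals in (
        (readset.seq1, readset.qual1, out.seq1, out.qual1),
        (readset.seq2, readset.qual2, out.seq2, out.qual2),
    ):
        for seq, qual in zip(seqs, quals):
            cut = _adapter_cut(seq, kmers, params.min_kmer_hits)
            oseqs.append(seq[:cut])
            oquals.append(qual[:cut])
    return out


def _mott_cuts(quals: list[str], threshold: int) -> np.ndarray:
    """Right-end cut index per read maximising the trimmed suffix penalty.

    The retained read is ``read[:cut]`` where ``cut`` maximises
    sum(threshold - Q_i) over the removed suffix; score ties keep the
    longer read, and a read is only trimmed when the best score is > 0.
    """
    n = len(quals)
    lens = np.array([len(q) for q in quals], dtype=int)
    lmax = int(lens.max(initial=0))
    if lmax == 0:
        return lens
    score = np.zeros((n, lmax), dtype=np.int64)
    for i, q in enumerate(quals):
        if q:
            score[i, : len(q)] = threshold - (
                np.frombuffer(q.encode(), dtype=np.uint8).astype(np.int64) - 33
            )
    # V[i, j] = penalty removed when cutting at j (suffix sums; V[i, len]=0)
    v = np.zeros((n, lmax + 1), dtype=np.int64)
    v[:, :-1] = np.flip(np.cumsum(np.flip(score, axis=1), axis=1), axis=1)
    invalid = np.arange(lmax + 1)[None, :] > lens[:, None]
    v[invalid] = np.iinfo(np.int64).min
    # argmax with ties resolved to the largest j (longer read)
    flipped = np.flip(v, axis=1)
    cuts = lmax - np.argmax(flipped, axis=1)
    best = v[np.arange(n), cuts]
    return np.where(best > 0, cuts, lens)


def quality_trim(readset: ReadSet, params: QCParams = QCParams()) -> ReadSet:
    out = ReadSet(readset.sample_id, list(readset.ids), truth=list(readset.truth))
    for seqs, quals, oseqs, oquals in (
        (readset.seq1, readset.qual1, out.seq1, out.qual1),
        (readset.seq2, readset.qual2, out.seq2, out.qual2),
    ):
        if not seqs:
            continue
        cuts = _mott_cuts(quals, params.trim_quality)
        for (seq, qual), cut in zip(zip(seqs, quals), cuts):
            oseqs.append(seq[: int(cut)])
            oquals.append(qual[: int(cut)])
    return out


def length_filter(readset: ReadSet, params: QCParams = QCParams()) -> ReadSet:
    keep = [
        i
        for i in range(readset.n_pairs)
        if len(readset.seq1[i]) >= params.min_length
        and len(readset.seq2[i]) >= params.min_length
    ]
    return readset.subset(keep)


def qc_report(before: ReadSet, after: ReadSet) -> QCReport:
    """Summarise pair retention; ``after`` must be an ordered subset of ``before``."""
    it = iter(before.ids)
    for rid in after.ids:
        for other in it:
            if other == rid:
                break
        else:
            raise ValueError(f"read {rid!r} in the filtered set is not in the input set")
    return QCReport(pairs_before=before.n_pairs, pairs_after=after.n_pairs)


def apply_qc(readset: ReadSet, params: QCParams = QCParams()) -> tuple[ReadSet, QCReport]:
    """Full chain: adapter trim -> quality trim -> length filter."""
    filtered = length_filter(quality_trim(trim_adapters(readset, params), params), params)
    return filtered, qc_report(readset, filtered)
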