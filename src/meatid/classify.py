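"""Read-to-reference assignment, coverage accumulation and composition.

Each read pair is assigned to the single best-scoring reference, scoring
the two mates jointly (sum of per-mate local-alignment scores) and
requiring both mates to hit the same reference in a proper forward/reverse
orientation.  Pairs below ``min_score_frac`` of the maximum attainable
score are counted as unassigned, never silently dropped.  Ties are broken
deterministically towards the lexicographically smallest accession.

The default mode shortlists references with a k-mer index (k = 15) and
scores candidates by gapless diagonal extension, falling back to full
affine Smith-Waterman only when no full-length perfect hit exists; a
full-length perfect gapless hit already attains the maximum local-alignment
score, so the shortcut is exact with respect to the Smith-Waterman
objective.  ``mode="exhaustive"`` aligns every read against every
reference with full Smith-Waterman and is intended for small instances
and oracle checks.

The per-sample composition statistic is the percentage average fold:
avg_fold(r) = aligned_bases(r) / length(r) per reference, aggregated to
genus and normalised to sum to 100 across genera with non-zero fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import GaplessHit, LocalAlignment, Scoring, best_gapless, sw_align
from .panel import ReferencePanel
from .simulate import ReadSet

_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    accession: str
    score: int
    aligned_bases: int
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class ClassificationResult:
    hits: list[AlignmentHit]
    assigned_pairs: int
    unassigned_pairs: int

    @property
    def total_pairs(self) -> int:
        return self.assigned_pairs + self.unassigned_pairs


class KmerIndex:
    """Exact k-mer -> (reference, position) lookup over the panel."""

    def __init__(self, panel: ReferencePanel, k: int = 15):
        self.k = k
        self.ref_codes = [_encode(rec.sequence) for rec in panel]
        self.accessions = panel.accessions
        self.lookup: dict[bytes, list[tuple[int, int]]] = {}
        for ridx, codes in enumerate(self.ref_codes):
            buf = codes.tobytes()
            for pos in range(len(codes) - k + 1):
                self.lookup.setdefault(buf[pos : pos + k], []).append((ridx, pos))

    def candidates(self, codes: np.ndarray) -> dict[int, set[int]]:
        """Candidate diagonals per reference from tiled seed k-mers."""
        k = self.k
        n = len(codes)
        if n < k:
            return {}
        buf = codes.tobytes()
        offsets = list(range(0, n - k + 1, k))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        out: dict[int, set[int]] = {}
        for off in offsets:
            for ridx, pos in self.lookup.get(buf[off : off + k], ()):
                out.setdefault(ridx, set()).add(pos - off)
        return out


@dataclass
class _MateScore:
    score: int
    ref_start: int
    ref_end: int
    aligned: int


def _gapless_mate(
    codes: np.ndarray, ridx: int, diags: set[int], index: KmerIndex, scoring: Scoring
) -> tuple[_MateScore | None, bool]:
    """Best gapless score over the seeded diagonals; flags full-length perfect.

    A full-length perfect gapless hit attains the Smith-Waterman maximum for
    the mate, and conversely an exact full-length occurrence anywhere on the
    reference implies every tiled seed k-mer hits its diagonal — so when no
    seeded diagonal is perfect, no perfect occurrence exists at all.
    """
    ref = index.ref_codes[ridx]
    perfect = len(codes) * scoring.match
    best: GaplessHit | None = None
    for d in sorted(diags):
        hit = best_gapless(codes, ref, d, scoring)
        if hit is None:
            continue
        if best is None or hit.score > best.score:
            best = hit
            if hit.score == perfect:
                break
    if best is None:
        return None, False
    if best.score == perfect:
        return (
            _MateScore(best.score, best.ref_start, best.ref_start + len(codes), len(codes)),
            True,
        )
    return (
        _MateScore(
            best.score, best.ref_start,
            best.ref_start + (best.query_end - best.query_start),
            best.query_end - best.query_start,
        ),
        False,
    )


def _sw_mate(codes, ridx, index, scoring, sw_cache) -> _MateScore | None:
    key = (codes.tobytes(), ridx)
    if key not in sw_cache:
        sw_cache[key] = sw_align(codes, index.ref_codes[ridx], scoring)
    aln: LocalAlignment = sw_cache[key]
    if aln.score <= 0:
        return None
    return _MateScore(aln.score, aln.ref_start, aln.ref_end, aln.aligned_pairs)


def align_reads(
    readset: ReadSet,
    panel: ReferencePanel,
    scoring: Scoring = Scoring(),
    min_score_frac: float = 0.6,
    mode: str = "seeded",
    k: int = 15,
    index: KmerIndex | None = None,
) -> ClassificationResult:
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if mode not in ("seeded", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if index is None:
        index = KmerIndex(panel, k)
    n_refs = len(index.ref_codes)
    rank = np.empty(n_refs, dtype=int)  # lexicographic tie-break order
    rank[np.argsort(index.accessions)] = np.arange(n_refs)

    hits: list[AlignmentHit] = []
    assigned = 0
    unassigned = 0
    for i in range(readset.n_pairs):
        c1 = _encode(readset.seq1[i])
        c2 = _encode(readset.seq2[i])
        if len(c1) == 0 or len(c2) == 0:
            unassigned += 1
            continue
        max_attainable = (len(c1) + len(c2)) * scoring.match
        threshold = min_score_frac * max_attainable
        best = None  # (score, -acc_rank, -orient, m1: _MateScore, m2, ridx)
        sw_cache: dict = {}
        for orient, (ma, mb) in enumerate(((c1, _rc_codes(c2)), (_rc_codes(c1), c2))):
            if mode == "exhaustive":
                shared: dict[int, tuple[set[int], set[int]]] = {
                    r: (set(), set()) for r in range(n_refs)
                }
            else:
                ca, cb = index.candidates(ma), index.candidates(mb)
                shared = {r: (ca[r], cb[r]) for r in ca if r in cb}
            # fast path: first reference (in accession order) where both
            # mates have a full-length perfect gapless hit wins outright —
            # no other candidate can score higher, and an equal-scoring one
            # would lose the lexicographic tie-break.
            ordered = sorted(shared, key=lambda r: rank[r])
            gapless: dict[int, tuple[_MateScore | None, _MateScore | None]] = {}
            winner = None
            if mode == "seeded":
                for ridx in ordered:
                    da, db = shared[ridx]
                    sa, pa = _gapless_mate(ma, ridx, da, index, scoring)
                    sb, pb = _gapless_mate(mb, ridx, db, index, scoring)
                    gapless[ridx] = (sa, sb)
                    if pa and pb:
                        winner = (max_attainable, -int(rank[ridx]), -orient, sa, sb, ridx)
                        break
            if winner is not None:
                best = winner
                break  # the opposite orientation could at most tie and lose
            for ridx in ordered:
                if mode == "exhaustive":
                    sa = _sw_mate(ma, ridx, index, scoring, sw_cache)
                    sb = _sw_mate(mb, ridx, index, scoring, sw_cache)
                else:
                    ga, gb = gapless[ridx]
                    sa = ga if (ga and ga.score == len(ma) * scoring.match) \
                        else _sw_mate(ma, ridx, index, scoring, sw_cache)
                    sb = gb if (gb and gb.score == len(mb) * scoring.match) \
                        else _sw_mate(mb, ridx, index, scoring, sw_cache)
                if sa is None or sb is None:
                    continue
                cand = (sa.score + sb.score, -int(rank[ridx]), -orient, sa, sb, ridx)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None or best[0] < threshold:
            unassigned += 1
            continue
        assigned += 1
        _score, _rank, neg_orient, sa, sb, ridx = best
        acc = index.accessions[ridx]
        strands = ("+", "-") if neg_orient == 0 else ("-", "+")
        for mate, ms, strand in ((1, sa, strands[0]), (2, sb, strands[1])):
            hits.append(
                AlignmentHit(
                    read_id=f"{readset.ids[i]}/{mate}", accession=acc,
                    score=ms.score, aligned_bases=ms.aligned,
                    ref_start=ms.ref_start, ref_end=ms.ref_end, strand=strand,
                )
            )
    return ClassificationResult(hits, assigned, unassigned)


def _sw_mate(codes, ridx, index, scoring, sw_cache) -> _MateScore | None:
    key = (codes.tobytes(), ridx)
    if key not in sw_cache:
        sw_cache[key] = sw_align(codes, index.ref_codes[ridx], scoring)
    aln: LocalAlignment = sw_cache[key]
    if aln.score <= 0:
        return None
    return _MateScore(aln.score, aln.ref_start, aln.ref_end, aln.aligned_pairs)


# ---------------------------------------------------------------------------
# Coverage and composition

@dataclass(frozen=True)
class CoverageStats:
    accession: str
    ref_length: int
    total_aligned_bases: int
    covered_positions: int

    @property
    def avg_fold(self) -> float:
        return self.total_aligned_bases / self.ref_length

    @property
    def pct_covered(self) -> float:
        return 100.0 * self.covered_positions / self.ref_length


def compute_coverage(hits: list[AlignmentHit], panel: ReferencePanel) -> list[CoverageStats]:
    """Per-reference aligned-base totals and breadth of coverage.

    ``avg_fold`` divides aligned bases by the full reference length;
    ``covered_positions`` is the union of hit intervals.
    """
    by_acc: dict[str, list[AlignmentHit]] = {acc: [] for acc in panel.accessions}
    for h in hits:
        by_acc[h.accession].append(h)
    out = []
    for rec in panel:
        hs = by_acc[rec.accession]
        total = sum(h.aligned_bases for h in hs)
        if hs:
            diff = np.zeros(rec.length + 1, dtype=np.int64)
            starts = np.fromiter((h.ref_start for h in hs), dtype=np.int64)
            ends = np.fromiter((h.ref_end for h in hs), dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
            covered = int(np.count_nonzero(np.cumsum(diff[:-1]) > 0))
        else:
            covered = 0
        out.append(CoverageStats(rec.accession, rec.length, total, covered))
    return out


@dataclass
class CompositionProfile:
    """Per-genus percentage average fold; empty entries flag a failed sample."""

    sample_id: str
    entries: dict[str, float] = field(default_factory=dict)
    unassigned_reads: int = 0

    @property
    def failed(self) -> bool:
        return not self.entries

    @property
    def top(self) -> tuple[str, float] | None:
        if self.failed:
            return None
        genus = max(self.entries, key=lambda g: (self.entries[g], g))
        return genus, self.entries[genus]


def composition(
    coverage: list[CoverageStats],
    genus_map: dict[str, str],
    sample_id: str = "",
    unassigned_reads: int = 0,
) -> CompositionProfile:
    """Genus-level percentage average fold (zero-fold genera omitted)."""
    folds: dict[str, float] = {}
    for cov in coverage:
        if cov.accession not in genus_map:
            raise KeyError(f"accession {cov.accession!r} missing from taxonomy")
        if cov.avg_fold > 0:
            genus = genus_map[cov.accession]
            folds[genus] = folds.get(genus, 0.0) + cov.avg_fold
    total = sum(folds.values())
    entries = {g: 100.0 * f / total for g, f in folds.items()} if total > 0 else {}
    return CompositionProfile(sample_id, entries, unassigned_reads)


def coverage_table(coverage: list[CoverageStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": c.accession, "length": c.ref_length,
                "total_aligned_bases": c.total_aligned_bases,
                "avg_fold": c.avg_fold, "pct_covered": c.pct_covered,
            }
            for c in coverage
        ]
    )


def composition_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for genus, pct in sorted(p.entries.items()):
            rows.append({"sample_id": p.sample_id, "genus": genus, "pct_avg_fold": pct})
    return pd.DataFrame(rows, columns=["sample_id", "genus", "pct_avg_fold"])
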