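"""Read assignment vs exhaustive alignment oracles; coverage and composition."""

import numpy as np
import pytest

from meatid.align import best_gapless, sw_align
from meatid.classify import AlignmentHit, align_reads, composition, compute_coverage
from meatid.qc import apply_qc
from meatid.simulate import MixtureDesign, ReadSet, simulate_sample

from _oracles import assign_oracle, sw_score_oracle

_LUT = {c: i for i, c in enumerate("ACGT")}


def _codes(seq):
    return np.array([_LUT[c] for c in seq], dtype=np.uint8)


def _random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestSmithWaterman:
    def test_scores_match_textbook_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            q = _random_seq(rng, int(rng.integers(5, 40)))
            r = _random_seq(rng, int(rng.integers(5, 60)))
            assert sw_align(_codes(q), _codes(r)).score == sw_score_oracle(q, r)

    def test_scores_match_oracle_on_mutated_substrings(self):
        # near-identical segments exercise the gap states
        rng = np.random.default_rng(6)
        for _ in range(15):
            r = _random_seq(rng, 120)
            start = int(rng.integers(0, 60))
            q = list(r[start : start + 50])
            for _e in range(int(rng.integers(0, 5))):
                pos = int(rng.integers(0, len(q)))
                op = rng.integers(0, 3)
                if op == 0:
                    q[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif op == 1 and len(q) > 2:
                    del q[pos]
                else:
                    q.insert(pos, "ACGT"[int(rng.integers(0, 4))])
            qs = "".join(q)
            assert sw_align(_codes(qs), _codes(r)).score == sw_score_oracle(qs, r)

    def test_exact_substring_scores_full_length_with_coordinates(self):
        rng = np.random.default_rng(7)
        r = _random_seq(rng, 200)
        q = r[40:90]
        aln = sw_align(_codes(q), _codes(r))
        assert aln.score == 50
        assert (aln.ref_start, aln.ref_end) == (40, 90)
        assert aln.aligned_pairs == 50

    def test_gapless_kadane_finds_best_segment(self):
        r = _codes("AAAATTTTGGGG")
        q = _codes("CCCCTTTTCCCC")  # only the TTTT block matches on diagonal 0
        hit = best_gapless(q, r, 0)
        assert hit.score == 4
        assert (hit.query_start, hit.query_end) == (4, 8)
        assert hit.ref_start == 4


class TestAssignment:
    def test_error_free_reads_assigned_to_truth(self, meat9):
        panel, amps = meat9
        design = MixtureDesign("a", (("beef", 0.5), ("kangaroo", 0.5)))
        rs = simulate_sample(panel, amps, design, 300, error_rate=0.0, seed=2)
        filtered, _ = apply_qc(rs)
        res = align_reads(filtered, panel)
        assert res.unassigned_pairs == 0
        by_read = {}
        for h in res.hits:
            by_read[h.read_id.rsplit("/", 1)[0]] = h.accession
        for rid, acc in zip(filtered.ids, filtered.truth):
            assert by_read[rid] == acc

    def test_seeded_equals_independent_oracle_on_small_instance(self, tiny_panel):
        panel, amps = tiny_panel
        rng = np.random.default_rng(11)
        reads = ReadSet("o")
        # 5 clean reads per spec-scale instance plus 7 mutated ones
        for i in range(12):
            acc = panel.accessions[i % 3]
            amp = next(a for a in amps if a.accession == acc)
            seq = amp.insert_seq
            if i >= 5:
                seq = list(seq)
                for _e in range(int(rng.integers(1, 4))):
                    pos = int(rng.integers(0, len(seq)))
                    seq[pos] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(seq)
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            reads.ids.append(f"o|{i}|{acc}")
            reads.seq1.append(seq)
            reads.seq2.append(rc)
            reads.qual1.append("I" * len(seq))
            reads.qual2.append("I" * len(rc))
            reads.truth.append(acc)
        seeded = align_reads(reads, panel, mode="seeded")
        exhaustive = align_reads(reads, panel, mode="exhaustive")

        def assignments(result):
            out = {rid: None for rid in reads.ids}
            for h in result.hits:
                out[h.read_id.rsplit("/", 1)[0]] = h.accession
            return out

        a_seeded, a_exh = assignments(seeded), assignments(exhaustive)
        assert a_seeded == a_exh
        for i, rid in enumerate(reads.ids):
            oracle = assign_oracle(reads.seq1[i], reads.seq2[i], panel)
            assert a_seeded[rid] == oracle

    def test_random_reads_stay_unassigned(self, meat9):
        panel, _ = meat9
        rng = np.random.default_rng(13)
        reads = ReadSet("junk")
        for i in range(10):
            s = _random_seq(rng, 180)
            reads.ids.append(f"junk|{i}|X")
            reads.seq1.append(s)
            reads.seq2.append(_random_seq(rng, 180))
            reads.qual1.append("I" * 180)
            reads.qual2.append("I" * 180)
            reads.truth.append(None)
        res = align_reads(reads, panel)
        assert res.assigned_pairs == 0
        assert res.unassigned_pairs == 10

    def test_pair_conservation(self, meat9):
        panel, amps = meat9
        design = MixtureDesign("c", (("pork", 0.7), ("beef", 0.3)))
        rs = simulate_sample(panel, amps, design, 200, error_rate=0.02, seed=4)
        filtered, _ = apply_qc(rs)
        res = align_reads(filtered, panel)
        assert res.assigned_pairs + res.unassigned_pairs == filtered.n_pairs
        assert len(res.hits) == 2 * res.assigned_pairs


class TestCoverage:
    def _hit(self, acc, start, end, read="r1"):
        return AlignmentHit(read, acc, end - start, end - start, start, end, "+")

    def test_fold_and_breadth_arithmetic(self, tiny_panel):
        panel, _ = tiny_panel
        acc = panel.accessions[0]
        ref_len = panel.get(acc).length
        cov = compute_coverage([self._hit(acc, 0, 100)], panel)
        stats = {c.accession: c for c in cov}
        assert stats[acc].avg_fold == pytest.approx(100 / ref_len)
        assert stats[acc].pct_covered == pytest.approx(100 * 100 / ref_len)

    def test_depth_differs_from_breadth(self, tiny_panel):
        panel, _ = tiny_panel
        acc = panel.accessions[0]
        ref_len = panel.get(acc).length
        cov = compute_coverage(
            [self._hit(acc, 0, 100, "a"), self._hit(acc, 0, 100, "b")], panel
        )
        stats = {c.accession: c for c in cov}
        assert stats[acc].avg_fold == pytest.approx(200 / ref_len)
        assert stats[acc].pct_covered == pytest.approx(100 * 100 / ref_len)

    def test_unhit_reference_has_zero_coverage(self, tiny_panel):
        panel, _ = tiny_panel
        cov = compute_coverage([], panel)
        assert all(c.avg_fold == 0 and c.pct_covered == 0 for c in cov)


class TestComposition:
    def test_single_genus_is_100(self, tiny_panel):
        panel, _ = tiny_panel
        acc = panel.accessions[0]
        cov = compute_coverage(
            [AlignmentHit("r/1", acc, 50, 50, 0, 50, "+")], panel
        )
        prof = composition(cov, panel.genus_map, "s")
        genus = panel.genus_map[acc]
        assert prof.entries == {genus: pytest.approx(100.0)}

    def test_three_to_one_fold_ratio_gives_75_25(self):
        from meatid.classify import CoverageStats

        cov = [
            CoverageStats("B1", 1000, 3000, 500),
            CoverageStats("S1", 1000, 1000, 400),
        ]
        prof = composition(cov, {"B1": "Bos", "S1": "Sus"}, "s")
        assert prof.entries["Bos"] == pytest.approx(75.0)
        assert prof.entries["Sus"] == pytest.approx(25.0)

    def test_scale_invariance_and_sum_to_100(self):
        from meatid.classify import CoverageStats

        base = [
            CoverageStats("A1", 1000, 1234, 10),
            CoverageStats("B1", 2000, 777, 10),
            CoverageStats("C1", 1500, 0, 0),
        ]
        scaled = [
            CoverageStats(c.accession, c.ref_length, 7 * c.total_aligned_bases, c.covered_positions)
            for c in base
        ]
        gmap = {"A1": "Ga", "B1": "Gb", "C1": "Gc"}
        p1 = composition(base, gmap, "s")
        p2 = composition(scaled, gmap, "s")
        assert p1.entries.keys() == p2.entries.keys() == {"Ga", "Gb"}
        for g in p1.entries:
            assert p1.entries[g] == pytest.approx(p2.entries[g])
        assert sum(p1.entries.values()) == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_coverage_flags_failed_sample(self):
        from meatid.classify import CoverageStats

        prof = composition([CoverageStats("A1", 1000, 0, 0)], {"A1": "Ga"}, "s")
        assert prof.failed and prof.entries == {} and prof.top is None

    def test_90_10_mixture_recovered_within_3_se(self, meat9):
        panel, amps = meat9
        design = MixtureDesign("m", (("pork", 0.9), ("beef", 0.1)))
        n = 10_000
        rs = simulate_sample(panel, amps, design, n, error_rate=0.0, seed=6)
        filtered, _ = apply_qc(rs)
        res = align_reads(filtered, panel)
        prof = composition(
            compute_coverage(res.hits, panel), panel.genus_map, "m", res.unassigned_pairs
        )
        se = 100 * np.sqrt(0.9 * 0.1 / n)
        assert prof.entries["Sus"] == pytest.approx(90.0, abs=3 * se)
        assert prof.entries["Bos"] == pytest.approx(10.0, abs=3 * se)
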