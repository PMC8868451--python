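"""Read simulator: mixture sampling, read structure, determinism, FASTQ I/O."""

import numpy as np
import pytest

from meatid.panel import UNIVERSAL_16S
from meatid.seq import revcomp
from meatid.simulate import (
    MixtureDesign, QualityProfile, build_paper_designs, read_fastq,
    simulate_sample, write_fastq,
)


class TestMixtureDesign:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MixtureDesign("bad", (("pork", 0.5), ("beef", 0.4)))
        with pytest.raises(ValueError, match="non-empty"):
            MixtureDesign("bad", ())

    def test_expected_genus_percentages(self):
        d = MixtureDesign("m", (("pork", 0.9), ("beef", 0.1)))
        assert d.expected_genus_pct == {"Sus": 90.0, "Bos": 10.0}


class TestSimulateSample:
    def test_truth_composition_tracks_design(self, meat9):
        panel, amps = meat9
        design = MixtureDesign("bk", (("beef", 0.5), ("kangaroo", 0.5)))
        rs = simulate_sample(panel, amps, design, 10_000, error_rate=0.0, seed=3)
        bos = panel.accessions_for_species("Bos taurus")[0]
        frac = np.mean([t == bos for t in rs.truth])
        # 3 multinomial SDs around 0.5 at n = 10,000
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_single_component_maps_all_reads_to_sus(self, meat9):
        panel, amps = meat9
        rs = simulate_sample(
            panel, amps, MixtureDesign("p", (("pork", 1.0),)), 50, seed=1
        )
        sus = panel.accessions_for_species("Sus scrofa")[0]
        assert set(rs.truth) == {sus}

    def test_deterministic_fastq_bytes(self, meat9, tmp_path):
        panel, amps = meat9
        design = MixtureDesign("d", (("pork", 0.9), ("beef", 0.1)))
        for tag in ("a", "b"):
            rs = simulate_sample(panel, amps, design, 300, error_rate=0.01, seed=42)
            write_fastq(rs, tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_error_free_reads_contain_insert_and_adapter(self, meat9):
        panel, amps = meat9
        amp_by_acc = {a.accession: a for a in amps}
        rs = simulate_sample(
            panel, amps, MixtureDesign("p", (("mutton", 1.0),)), 20,
            error_rate=0.0, seed=9,
        )
        tail1 = revcomp(UNIVERSAL_16S.reverse_tail).upper()
        tail2 = revcomp(UNIVERSAL_16S.forward_tail).upper()
        for s1, s2, acc in zip(rs.seq1, rs.seq2, rs.truth):
            insert = amp_by_acc[acc].insert_seq
            assert len(s1) == len(s2) == 300
            assert s1.startswith(insert + tail1)
            assert s2.startswith(revcomp(insert) + tail2)
            assert insert in panel.get(acc).sequence

    def test_truth_converges_to_design_at_large_n(self, meat9):
        panel, amps = meat9
        design = MixtureDesign("m", (("pork", 0.9), ("beef", 0.1)))
        n = 100_000
        rs = simulate_sample(panel, amps, design, n, error_rate=0.0, seed=17)
        sus = panel.accessions_for_species("Sus scrofa")[0]
        frac = np.mean([t == sus for t in rs.truth])
        assert abs(frac - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)

    def test_mean_quality_decays_along_cycles(self, meat9):
        panel, amps = meat9
        rs = simulate_sample(
            panel, amps, MixtureDesign("p", (("duck", 1.0),)), 500, seed=5
        )
        q = np.array([[ord(c) - 33 for c in qual] for qual in rs.qual1], dtype=float)
        mean = q.mean(axis=0)
        # binned means along the cycle axis must be non-increasing
        bins = mean.reshape(10, 30).mean(axis=1)
        assert np.all(np.diff(bins) <= 0)
        profile_means = QualityProfile().means(300)
        assert np.all(np.diff(profile_means) <= 0)

    def test_unknown_species_is_hard_error(self, meat9):
        panel, amps = meat9
        with pytest.raises(ValueError, match="no amplifiable reference"):
            simulate_sample(
                panel, amps, MixtureDesign("x", (("horse", 1.0),)), 10, seed=0
            )


class TestStudyDesigns:
    def test_pure_and_mixture_sample_counts(self):
        designs = build_paper_designs()
        pure = [d for d in designs if len(d.components) == 1]
        mixtures = [d for d in designs if len(d.components) == 2]
        assert len(pure) == 18  # 9 species x 2 replicates
        assert len(mixtures) == 39  # 13 mixture designs x 3 replicates
        assert len({d.sample_id for d in designs}) == 57

    def test_nine_to_one_designs_have_90_10_proportions(self):
        designs = [d for d in build_paper_designs() if d.sample_id.startswith("mix91")]
        assert len(designs) == 24
        for d in designs:
            assert sorted(p for _, p in d.components) == [0.1, 0.9]

    def test_pure_designs_are_labelled(self):
        for d in build_paper_designs():
            if len(d.components) == 1:
                assert d.declared_genus is not None
            else:
                assert d.label is None


class TestFastqIO:
    def test_roundtrip_sequences_and_qualities(self, meat9, tmp_path):
        panel, amps = meat9
        rs = simulate_sample(
            panel, amps, MixtureDesign("rt", (("beef", 1.0),)), 100,
            error_rate=0.01, seed=7,
        )
        write_fastq(rs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        back = read_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert back.ids == rs.ids
        assert back.seq1 == rs.seq1 and back.seq2 == rs.seq2
        assert back.qual1 == rs.qual1 and back.qual2 == rs.qual2
        assert back.truth == rs.truth

    def test_mate_count_mismatch_rejected(self, tmp_path):
        (tmp_path / "r1.fq").write_text("@a/1\nACGT\n+\nIIII\n@b/1\nACGT\n+\nIIII\n")
        (tmp_path / "r2.fq").write_text("@a/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="mate-count mismatch"):
            read_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")

    def test_malformed_record_reports_position(self, tmp_path):
        (tmp_path / "r1.fq").write_text("@a/1\nACGT\n+\nIIII\n@b/1\nACGT\n+\nII\n")
        (tmp_path / "r2.fq").write_text("@a/2\nACGT\n+\nIIII\n@b/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="record 2"):
            read_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")

    def test_empty_readset_roundtrip(self, tmp_path):
        from meatid.simulate import ReadSet

        write_fastq(ReadSet("empty"), tmp_path / "e1.fq", tmp_path / "e2.fq")
        back = read_fastq(tmp_path / "e1.fq", tmp_path / "e2.fq")
        assert back.n_pairs == 0
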