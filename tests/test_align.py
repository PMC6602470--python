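"""Read filtering and four-strand bisulfite alignment."""

import random

import numpy as np
import pytest

from _oracle import best_placements, semiglobal_score
from amplimeth.align import (
    FilterPolicy,
    ReadRecord,
    Strand,
    StrandAligner,
    UnmappedRead,
    align_reads,
    build_strand_references,
    filter_reads,
    read_fastq,
    trim_primer_pairs,
)
from amplimeth.simulate import emit_read_bases
from amplimeth.targets import TargetRegion, locate_primers


def rr(bases, read_id="r", qual=40, sample="s"):
    return ReadRecord(read_id, bases, [qual] * len(bases), sample)


def make_target(seq, tid="t"):
    return locate_primers(
        TargetRegion(target_id=tid, chrom=tid, start=0, end=len(seq), sequence=seq)
    )


class TestFilterReads:
    def test_length_window(self):
        reads = [rr("A" * n, f"r{n}") for n in (30, 50, 100)]
        policy = FilterPolicy(min_read_length=40, max_read_length=90)
        passed, stats = filter_reads(reads, policy)
        assert [r.read_id for r in passed] == ["r50"]
        assert stats.drop_too_short == 1 and stats.drop_too_long == 1
        assert stats.n_input == 3 and stats.n_passed == 1

    def test_mean_quality_gate(self):
        good = rr("ACGT" * 10, "good", qual=40)
        bad = rr("ACGT" * 10, "bad", qual=10)
        passed, stats = filter_reads([good, bad], FilterPolicy())
        assert [r.read_id for r in passed] == ["good"]
        assert stats.drop_low_quality == 1

    def test_empty_input(self):
        passed, stats = filter_reads([], FilterPolicy())
        assert passed == [] and stats.n_input == 0 and stats.n_passed == 0

    def test_inverted_length_window_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy(min_read_length=100, max_read_length=50)


class TestFastqIO:
    def test_round_trip_plain_and_gz(self, tmp_path):
        import gzip

        content = "@r1 extra\nACGT\n+\nIIII\n@r2\nTTTT\n+\n!!!!\n"
        plain = tmp_path / "a.fastq"
        plain.write_text(content)
        gz = tmp_path / "a.fastq.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(content)
        for path in (plain, gz):
            reads = read_fastq(path, sample_id="sampleA")
            assert [r.read_id for r in reads] == ["r1", "r2"]
            assert reads[0].qualities == [40, 40, 40, 40]
            assert reads[1].qualities == [0, 0, 0, 0]
            assert all(r.sample_id == "sampleA" for r in reads)

    def test_malformed_record_names_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nMISSING_PLUS\n")
        with pytest.raises(ValueError, match="record 1"):
            read_fastq(p)


class TestStrandReferences:
    def test_worked_example(self):
        refs = build_strand_references(make_target("AACGT"))
        assert refs[Strand.OT] == "AATGT"
        assert refs[Strand.OB] == "ATGTT"
        assert refs[Strand.CTOT] == "ACATT"
        assert refs[Strand.CTOB] == "AACAT"

    def test_no_c_or_g_collapses_to_s_and_r(self):
        t = make_target("ATTA")
        refs = build_strand_references(t)
        assert refs[Strand.OT] == refs[Strand.CTOB] == "ATTA"
        assert refs[Strand.OB] == refs[Strand.CTOT] == "TAAT"

    def test_pure_function(self):
        t = make_target("ACGTACGT")
        assert build_strand_references(t) == build_strand_references(t)


class TestAlignRead:
    @pytest.fixture
    def micro_engine(self):
        return StrandAligner([make_target("AACGT")], FilterPolicy())

    @pytest.mark.parametrize(
        "read,expected_strand",
        [("AATGT", Strand.OT), ("ATGTT", Strand.OB),
         ("ACATT", Strand.CTOT), ("AACAT", Strand.CTOB)],
    )
    def test_unmethylated_strand_reads_assigned(self, micro_engine, read,
                                                expected_strand):
        aln = micro_engine.align_read(rr(read))
        assert aln.strand is expected_strand
        assert aln.score == 5.0
        assert (aln.ref_start, aln.ref_end) == (0, 5)

    def test_fully_methylated_micro_read_is_ambiguous(self, micro_engine):
        # on a 5-mer whose only C is the CpG, the methylated OT and CTOB
        # products are the same sequence, so the placement genuinely ties
        result = micro_engine.align_read(rr("AACGT"))
        assert isinstance(result, UnmappedRead)
        assert result.reason == "ambiguous"

    def test_projection_restores_original_bases_forward(self, micro_engine):
        aln = micro_engine.align_read(rr("AATGT"))
        assert aln.pairs == [(i, b) for i, b in enumerate("AATGT")]

    def test_projection_reverse_complements_ob_read(self, micro_engine):
        aln = micro_engine.align_read(rr("ATGTT"))
        # revcomp("ATGTT") = "AACAT" laid out on forward coordinates
        assert aln.pairs == [(i, b) for i, b in enumerate("AACAT")]
        assert aln.quals == [40] * 5

    def test_overlong_read_reports_length(self, micro_engine):
        result = micro_engine.align_read(rr("A" * 10))
        assert isinstance(result, UnmappedRead) and result.reason == "length"

    def test_low_score_read_unmapped(self):
        engine = StrandAligner([make_target("AAAAAAAAAACCCCCCCCCC")])
        result = engine.align_read(rr("GTGTGTGTGTGTGTGTGTGT"))
        assert isinstance(result, UnmappedRead) and result.reason == "low-score"

    def test_score_symmetry_read_equals_variant(self):
        t = make_target("ACGTACGGTACCGTTACGTA")
        refs = build_strand_references(t)
        engine = StrandAligner([t])
        for strand, ref in refs.items():
            aln = engine.align_read(rr(ref))
            assert aln.score == len(ref), strand

    def test_deterministic_under_read_order(self):
        t1 = make_target("ACGTACGGTACCGTTACGTAACCGGTT", "t1")
        t2 = make_target("TTGACCAATTGGCCAACGGATCGATCG", "t2")
        rng = random.Random(5)
        reads = [
            rr("".join(rng.choice("ACGT") for _ in range(20)), f"r{i}")
            for i in range(30)
        ]
        a_fwd, u_fwd = align_reads(reads, [t1, t2])
        a_rev, u_rev = align_reads(list(reversed(reads)), [t1, t2])
        key = lambda a: (a.read_id, a.target_id, a.strand, a.score, tuple(a.pairs))
        assert sorted(map(key, a_fwd)) == sorted(map(key, a_rev))
        ukey = lambda u: (u.read_id, u.reason)
        assert sorted(map(ukey, u_fwd)) == sorted(map(ukey, u_rev))


class TestOracleEquivalence:
    def test_best_placement_matches_exhaustive_dp(self):
        """Reads <= 30 nt vs targets <= 60 nt: align_read's best
        (target, strand, score) equals the independent brute-force DP
        over all four variants, including its tie verdicts."""
        rng = random.Random(42)
        targets = []
        for i in range(2):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 60)))
            targets.append(make_target(seq, f"t{i + 1}"))
        seqs = {t.target_id: t.sequence for t in targets}
        engine = StrandAligner(targets, FilterPolicy())
        for k in range(60):
            src = targets[rng.randrange(2)]
            start = rng.randint(0, len(src) - 30)
            frag = list(src.sequence[start : start + 30])
            pos = rng.randrange(30)  # one random substitution
            frag[pos] = rng.choice("ACGT".replace(frag[pos], ""))
            read = "".join(frag)
            best, winners = best_placements(read, seqs)
            result = engine.align_read(rr(read, f"r{k}"))
            if len(winners) > 1:
                assert isinstance(result, UnmappedRead)
                assert result.reason == "ambiguous"
            elif best < 0.6 * len(read):
                assert isinstance(result, UnmappedRead)
            else:
                assert (result.target_id, result.strand.value) == winners[0]
                assert result.score == best

    def test_scores_match_dp_on_random_pairs(self):
        rng = random.Random(7)
        engine = StrandAligner([make_target("ACGT")])  # only for its aligner
        for _ in range(100):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 50)))
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            assert engine.aligner.score(ref, read) == semiglobal_score(ref, read)


class TestSimulatedStrandAssignment:
    def test_error_free_reads_recover_strand_and_target(self, clean_panel):
        spec, targets, reads, truth = clean_panel
        policy = FilterPolicy()
        alns, unmapped = align_reads(
            [r for recs in reads.values() for r in recs], targets, policy
        )
        assert not unmapped
        for aln in alns:
            info = truth.reads[aln.read_id]
            assert aln.target_id == info["target"]
            assert aln.strand.value == info["strand"]

    def test_all_four_strands_emitted(self, clean_panel):
        spec, targets, reads, truth = clean_panel
        strands = {info["strand"] for info in truth.reads.values()}
        assert strands == {"OT", "OB", "CTOT", "CTOB"}


class TestTrimPrimerPairs:
    def test_primer_positions_flagged(self):
        t = locate_primers(
            TargetRegion("t", "t", 0, 12, "AAACGTTTGGCC",
                         fwd_primer="AAA", rev_primer="GGCC")
        )
        engine = StrandAligner([t])
        rng = np.random.default_rng(0)
        bases = emit_read_bases(t, "U" * len(t.callable_cpgs()), Strand.OT, rng)
        aln = trim_primer_pairs(engine.align_read(rr(bases)), t)
        flagged = {pos for (pos, _), f in zip(aln.pairs, aln.primer_mask) if f}
        assert flagged == set(range(0, 3)) | set(range(8, 12))

    def test_alignment_inside_inner_span_unflagged(self):
        t = locate_primers(
            TargetRegion("t", "t", 0, 24, "AAAAAGGATCGATCGATTTTTTTT",
                         fwd_primer="AAAAA", rev_primer="AAAAAAAA")
        )
        assert t.inner_span == (5, 16)
        engine = StrandAligner([t], FilterPolicy(min_alignment_score_fraction=0.5))
        # OT-converted inner fragment (an unconverted one would tie OT/CTOB)
        aln = engine.align_read(rr("GGATTGATTGA"))
        aln = trim_primer_pairs(aln, t)
        assert not any(aln.primer_mask)
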