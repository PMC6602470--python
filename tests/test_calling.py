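"""Methylation calling, aggregation, conversion estimation, grouping."""

import numpy as np
import pandas as pd
import pytest

from amplimeth.align import Strand, StrandedAlignment, align_reads
from amplimeth.calling import (
    CallState,
    CpGCall,
    ConversionEstimate,
    aggregate_calls,
    call_read,
    estimate_conversion,
    group_summaries,
    noncpg_c_positions,
)
from amplimeth.targets import revcomp


def manual_alignment(target, strand, strand_read, read_id="r", sample="s",
                     qual=40):
    """Build the projected alignment for a full-length strand read without
    going through the aligner (strand is known by construction)."""
    projected = strand_read if strand in (Strand.OT, Strand.CTOB) \
        else revcomp(strand_read)
    pairs = list(enumerate(projected))
    return StrandedAlignment(
        read_id=read_id, sample_id=sample, target_id=target.target_id,
        strand=strand, ref_start=0, ref_end=len(projected),
        pairs=pairs, quals=[qual] * len(pairs), score=float(len(pairs)),
    )


UNMETH_READS = {
    Strand.OT: "AATGT",
    Strand.OB: "ATGTT",
    Strand.CTOT: "ACATT",
    Strand.CTOB: "AACAT",
}
METH_READS = {
    Strand.OT: "AACGT",
    Strand.OB: "ACGTT",
    Strand.CTOT: "ACGTT",
    Strand.CTOB: "AACGT",
}


class TestCallReadMicroExample:
    """S="AACGT" with its single CpG at forward position 2 (C) / 3 (G)."""

    @pytest.mark.parametrize("strand", list(Strand))
    def test_unmethylated_strand_reads_call_unmeth(self, micro_target, strand):
        aln = manual_alignment(micro_target, strand, UNMETH_READS[strand])
        (call,) = call_read(aln, micro_target)
        assert call.cpg_pos == 2
        assert call.state is CallState.UNMETH

    @pytest.mark.parametrize("strand", list(Strand))
    def test_methylated_strand_reads_call_meth(self, micro_target, strand):
        aln = manual_alignment(micro_target, strand, METH_READS[strand])
        (call,) = call_read(aln, micro_target)
        assert call.state is CallState.METH

    def test_n_at_evidence_position_is_ambiguous(self, micro_target):
        aln = manual_alignment(micro_target, Strand.OT, "AANGT")
        (call,) = call_read(aln, micro_target)
        assert call.state is CallState.AMBIGUOUS

    def test_low_base_quality_is_ambiguous(self, micro_target):
        aln = manual_alignment(micro_target, Strand.OT, "AACGT", qual=10)
        (call,) = call_read(aln, micro_target)
        assert call.state is CallState.AMBIGUOUS

    def test_strand_consistency_same_fragment_same_state(self, micro_target):
        # the same molecule observed on all four strands yields one verdict
        for reads, expected in (
            (UNMETH_READS, CallState.UNMETH),
            (METH_READS, CallState.METH),
        ):
            states = {
                call_read(
                    manual_alignment(micro_target, s, reads[s]), micro_target
                )[0].state
                for s in Strand
            }
            assert states == {expected}

    def test_uncovered_cpg_absent(self, micro_target):
        aln = StrandedAlignment(
            read_id="r", sample_id="s", target_id="micro", strand=Strand.OT,
            ref_start=0, ref_end=2, pairs=[(0, "A"), (1, "A")], quals=[40, 40],
            score=2.0,
        )
        assert call_read(aln, micro_target) == []


class TestAggregateCalls:
    def mk(self, state, i, sample="s1"):
        return CpGCall("t1", 2, f"r{i}", sample, state, Strand.OT)

    def test_fraction(self):
        calls = [self.mk(CallState.METH, i) for i in range(7)]
        calls += [self.mk(CallState.UNMETH, i + 7) for i in range(3)]
        m = aggregate_calls(calls, min_coverage=10)
        assert m.fraction.loc["s1", ("t1", 2)] == pytest.approx(0.7)
        assert m.count_meth.loc["s1", ("t1", 2)] == 7

    def test_masking_keeps_counts(self):
        calls = [self.mk(CallState.METH, i) for i in range(4)]
        calls += [self.mk(CallState.UNMETH, i + 4) for i in range(3)]
        m = aggregate_calls(calls, min_coverage=10)
        assert pd.isna(m.fraction.loc["s1", ("t1", 2)])
        assert m.count_meth.loc["s1", ("t1", 2)] == 4
        assert m.count_unmeth.loc["s1", ("t1", 2)] == 3

    def test_ambiguous_excluded_from_fraction(self):
        calls = [self.mk(CallState.METH, i) for i in range(9)]
        calls += [self.mk(CallState.UNMETH, 9), self.mk(CallState.AMBIGUOUS, 10)]
        m = aggregate_calls(calls, min_coverage=10)
        assert m.fraction.loc["s1", ("t1", 2)] == pytest.approx(0.9)
        assert m.count_ambiguous.loc["s1", ("t1", 2)] == 1

    def test_min_coverage_validated(self):
        with pytest.raises(ValueError):
            aggregate_calls([], min_coverage=0)


class TestEndToEndRecovery:
    def test_planted_mixture_recovered_exactly(self, clean_panel):
        """70/30 fully-methylated/unmethylated molecules, conversion 1.0,
        error 0: every CpG fraction is exactly 0.7."""
        spec, targets, reads, truth = clean_panel
        alns, unmapped = align_reads(
            [r for recs in reads.values() for r in recs], targets
        )
        assert not unmapped
        tmap = {t.target_id: t for t in targets}
        calls = [c for a in alns for c in call_read(a, tmap[a.target_id])]
        m = aggregate_calls(calls, min_coverage=10)
        frac = m.fraction
        assert not frac.isna().any().any()
        assert np.allclose(frac.values, 0.7)

    def test_conservation_identity(self, clean_panel):
        """count_meth + count_unmeth + count_ambiguous equals the number of
        non-primer aligned pairs covering each CpG's evidence position."""
        spec, targets, reads, truth = clean_panel
        alns, _ = align_reads(reads["s1"], targets)
        tmap = {t.target_id: t for t in targets}
        calls = [c for a in alns for c in call_read(a, tmap[a.target_id])]
        m = aggregate_calls(calls, min_coverage=1)
        total = m.count_meth + m.count_unmeth + m.count_ambiguous
        for t in targets:
            for p in t.callable_cpgs():
                expected = 0
                for a in alns:
                    if a.target_id != t.target_id:
                        continue
                    ev = p if a.strand in (Strand.OT, Strand.CTOT) else p + 1
                    expected += sum(
                        1
                        for (pos, _), flagged in zip(a.pairs, a.primer_mask)
                        if pos == ev and not flagged
                    )
                assert total.loc["s1", (t.target_id, p)] == expected


class TestConversionEstimate:
    def test_rate_arithmetic(self):
        est = ConversionEstimate("s", 99, 100)
        assert est.rate == pytest.approx(0.99)
        assert ConversionEstimate("s", 0, 0).rate is None

    def test_perfect_conversion_estimates_one(self, clean_panel):
        spec, targets, reads, truth = clean_panel
        alns, _ = align_reads(reads["s1"], targets)
        est = estimate_conversion(alns, targets)
        assert est["s1"].rate == pytest.approx(1.0)
        assert est["s1"].total_nonCpG_C > 1000

    def test_no_noncpg_c_gives_missing_rate(self):
        from amplimeth.targets import TargetRegion, locate_primers

        t = locate_primers(TargetRegion("t", "t", 0, 4, "ATTA"))
        top, bottom = noncpg_c_positions(t)
        assert top == [] and bottom == []
        assert estimate_conversion([], [t]) == {}

    def test_planted_efficiency_recovered(self, clean_panel):
        """Reads emitted at conversion 0.98 yield an estimate within
        +/-0.01 given thousands of non-CpG observations."""
        from amplimeth.simulate import SimulationSpec, simulate_reads

        _, targets, _, _ = clean_panel
        spec = SimulationSpec(
            n_targets=3, n_cpgs_per_target=4,
            mixtures={t.target_id: [("MMMM", 0.5), ("UUUU", 0.5)]
                      for t in targets},
            conversion_efficiency=0.98, reads_per_sample_per_target=100,
            samples=("sx",), rng_seed=3,
        )
        reads, _ = simulate_reads(spec, targets)
        alns, _ = align_reads(reads["sx"], targets)
        est = estimate_conversion(alns, targets)
        assert est["sx"].total_nonCpG_C >= 2000
        assert est["sx"].rate == pytest.approx(0.98, abs=0.01)


class TestGroupSummaries:
    def build(self, fractions):
        calls = []
        for sample, frac in fractions.items():
            n_meth = int(round(frac * 10))
            for i in range(10):
                state = CallState.METH if i < n_meth else CallState.UNMETH
                calls.append(CpGCall("t1", 2, f"{sample}r{i}", sample, state,
                                     Strand.OT))
        return aggregate_calls(calls, min_coverage=10)

    def test_group_mean_of_two_samples(self):
        m = self.build({"a": 0.2, "b": 0.4})
        out = group_summaries(m, {"a": "g", "b": "g"})
        assert out["cpg_group_means"].loc["g", ("t1", 2)] == pytest.approx(0.3)

    def test_singleton_group_is_identity(self):
        m = self.build({"a": 0.2})
        out = group_summaries(m, {"a": "g"})
        assert out["cpg_group_means"].loc["g", ("t1", 2)] == pytest.approx(0.2)
        assert out["target_sample_means"].loc["a", "t1"] == pytest.approx(0.2)

    def test_masked_everywhere_gives_missing(self):
        calls = [CpGCall("t1", 2, "r0", "a", CallState.METH, Strand.OT)]
        m = aggregate_calls(calls, min_coverage=10)
        out = group_summaries(m, {"a": "g"})
        assert pd.isna(out["cpg_group_means"].loc["g", ("t1", 2)])

    def test_unknown_sample_rejected(self):
        m = self.build({"a": 0.2})
        with pytest.raises(ValueError, match="unknown"):
            group_summaries(m, {"ghost": "g"})

    def test_ungrouped_samples_fall_into_default(self):
        m = self.build({"a": 0.2, "b": 0.6})
        out = group_summaries(m, {"a": "g"})
        assert out["cpg_group_means"].loc["default", ("t1", 2)] == pytest.approx(0.6)
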