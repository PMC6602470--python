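"""Four-strand bisulfite-aware amplicon alignment.

PCR of bisulfite-converted DNA yields four distinguishable strand species
per locus: the original top (OT) and bottom (OB) strands and their PCR
complements (CTOT, CTOB).  Each species matches a different in-silico
converted version of the target sequence.  With S the forward target
sequence and R its reverse complement:

    OT_ref   = CtoT(S)        coordinates: identity
    OB_ref   = CtoT(R)        coordinates: j -> L-1-j
    CTOT_ref = GtoA(R)        coordinates: j -> L-1-j
    CTOB_ref = GtoA(S)        coordinates: identity

A read is C->T converted and scored against OT/OB references, G->A
converted and scored against CTOT/CTOB references; the best-scoring
(target, strand) wins.  Alignment is semi-global — the read must align
end to end, reference overhangs are free — with match +1, mismatch -1,
and an affine gap of length k costing 3 + k.  Strict score ties across
targets or strands make the read *ambiguous*: silent misassignment would
corrupt downstream epiallele patterns, so ambiguous reads are discarded
and accounted for in QC.

Aligned pairs store the ORIGINAL (unconverted) read bases projected to
the forward target orientation (reverse-complemented for OB/CTOT
placements), so methylation evidence survives the strand bookkeeping.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum

from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .targets import COMPLEMENT, TargetRegion, revcomp

CTOT_TABLE = str.maketrans("C", "T")
GTOA_TABLE = str.maketrans("G", "A")


class Strand(str, Enum):
    OT = "OT"
    OB = "OB"
    CTOT = "CTOT"
    CTOB = "CTOB"


#: Strands whose variant reference lives on the forward sequence S; their
#: variant coordinates are forward coordinates.  OB/CTOT live on R.
FORWARD_STRANDS = frozenset({Strand.OT, Strand.CTOB})

#: Strand sets per protocol. Directional libraries only sequence OT/OB.
STRAND_SETS = {
    "non-directional": (Strand.OT, Strand.OB, Strand.CTOT, Strand.CTOB),
    "directional": (Strand.OT, Strand.OB),
}


@dataclass
class ReadRecord:
    read_id: str
    bases: str
    qualities: list[int]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality values"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass
class FilterPolicy:
    min_read_length: int = 20
    max_read_length: int = 1000
    min_mean_quality: float = 20.0
    min_alignment_score_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.min_read_length > self.max_read_length:
            raise ValueError("min_read_length > max_read_length")


@dataclass
class FilterStats:
    n_input: int = 0
    n_passed: int = 0
    drop_too_short: int = 0
    drop_too_long: int = 0
    drop_low_quality: int = 0

    def check(self) -> None:
        dropped = self.drop_too_short + self.drop_too_long + self.drop_low_quality
        assert self.n_input == self.n_passed + dropped, "filter accounting broken"


@dataclass
class StrandedAlignment:
    """A read placed on one target with a bisulfite strand label.

    ``pairs`` lists ``(forward_target_pos, projected_base)`` with strictly
    increasing positions; a deletion in the read is recorded as base
    ``'-'``.  ``quals`` parallels ``pairs`` (0 at deletions).
    ``primer_mask`` parallels ``pairs``; True marks primer-derived bases
    which are kept for coverage but excluded from methylation calling.
    """

    read_id: str
    sample_id: str
    target_id: str
    strand: Strand
    ref_start: int
    ref_end: int
    pairs: list[tuple[int, str]]
    quals: list[int]
    score: float
    valid: bool = True
    primer_mask: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.primer_mask:
            self.primer_mask = [False] * len(self.pairs)


@dataclass
class UnmappedRead:
    read_id: str
    sample_id: str
    reason: str  # "low-score" | "ambiguous" | "length"


def read_fastq(path, sample_id: str = "") -> list[ReadRecord]:
    """Load a FASTQ or FASTQ.gz file into ReadRecords."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt", encoding="utf-8") as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                records.append(
                    ReadRecord(
                        read_id=title.split()[0],
                        bases=seq.upper(),
                        qualities=[ord(c) - 33 for c in qual],
                        sample_id=sample_id,
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ at record {len(records)}: {exc}"
            ) from exc
    return records


def filter_reads(
    reads, policy: FilterPolicy | None = None
) -> tuple[list[ReadRecord], FilterStats]:
    """Whole-read filtering by length and mean base quality."""
    policy = policy or FilterPolicy()
    stats = FilterStats()
    passed = []
    for read in reads:
        stats.n_input += 1
        n = len(read.bases)
        if n < policy.min_read_length:
            stats.drop_too_short += 1
        elif n > policy.max_read_length:
            stats.drop_too_long += 1
        elif read.mean_quality < policy.min_mean_quality:
            stats.drop_low_quality += 1
        else:
            stats.n_passed += 1
            passed.append(read)
    stats.check()
    return passed, stats


def build_strand_references(target: TargetRegion) -> dict[Strand, str]:
    """In-silico converted reference variants for the four strand species."""
    s = target.sequence
    r = revcomp(s)
    return {
        Strand.OT: s.translate(CTOT_TABLE),
        Strand.OB: r.translate(CTOT_TABLE),
        Strand.CTOT: r.translate(GTOA_TABLE),
        Strand.CTOB: s.translate(GTOA_TABLE),
    }


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # gap of length k costs 3 + k
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # reference overhangs (gap characters in the read row at its ends) are free
    aligner.end_deletion_score = 0
    return aligner


class StrandAligner:
    """Aligns reads against the converted references of a target panel."""

    def __init__(
        self,
        targets: list[TargetRegion],
        policy: FilterPolicy | None = None,
        strand_mode: str = "non-directional",
    ):
        if strand_mode not in STRAND_SETS:
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        self.targets = {t.target_id: t for t in targets}
        self.policy = policy or FilterPolicy()
        self.strands = STRAND_SETS[strand_mode]
        self.aligner = _make_aligner()
        self.refs: list[tuple[str, Strand, str]] = []
        for t in targets:
            variants = build_strand_references(t)
            for strand in self.strands:
                self.refs.append((t.target_id, strand, variants[strand]))
        self.max_target_len = max((len(t) for t in targets), default=0)

    def align_read(self, read: ReadRecord) -> StrandedAlignment | UnmappedRead:
        if len(read.bases) > 1.2 * self.max_target_len:
            return UnmappedRead(read.read_id, read.sample_id, "length")

        conv = {
            "CT": read.bases.translate(CTOT_TABLE),
            "GA": read.bases.translate(GTOA_TABLE),
        }
        scores = []
        for target_id, strand, ref in self.refs:
            q = conv["CT"] if strand in (Strand.OT, Strand.OB) else conv["GA"]
            scores.append(self.aligner.score(ref, q))
        best = max(scores)
        winners = [i for i, s in enumerate(scores) if s == best]
        if best < self.policy.min_alignment_score_fraction * len(read.bases):
            return UnmappedRead(read.read_id, read.sample_id, "low-score")
        # a tie within one (target, strand) pair is harmless; across pairs it
        # is a genuine ambiguity and the read is discarded
        if len(winners) > 1:
            return UnmappedRead(read.read_id, read.sample_id, "ambiguous")

        target_id, strand, ref = self.refs[winners[0]]
        q = conv["CT"] if strand in (Strand.OT, Strand.OB) else conv["GA"]
        aln = self.aligner.align(ref, q)[0]
        return self._project(read, target_id, strand, aln, best)

    def _project(
        self,
        read: ReadRecord,
        target_id: str,
        strand: Strand,
        aln,
        score: float,
    ) -> StrandedAlignment:
        """Turn a variant-space alignment into forward-coordinate pairs
        carrying the original read bases."""
        target = self.targets[target_id]
        L = len(target)
        blocks = aln.aligned  # ((tstart,tend),...), ((qstart,qend),...)
        tblocks, qblocks = blocks[0], blocks[1]
        var_pairs: list[tuple[int, int | None]] = []  # (variant_pos, read_idx|None)
        prev_tend = None
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if prev_tend is not None:
                for pos in range(prev_tend, ts):  # deletion in the read
                    var_pairs.append((pos, None))
            for k in range(te - ts):
                var_pairs.append((ts + k, qs + k))
            prev_tend = te
        ref_start_var = int(tblocks[0][0])
        ref_end_var = int(tblocks[-1][1])

        if strand in FORWARD_STRANDS:
            fwd = [(pos, idx) for pos, idx in var_pairs]
            ref_start, ref_end = ref_start_var, ref_end_var
            def project_base(b: str) -> str:
                return b
        else:
            # variant lives on the reverse complement: flip coordinates and
            # complement the read bases so everything reads forward
            fwd = [(L - 1 - pos, idx) for pos, idx in reversed(var_pairs)]
            ref_start, ref_end = L - ref_end_var, L - ref_start_var
            def project_base(b: str) -> str:
                return b.translate(COMPLEMENT)

        pairs: list[tuple[int, str]] = []
        quals: list[int] = []
        for pos, idx in fwd:
            if idx is None:
                pairs.append((pos, "-"))
                quals.append(0)
            else:
                pairs.append((pos, project_base(read.bases[idx])))
                quals.append(read.qualities[idx])
        return StrandedAlignment(
            read_id=read.read_id,
            sample_id=read.sample_id,
            target_id=target_id,
            strand=strand,
            ref_start=ref_start,
            ref_end=ref_end,
            pairs=pairs,
            quals=quals,
            score=score,
        )


def trim_primer_pairs(
    aln: StrandedAlignment, target: TargetRegion
) -> StrandedAlignment:
    """Flag primer-derived aligned pairs.

    Flagged positions stay in the alignment (they count toward coverage
    and spanning) but are excluded from methylation calling, since primer
    bases are synthetic.
    """
    aln.primer_mask = [target.in_primer(pos) for pos, _ in aln.pairs]
    return aln


def align_reads(
    reads: list[ReadRecord],
    targets: list[TargetRegion],
    policy: FilterPolicy | None = None,
    strand_mode: str = "non-directional",
) -> tuple[list[StrandedAlignment], list[UnmappedRead]]:
    """Align a batch of reads; returns accepted (primer-flagged) alignments
    and the unmapped accounting."""
    engine = StrandAligner(targets, policy, strand_mode)
    tmap = {t.target_id: t for t in targets}
    accepted, unmapped = [], []
    for read in reads:
        result = engine.align_read(read)
        if isinstance(result, UnmappedRead):
            unmapped.append(result)
        else:
            accepted.append(trim_primer_pairs(result, tmap[result.target_id]))
    return accepted, unmapped


def write_sam(
    alignments: list[StrandedAlignment],
    targets: list[TargetRegion],
    path,
) -> None:
    """Write accepted alignments as SAM, one reference per target.

    The bisulfite strand is recorded in the ``XS`` tag; the stored SEQ is
    the forward-projected original read sequence over the aligned span
    (deletions appear in the CIGAR).  Insertions relative to the target
    are not representable after projection and are omitted, so this export
    is for inspection, not round-tripping.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.target_id, "LN": len(t)} for t in targets],
    }
    tid_index = {t.target_id: i for i, t in enumerate(targets)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = tid_index[aln.target_id]
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60
            seq = "".join(b for _, b in aln.pairs if b != "-")
            rec.query_sequence = seq
            rec.query_qualities = [q for (_, b), q in zip(aln.pairs, aln.quals) if b != "-"]
            cigar = []
            for _, b in aln.pairs:
                op = 0 if b != "-" else 2  # M / D
                if cigar and cigar[-1][0] == op:
                    cigar[-1][1] += 1
                else:
                    cigar.append([op, 1])
            rec.cigartuples = [tuple(c) for c in cigar]
            rec.flag = 0
            rec.set_tag("XS", aln.strand.value)
            rec.set_tag("AS", int(aln.score))
            out.write(rec)


def write_unmapped_report(unmapped: list[UnmappedRead], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tsample_id\treason\n")
        for u in unmapped:
            fh.write(f"{u.read_id}\t{u.sample_id}\t{u.reason}\n")
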