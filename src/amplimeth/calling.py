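"""Per-CpG methylation calling from stranded alignments.

Bisulfite treatment converts unmethylated cytosine to uracil (read T)
while 5-methylcytosine is protected.  After four-strand alignment the
evidence base for a CpG whose C sits at forward position p is:

    OT, CTOT  -> projected base at p     (C = methylated, T = unmethylated)
    OB, CTOB  -> projected base at p+1   (G = methylated, A = unmethylated)

Evidence from both DNA strands of a CpG is merged onto the forward C
position, giving one count per site; per-strand counts are kept in QC.
Any other base, a deletion, or an evidence base below the base-quality
floor yields an AMBIGUOUS call, counted separately and excluded from the
methylation fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .align import Strand, StrandedAlignment
from .targets import TargetRegion

#: Evidence bases below this Phred score are called AMBIGUOUS.
DEFAULT_MIN_BASE_QUALITY = 20

#: Sites covered by fewer informative calls than this are masked.
DEFAULT_MIN_COVERAGE = 10


class CallState(str, Enum):
    METH = "METH"
    UNMETH = "UNMETH"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class CpGCall:
    target_id: str
    cpg_pos: int
    read_id: str
    sample_id: str
    state: CallState
    strand: Strand


@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite conversion rate from non-CpG cytosines.

    Cytosines outside CpG context are assumed unmethylated, so the
    fraction observed converted estimates the chemical efficiency."""

    sample_id: str
    converted_nonCpG_C: int
    total_nonCpG_C: int

    @property
    def rate(self) -> float | None:
        if self.total_nonCpG_C == 0:
            return None
        return self.converted_nonCpG_C / self.total_nonCpG_C


def _evidence(aln: StrandedAlignment, pos: int) -> tuple[str, int] | None:
    """Projected (base, qual) at a forward position, skipping primer pairs."""
    for (p, base), qual, flagged in zip(aln.pairs, aln.quals, aln.primer_mask):
        if p == pos:
            return None if flagged else (base, qual)
    return None


class _PairIndex:
    """Position -> (base, qual, primer_flag) lookup for one alignment."""

    def __init__(self, aln: StrandedAlignment):
        self.lut = {
            p: (base, qual, flagged)
            for (p, base), qual, flagged in zip(aln.pairs, aln.quals, aln.primer_mask)
        }

    def get(self, pos: int):
        return self.lut.get(pos)


def call_read(
    aln: StrandedAlignment,
    target: TargetRegion,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[CpGCall]:
    """Call every covered, non-primer CpG of ``target`` from one alignment."""
    lut = _PairIndex(aln)
    top = aln.strand in (Strand.OT, Strand.CTOT)
    calls = []
    for p in target.callable_cpgs():
        ev_pos = p if top else p + 1
        hit = lut.get(ev_pos)
        if hit is None:
            continue  # not covered by this alignment
        base, qual, flagged = hit
        if flagged:
            continue
        if base == "-" or qual < min_base_quality:
            state = CallState.AMBIGUOUS
        elif top:
            state = {
                "C": CallState.METH,
                "T": CallState.UNMETH,
            }.get(base, CallState.AMBIGUOUS)
        else:
            state = {
                "G": CallState.METH,
                "A": CallState.UNMETH,
            }.get(base, CallState.AMBIGUOUS)
        calls.append(
            CpGCall(target.target_id, p, aln.read_id, aln.sample_id, state, aln.strand)
        )
    return calls


class MethylationMatrix:
    """Per-sample, per-CpG methylation counts and fractions.

    Rows are samples; columns are a (target_id, cpg_pos) MultiIndex.
    The fraction count_meth / (count_meth + count_unmeth) is masked (NaN)
    exactly where informative coverage is below ``min_coverage``;
    AMBIGUOUS calls never enter the fraction.
    """

    def __init__(
        self,
        count_meth: pd.DataFrame,
        count_unmeth: pd.DataFrame,
        count_ambiguous: pd.DataFrame,
        min_coverage: int = DEFAULT_MIN_COVERAGE,
    ):
        self.count_meth = count_meth
        self.count_unmeth = count_unmeth
        self.count_ambiguous = count_ambiguous
        self.min_coverage = min_coverage

    @property
    def samples(self) -> list[str]:
        return list(self.count_meth.index)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return list(self.count_meth.columns)

    @property
    def coverage(self) -> pd.DataFrame:
        return self.count_meth + self.count_unmeth

    @property
    def fraction(self) -> pd.DataFrame:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.count_meth / cov
        return frac.where(cov >= self.min_coverage)


def aggregate_calls(
    calls,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    samples: list[str] | None = None,
    targets: list[TargetRegion] | None = None,
) -> MethylationMatrix:
    """Accumulate CpG calls into a :class:`MethylationMatrix`.

    ``samples``/``targets`` pin the row/column universe (and their order)
    so uncovered combinations appear as explicit zeros.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    counts: dict[tuple[str, str, int], list[int]] = {}
    seen_samples: list[str] = list(samples) if samples else []
    seen_sites: list[tuple[str, int]] = []
    if targets is not None:
        for t in targets:
            for p in t.callable_cpgs():
                seen_sites.append((t.target_id, p))
    site_set = set(seen_sites)
    sample_set = set(seen_samples)
    for c in calls:
        if c.sample_id not in sample_set:
            sample_set.add(c.sample_id)
            seen_samples.append(c.sample_id)
        key = (c.target_id, c.cpg_pos)
        if key not in site_set:
            site_set.add(key)
            seen_sites.append(key)
        cell = counts.setdefault((c.sample_id,) + key, [0, 0, 0])
        if c.state is CallState.METH:
            cell[0] += 1
        elif c.state is CallState.UNMETH:
            cell[1] += 1
        else:
            cell[2] += 1

    cols = pd.MultiIndex.from_tuples(
        seen_sites or [("__none__", 0)], names=["target_id", "cpg_pos"]
    )
    if not seen_sites:
        cols = pd.MultiIndex.from_tuples([], names=["target_id", "cpg_pos"])
    idx = pd.Index(seen_samples, name="sample_id")
    shape = (len(seen_samples), len(cols))
    meth = np.zeros(shape, dtype=int)
    unmeth = np.zeros(shape, dtype=int)
    ambig = np.zeros(shape, dtype=int)
    row_of = {s: i for i, s in enumerate(seen_samples)}
    col_of = {site: j for j, site in enumerate(cols)}
    for (sample, tid, pos), (m, u, a) in counts.items():
        i, j = row_of[sample], col_of[(tid, pos)]
        meth[i, j], unmeth[i, j], ambig[i, j] = m, u, a
    return MethylationMatrix(
        pd.DataFrame(meth, index=idx, columns=cols),
        pd.DataFrame(unmeth, index=idx, columns=cols),
        pd.DataFrame(ambig, index=idx, columns=cols),
        min_coverage=min_coverage,
    )


def noncpg_c_positions(target: TargetRegion) -> tuple[list[int], list[int]]:
    """Non-CpG cytosine positions outside primer spans, per strand.

    Returns (top, bottom): top-strand positions are forward Cs not
    followed by G; bottom-strand cytosines sit opposite forward Gs not
    preceded by C (reported at the forward G position, where OB/CTOB
    evidence is projected).
    """
    seq = target.sequence
    n = len(seq)
    top = [
        p
        for p in range(n)
        if seq[p] == "C"
        and (p + 1 >= n or seq[p + 1] != "G")
        and not target.in_primer(p)
    ]
    bottom = [
        q
        for q in range(n)
        if seq[q] == "G"
        and (q == 0 or seq[q - 1] != "C")
        and not target.in_primer(q)
    ]
    return top, bottom


def estimate_conversion(
    alignments,
    targets: list[TargetRegion],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> dict[str, ConversionEstimate]:
    """Per-sample conversion rate from non-CpG cytosine observations.

    Top-strand reads (OT/CTOT) are scored at top-strand non-CpG Cs
    (C unconverted, T converted); bottom-strand reads (OB/CTOB) at
    bottom-strand non-CpG Cs projected to the forward G position
    (G unconverted, A converted)."""
    pos_cache = {t.target_id: noncpg_c_positions(t) for t in targets}
    tallies: dict[str, list[int]] = {}
    for aln in alignments:
        top_pos, bottom_pos = pos_cache[aln.target_id]
        is_top = aln.strand in (Strand.OT, Strand.CTOT)
        watch = top_pos if is_top else bottom_pos
        unconverted_base = "C" if is_top else "G"
        converted_base = "T" if is_top else "A"
        lut = _PairIndex(aln)
        cell = tallies.setdefault(aln.sample_id, [0, 0])
        for p in watch:
            hit = lut.get(p)
            if hit is None:
                continue
            base, qual, flagged = hit
            if flagged or qual < min_base_quality:
                continue
            if base == converted_base:
                cell[0] += 1
                cell[1] += 1
            elif base == unconverted_base:
                cell[1] += 1
    return {
        s: ConversionEstimate(s, conv, total)
        for s, (conv, total) in sorted(tallies.items())
    }


def group_summaries(
    matrix: MethylationMatrix, groups: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Group-wise methylation summaries at CpG and target level.

    Returns ``cpg_group_means`` (group x site, unweighted mean of unmasked
    sample fractions), ``target_sample_means`` (sample x target, mean over
    that sample's unmasked CpGs) and ``target_group_means``.  Ungrouped
    samples fall into group "default"; unknown samples in the map are an
    error.
    """
    groups = dict(groups or {})
    unknown = set(groups) - set(matrix.samples)
    if unknown:
        raise ValueError(f"group map names unknown samples: {sorted(unknown)}")
    labels = pd.Series(
        [groups.get(s, "default") for s in matrix.samples],
        index=matrix.count_meth.index,
        name="group",
    )
    frac = matrix.fraction
    cpg_group = frac.groupby(labels).mean()
    target_sample = frac.T.groupby(level="target_id").mean().T
    target_group = target_sample.groupby(labels).mean()
    return {
        "cpg_group_means": cpg_group,
        "target_sample_means": target_sample,
        "target_group_means": target_group,
    }


def write_coverage_tsv(
    matrix: MethylationMatrix,
    targets: list[TargetRegion],
    sample_id: str,
    path,
) -> None:
    """Bismark-coverage dialect: chrom, 1-based pos (twice), methylation
    percent, methylated count, unmethylated count.  Masked rows keep their
    counts; the percent column is empty."""
    tmap = {t.target_id: t for t in targets}
    frac = matrix.fraction
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "chrom\tstart\tend\tmethylation_percent\t"
            "count_methylated\tcount_unmethylated\n"
        )
        for tid, p in matrix.sites:
            t = tmap[tid]
            gpos = t.genomic_cpg_pos(p)
            m = int(matrix.count_meth.loc[sample_id, (tid, p)])
            u = int(matrix.count_unmeth.loc[sample_id, (tid, p)])
            f = frac.loc[sample_id, (tid, p)]
            pct = "" if pd.isna(f) else f"{100 * f:.6g}"
            fh.write(f"{t.chrom}\t{gpos}\t{gpos}\t{pct}\t{m}\t{u}\n")


def write_matrix_tsv(matrix: MethylationMatrix, targets: list[TargetRegion], path) -> None:
    """Combined methylation-fraction matrix: one row per CpG, one column
    per sample, for downstream group comparisons."""
    tmap = {t.target_id: t for t in targets}
    frac = matrix.fraction
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_id\tchrom\tpos\t" + "\t".join(matrix.samples) + "\n")
        for tid, p in matrix.sites:
            t = tmap[tid]
            vals = []
            for s in matrix.samples:
                f = frac.loc[s, (tid, p)]
                vals.append("NA" if pd.isna(f) else f"{f:.6g}")
            fh.write(f"{tid}\t{t.chrom}\t{t.genomic_cpg_pos(p)}\t" + "\t".join(vals) + "\n")
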