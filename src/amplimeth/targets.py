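"""Amplicon target definitions for targeted bisulfite sequencing.

A *target* is one amplicon: its genomic placement (or bare sequence), the
forward/reverse PCR primer sequences, the resolved primer annealing spans,
the primer-free *inner span* that carries biological methylation signal,
and the inventory of CpG sites on the forward strand.

Internal coordinates are 0-based half-open throughout.  The target file
uses 1-based inclusive genomic coordinates; BED exports are 0-based
half-open; tabular methylation outputs use 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Methylation-sensitive restriction enzymes shipped as the default scan set.
DEFAULT_ENZYMES: list[tuple[str, str]] = [
    ("HhaI", "GCGC"),
    ("HpaII", "CCGG"),
    ("AciI", "CCGC"),
    ("Hin6I", "GCGC"),
]

#: Minimum fraction of primer positions that must match (exact or
#: bisulfite-tolerated) for a primer placement to be accepted.
PRIMER_IDENTITY_THRESHOLD = 0.8


class TargetFileFormatError(ValueError):
    """The target TSV is structurally malformed (missing columns/header)."""


class TargetValidationError(ValueError):
    """A target row is internally inconsistent or conflicts with another."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TargetRegion:
    """One amplicon target.

    ``start``/``end`` are genomic 0-based half-open; for sequence-only
    targets they default to ``0``/``len(sequence)`` on a synthetic contig
    named after the target.  ``cpg_positions`` hold the target-coordinate
    position of the C of every forward-strand CpG.
    """

    target_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    fwd_primer: str = ""
    rev_primer: str = ""
    fwd_primer_span: tuple[int, int] = (0, 0)
    rev_primer_span: tuple[int, int] = (0, 0)
    inner_span: tuple[int, int] = (0, 0)
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.end - self.start:
            raise TargetValidationError(
                f"target {self.target_id}: sequence length {len(self.sequence)} "
                f"!= end - start ({self.end - self.start})"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise TargetValidationError(
                f"target {self.target_id}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def in_primer(self, pos: int) -> bool:
        """True if target position ``pos`` lies inside a resolved primer span."""
        return (self.fwd_primer_span[0] <= pos < self.fwd_primer_span[1]) or (
            self.rev_primer_span[0] <= pos < self.rev_primer_span[1]
        )

    def callable_cpgs(self) -> list[int]:
        """CpG positions eligible for methylation calling.

        A CpG is excluded when its C or its G falls inside a primer span:
        primer bases are synthetic and carry no methylation signal.
        """
        return [
            p
            for p in self.cpg_positions
            if not (self.in_primer(p) or self.in_primer(p + 1))
        ]

    def genomic_cpg_pos(self, p: int) -> int:
        """1-based genomic coordinate of the CpG C at target position ``p``."""
        return self.start + p + 1


@dataclass(frozen=True)
class RestrictionSite:
    enzyme_name: str
    recognition_seq: str
    target_id: str
    position: int
    overlapping_cpgs: list[int]


def enumerate_cpgs(sequence: str) -> list[int]:
    """All positions ``p`` with ``sequence[p:p+2] == "CG"``, increasing."""
    out = []
    p = sequence.find("CG")
    while p != -1:
        out.append(p)
        p = sequence.find("CG", p + 1)
    return out


def _primer_scan(
    target_seq: str, probe: str, tolerated: tuple[str, str]
) -> tuple[int, float] | None:
    """Best ungapped placement of ``probe`` on ``target_seq``.

    ``tolerated`` is the (target_base, probe_base) pair that scores as a
    match despite differing — the bisulfite-conversion pairing.  Returns
    ``(offset, identity)`` for the best (leftmost on ties) placement with
    identity >= PRIMER_IDENTITY_THRESHOLD, else None.
    """
    n, m = len(target_seq), len(probe)
    if m == 0 or m > n:
        return None
    tb, pb = tolerated
    best: tuple[int, float] | None = None
    for off in range(n - m + 1):
        matches = 0
        for t, p in zip(target_seq[off : off + m], probe):
            if t == p or (t == tb and p == pb):
                matches += 1
        identity = matches / m
        if best is None or identity > best[1]:
            best = (off, identity)
    if best is None or best[1] < PRIMER_IDENTITY_THRESHOLD:
        return None
    return best


def locate_primers(target: TargetRegion) -> TargetRegion:
    """Resolve primer annealing spans and the primer-free inner span.

    The forward primer is searched on the forward target sequence with the
    bisulfite-tolerated pairing target C / primer T; the reverse primer is
    reverse-complemented and searched on the forward sequence with target
    G / primer A tolerated.  An unlocatable primer leaves an empty span
    and the inner span falls back to the corresponding target end.
    """
    seq = target.sequence
    fwd_hit = _primer_scan(seq, target.fwd_primer.upper(), ("C", "T"))
    rev_probe = revcomp(target.rev_primer.upper())
    rev_hit = _primer_scan(seq, rev_probe, ("G", "A"))

    if fwd_hit is None:
        fwd_span = (0, 0)
        inner_start = 0
        if target.fwd_primer:
            logger.warning(
                "target %s: forward primer not located; inner span starts at 0",
                target.target_id,
            )
    else:
        fwd_span = (fwd_hit[0], fwd_hit[0] + len(target.fwd_primer))
        inner_start = fwd_span[1]

    if rev_hit is None:
        rev_span = (0, 0)
        inner_end = len(seq)
        if target.rev_primer:
            logger.warning(
                "target %s: reverse primer not located; inner span ends at target end",
                target.target_id,
            )
    else:
        rev_span = (rev_hit[0], rev_hit[0] + len(rev_probe))
        inner_end = rev_span[0]

    if fwd_hit is not None and rev_hit is not None and fwd_span[1] > rev_span[0]:
        raise TargetValidationError(
            f"target {target.target_id}: primers overlap or inverted "
            f"(fwd {fwd_span}, rev {rev_span})"
        )

    return replace(
        target,
        fwd_primer_span=fwd_span,
        rev_primer_span=rev_span,
        inner_span=(inner_start, inner_end),
        cpg_positions=enumerate_cpgs(seq),
    )


COORD_COLUMNS = ["target_id", "chrom", "start", "end", "fwd_primer", "rev_primer"]
SEQ_COLUMNS = ["target_id", "sequence", "fwd_primer", "rev_primer"]


def parse_target_file(path, reference=None) -> list[TargetRegion]:
    """Parse a target TSV into resolved :class:`TargetRegion` objects.

    Two dialects are accepted, distinguished by the header: coordinate
    style (``target_id chrom start end fwd_primer rev_primer``, 1-based
    inclusive coordinates, requires ``reference`` as a FASTA path or
    :class:`pyfaidx.Fasta`) or sequence style (``target_id sequence
    fwd_primer rev_primer``).  Primer spans and CpG inventories are
    resolved on every returned target.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TargetFileFormatError(f"{path}: empty target file")
    header = lines[0].split("\t")
    if all(c in header for c in COORD_COLUMNS):
        mode = "coords"
        cols = COORD_COLUMNS
    elif all(c in header for c in SEQ_COLUMNS):
        mode = "sequence"
        cols = SEQ_COLUMNS
    else:
        raise TargetFileFormatError(
            f"{path}: header must contain columns {COORD_COLUMNS} or {SEQ_COLUMNS}; "
            f"got {header}"
        )
    idx = {c: header.index(c) for c in cols}

    fasta = None
    if mode == "coords":
        if reference is None:
            raise TargetValidationError(
                f"{path}: coordinate-style targets require a reference FASTA"
            )
        fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))

    targets: list[TargetRegion] = []
    seen: set[str] = set()
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < len(header):
            raise TargetFileFormatError(f"{path}:{i}: expected {len(header)} columns")
        row = {c: fields[idx[c]].strip() for c in cols}
        tid = row["target_id"]
        if tid in seen:
            raise TargetValidationError(f"{path}:{i}: duplicate target_id {tid!r}")
        seen.add(tid)
        if mode == "coords":
            chrom = row["chrom"]
            try:
                start1, end1 = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise TargetFileFormatError(
                    f"{path}:{i}: non-integer coordinates"
                ) from exc
            if chrom not in fasta:
                raise TargetValidationError(f"{path}:{i}: unknown contig {chrom!r}")
            contig_len = len(fasta[chrom])
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if not (0 <= start0 < end0 <= contig_len):
                raise TargetValidationError(
                    f"{path}:{i}: coordinates {start1}-{end1} outside contig "
                    f"{chrom} (length {contig_len})"
                )
            seq = str(fasta[chrom][start0:end0]).upper()
            region = TargetRegion(tid, chrom, start0, end0, seq,
                                  row["fwd_primer"].upper(), row["rev_primer"].upper())
        else:
            seq = row["sequence"].upper()
            region = TargetRegion(tid, tid, 0, len(seq), seq,
                                  row["fwd_primer"].upper(), row["rev_primer"].upper())
        targets.append(locate_primers(region))
    return targets


def find_restriction_sites(
    target: TargetRegion, enzymes: list[tuple[str, str]] | None = None
) -> list[RestrictionSite]:
    """Scan the untreated forward target sequence for recognition sites.

    Overlapping occurrences are all reported.  Ambiguous IUPAC codes in
    recognition sequences are not supported.
    """
    if enzymes is None:
        enzymes = DEFAULT_ENZYMES
    sites: list[RestrictionSite] = []
    for name, recog in enzymes:
        recog = recog.upper()
        if set(recog) - set("ACGT"):
            raise TargetValidationError(
                f"enzyme {name}: ambiguous IUPAC codes in {recog!r} unsupported"
            )
        start = target.sequence.find(recog)
        while start != -1:
            over = [
                p
                for p in target.cpg_positions
                if start <= p < start + len(recog)
            ]
            sites.append(RestrictionSite(name, recog, target.target_id, start, over))
            start = target.sequence.find(recog, start + 1)
    sites.sort(key=lambda s: (s.position, s.enzyme_name))
    return sites


def load_enzyme_file(path) -> list[tuple[str, str]]:
    """Read a name<TAB>recognition_seq config file (``#`` comments allowed)."""
    enzymes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TargetFileFormatError(f"{path}: expected name<TAB>sequence")
            enzymes.append((parts[0], parts[1].upper()))
    return enzymes


def write_targets_fasta(targets: list[TargetRegion], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n{t.sequence}\n")


def write_targets_bed(targets: list[TargetRegion], path) -> None:
    """BED6-lite export: chrom, start, end (0-based half-open), target_id."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\n")
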