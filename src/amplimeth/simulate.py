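"""Bisulfite amplicon read simulator with complete ground truth.

The simulator emulates a targeted bisulfite sequencing experiment:
amplicons with CpG-free 20 nt primers flanking an inner region carrying a
known number of CpGs; molecules drawn from a per-target epiallele
mixture; bisulfite chemistry (methylated CpG cytosines survive, all
other cytosines convert with the configured efficiency, assumed
symmetric across strands); emission on one of the four PCR strand
species; uniform substitution sequencing error; constant Phred 40 base
qualities.

Everything stochastic flows from one numpy Generator keyed by
``rng_seed``, so runs are bit-reproducible.  Every draw is recorded in a
:class:`GroundTruth` object, which is the oracle for the test suite.

It does not emulate: indel errors, PCR bias or chimeras, quality decay
along the read, or hemimethylation.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .align import ReadRecord, Strand, STRAND_SETS
from .targets import TargetRegion, locate_primers, revcomp

BASES = "ACGT"
PRIMER_LEN = 20


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Study conditions for one simulated experiment."""

    n_targets: int = 3
    target_length: int = 160
    n_cpgs_per_target: int = 4
    #: target_id -> [(pattern, frequency)]; None draws a random 3-component
    #: mixture per target so per-CpG truth varies between 0 and 1.
    mixtures: dict[str, list[tuple[str, float]]] | None = None
    conversion_efficiency: float = 1.0
    sequencing_error_rate: float = 0.0
    reads_per_sample_per_target: int = 200
    strand_mode: str = "non-directional"
    samples: tuple[str, ...] = ("s1", "s2")
    groups: dict[str, str] = field(default_factory=dict)
    beta_jitter: float = 0.0
    truncation_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "sequencing_error_rate",
                     "beta_jitter", "truncation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0,1]")
        if self.target_length < 2 * PRIMER_LEN + 2 * self.n_cpgs_per_target + 10:
            raise SimulationError(
                f"target_length {self.target_length} too short for "
                f"{self.n_cpgs_per_target} CpGs plus primers"
            )
        if self.strand_mode not in STRAND_SETS:
            raise SimulationError(f"unknown strand_mode {self.strand_mode!r}")
        if self.mixtures is not None:
            for tid, mix in self.mixtures.items():
                tot = sum(f for _, f in mix)
                if abs(tot - 1.0) > 1e-9:
                    raise SimulationError(
                        f"target {tid}: mixture frequencies sum to {tot}"
                    )
                for pat, _ in mix:
                    if len(pat) != self.n_cpgs_per_target or set(pat) - set("MU"):
                        raise SimulationError(
                            f"target {tid}: bad pattern {pat!r}"
                        )


@dataclass
class GroundTruth:
    """Every simulated draw, recorded for downstream verification."""

    #: read_id -> {sample, target, strand, pattern, truncated}
    reads: dict[str, dict]
    #: (target_id, cpg_target_pos) -> mixture-weighted methylated fraction
    true_cpg_fraction: dict[tuple[str, int], float]
    #: target_id -> {pattern: planted frequency}
    pattern_freq: dict[str, dict[str, float]]
    #: (sample, target_id) -> {pattern: realized count among emitted reads}
    realized_counts: dict[tuple[str, str], dict[str, int]]

    def to_json(self, path) -> None:
        doc = {
            "reads": self.reads,
            "true_cpg_fraction": {
                f"{tid}:{p}": v for (tid, p), v in self.true_cpg_fraction.items()
            },
            "pattern_freq": self.pattern_freq,
            "realized_counts": {
                f"{s}:{tid}": v for (s, tid), v in self.realized_counts.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def _random_cg_free(rng: np.random.Generator, length: int, prev: str = "") -> str:
    """Random DNA with no CG dinucleotide (also across the ``prev`` join)."""
    out = []
    last = prev[-1:] if prev else ""
    for _ in range(length):
        choices = "ACT" if last == "C" else BASES
        b = choices[rng.integers(len(choices))]
        out.append(b)
        last = b
    return "".join(out)


def build_panel(spec: SimulationSpec) -> tuple[str, list[TargetRegion], int]:
    """Construct the reference contig and resolved targets.

    Returns (contig_sequence, targets, spacer) where targets carry genomic
    coordinates on the single contig ``chr_sim``; amplicons are separated
    by CG-free spacers.  CpG placement is exact: the inner region holds
    precisely ``n_cpgs_per_target`` CpGs and the primers none.
    """
    rng = np.random.default_rng(spec.rng_seed)
    spacer = 30
    pieces: list[str] = []
    targets: list[TargetRegion] = []
    offset = 0
    for i in range(spec.n_targets):
        tid = f"t{i + 1}"
        L = spec.target_length
        seq = _random_cg_free(rng, L)
        lo = PRIMER_LEN + 1
        hi = L - PRIMER_LEN - 2  # C at p, G at p+1 both inside the inner region
        # CpG positions at least 2 apart so planted sites never overlap
        pool = np.arange(lo, hi)
        positions: list[int] = []
        mask = np.ones(len(pool), dtype=bool)
        while len(positions) < spec.n_cpgs_per_target:
            avail = pool[mask]
            if len(avail) == 0:
                raise SimulationError("cannot place requested CpGs")
            p = int(avail[rng.integers(len(avail))])
            positions.append(p)
            mask &= np.abs(pool - p) >= 2
        positions.sort()
        chars = list(seq)
        for p in positions:
            chars[p], chars[p + 1] = "C", "G"
        seq = "".join(chars)
        fwd_primer = seq[:PRIMER_LEN]
        rev_primer = revcomp(seq[-PRIMER_LEN:])
        region = TargetRegion(
            target_id=tid,
            chrom="chr_sim",
            start=offset,
            end=offset + L,
            sequence=seq,
            fwd_primer=fwd_primer,
            rev_primer=rev_primer,
        )
        region = locate_primers(region)
        if region.callable_cpgs() != positions:
            raise SimulationError(
                f"{tid}: CpG accounting broken: {region.callable_cpgs()} vs {positions}"
            )
        targets.append(region)
        gap = _random_cg_free(rng, spacer, prev=seq)
        pieces.append(seq)
        pieces.append(gap)
        offset += L + spacer
    if len({t.fwd_primer for t in targets} | {t.rev_primer for t in targets}) \
            < 2 * len(targets):
        raise SimulationError("primer collision across targets")
    return "".join(pieces), targets, spacer


def _default_mixture(
    rng: np.random.Generator, n_cpgs: int
) -> list[tuple[str, float]]:
    """Three random distinct patterns with Dirichlet frequencies."""
    patterns: set[str] = set()
    while len(patterns) < min(3, 2**n_cpgs if n_cpgs else 1):
        patterns.add("".join("MU"[rng.integers(2)] for _ in range(n_cpgs)))
    pats = sorted(patterns)
    freqs = rng.dirichlet(np.ones(len(pats)) * 2.0)
    return list(zip(pats, freqs.tolist()))


def resolve_mixtures(
    spec: SimulationSpec, targets: list[TargetRegion]
) -> dict[str, list[tuple[str, float]]]:
    if spec.mixtures is not None:
        missing = {t.target_id for t in targets} - set(spec.mixtures)
        if missing:
            raise SimulationError(f"mixtures missing for targets {sorted(missing)}")
        return spec.mixtures
    rng = np.random.default_rng(spec.rng_seed + 1)
    return {
        t.target_id: _default_mixture(rng, spec.n_cpgs_per_target) for t in targets
    }


def allocate_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of ``n`` draws to mixture components.

    Mixture frequencies are realized exactly (up to integer rounding)
    rather than sampled i.i.d., so a 0.7/0.3 mixture at n=1000 yields
    exactly 700/300 molecules; read order is shuffled downstream."""
    raw = freqs * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _convert_top(
    seq: str,
    meth_positions: set[int],
    rng: np.random.Generator,
    efficiency: float,
) -> str:
    """Bisulfite-convert the forward strand of one molecule."""
    out = []
    for i, b in enumerate(seq):
        if b == "C" and i not in meth_positions and rng.random() < efficiency:
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    for i, b in enumerate(chars):
        if rng.random() < rate:
            alt = BASES.replace(b, "") if b in BASES else BASES
            chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def emit_read_bases(
    target: TargetRegion,
    pattern: str,
    strand: Strand,
    rng: np.random.Generator,
    conversion_efficiency: float = 1.0,
    sequencing_error_rate: float = 0.0,
) -> str:
    """Bisulfite-converted read sequence for one molecule on one strand.

    ``pattern`` gives M/U states over the target's callable CpGs.
    Methylation is symmetric: the bottom-strand cytosine of a methylated
    CpG (opposite the forward G at p+1) is protected too."""
    cpgs = target.callable_cpgs()
    meth_c = {p for p, st in zip(cpgs, pattern) if st == "M"}
    if strand in (Strand.OT, Strand.CTOT):
        conv = _convert_top(target.sequence, meth_c, rng, conversion_efficiency)
        bases = conv if strand is Strand.OT else revcomp(conv)
    else:
        bottom = revcomp(target.sequence)
        L = len(target.sequence)
        meth_bottom = {L - 1 - (p + 1) for p in meth_c}
        conv = _convert_top(bottom, meth_bottom, rng, conversion_efficiency)
        bases = conv if strand is Strand.OB else revcomp(conv)
    return _apply_errors(bases, rng, sequencing_error_rate)


def simulate_reads(
    spec: SimulationSpec, targets: list[TargetRegion]
) -> tuple[dict[str, list[ReadRecord]], GroundTruth]:
    """Emit full-amplicon bisulfite reads per sample with ground truth."""
    rng = np.random.default_rng(spec.rng_seed + 2)
    mixtures = resolve_mixtures(spec, targets)
    strands = STRAND_SETS[spec.strand_mode]

    true_frac: dict[tuple[str, int], float] = {}
    pattern_freq: dict[str, dict[str, float]] = {}
    for t in targets:
        mix = mixtures[t.target_id]
        pattern_freq[t.target_id] = {p: f for p, f in mix}
        for k, p in enumerate(t.callable_cpgs()):
            true_frac[(t.target_id, p)] = sum(
                f for pat, f in mix if pat[k] == "M"
            )

    reads: dict[str, list[ReadRecord]] = {s: [] for s in spec.samples}
    truth_reads: dict[str, dict] = {}
    realized: dict[tuple[str, str], dict[str, int]] = {}
    for sample in spec.samples:
        for t in targets:
            mix = mixtures[t.target_id]
            pats = [p for p, _ in mix]
            freqs = np.array([f for _, f in mix])
            freqs = freqs / freqs.sum()
            cell = realized.setdefault((sample, t.target_id), {})
            n = spec.reads_per_sample_per_target
            draws = np.repeat(np.arange(len(pats)), allocate_counts(freqs, n))
            rng.shuffle(draws)
            for i in range(n):
                pattern = pats[draws[i]]
                strand = strands[rng.integers(len(strands))]
                bases = emit_read_bases(
                    t, pattern, strand, rng, spec.conversion_efficiency
                )
                truncated = False
                if spec.truncation_fraction and rng.random() < spec.truncation_fraction:
                    truncated = True
                    keep = len(bases) // 2
                    bases = bases[:keep] if rng.random() < 0.5 else bases[-keep:]
                bases = _apply_errors(bases, rng, spec.sequencing_error_rate)
                read_id = f"{sample}|{t.target_id}|{i}"
                reads[sample].append(
                    ReadRecord(read_id, bases, [40] * len(bases), sample)
                )
                truth_reads[read_id] = {
                    "sample": sample,
                    "target": t.target_id,
                    "strand": strand.value,
                    "pattern": pattern,
                    "truncated": truncated,
                }
                cell[pattern] = cell.get(pattern, 0) + 1
    return reads, GroundTruth(truth_reads, true_frac, pattern_freq, realized)


def array_betas_from_truth(
    spec: SimulationSpec,
    targets: list[TargetRegion],
    truth: GroundTruth,
) -> list[tuple[str, str, int, list[float]]]:
    """Array rows (probe_id, chrom, 1-based pos, betas per sample).

    Betas equal the planted per-CpG methylated fraction, optionally
    jittered by a uniform offset of at most ``beta_jitter`` and clipped
    to [0,1]."""
    rng = np.random.default_rng(spec.rng_seed + 3)
    rows = []
    k = 0
    for t in targets:
        for p in t.callable_cpgs():
            k += 1
            base = truth.true_cpg_fraction[(t.target_id, p)]
            betas = []
            for _ in spec.samples:
                b = base
                if spec.beta_jitter:
                    b += rng.uniform(-spec.beta_jitter, spec.beta_jitter)
                betas.append(float(min(1.0, max(0.0, b))))
            rows.append((f"cg{k:06d}", t.chrom, t.genomic_cpg_pos(p), betas))
    return rows


def write_simulation(spec: SimulationSpec, outdir) -> dict:
    """Write FASTA, target TSV, per-sample FASTQ.gz, array TSV and ground
    truth JSON; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig, targets, _ = build_panel(spec)
    reads, truth = simulate_reads(spec, targets)

    ref_path = outdir / "reference.fasta"
    with open(ref_path, "w", encoding="utf-8") as fh:
        fh.write(">chr_sim\n")
        for i in range(0, len(contig), 70):
            fh.write(contig[i : i + 70] + "\n")
    # drop any stale pyfaidx index so re-simulation into the same directory
    # never reads an outdated offset table
    idx = Path(str(ref_path) + ".fai")
    if idx.exists():
        idx.unlink()

    tsv_path = outdir / "targets.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("target_id\tchrom\tstart\tend\tfwd_primer\trev_primer\n")
        for t in targets:
            fh.write(
                f"{t.target_id}\t{t.chrom}\t{t.start + 1}\t{t.end}\t"
                f"{t.fwd_primer}\t{t.rev_primer}\n"
            )

    fastqs = {}
    for sample, recs in reads.items():
        fq = outdir / f"{sample}.fastq.gz"
        # fixed mtime so identical simulations are byte-identical on disk
        with gzip.GzipFile(
            filename="", mode="wb", fileobj=open(fq, "wb"), mtime=0
        ) as gz:
            for r in recs:
                qual = "".join(chr(q + 33) for q in r.qualities)
                gz.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n".encode())
        fastqs[sample] = fq

    array_path = outdir / "array.tsv"
    rows = array_betas_from_truth(spec, targets, truth)
    with open(array_path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tchrom\tpos\t" + "\t".join(spec.samples) + "\n")
        for probe, chrom, pos, betas in rows:
            fh.write(
                f"{probe}\t{chrom}\t{pos}\t"
                + "\t".join(f"{b:.6g}" for b in betas)
                + "\n"
            )

    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    spec_path = outdir / "simulation_spec.json"
    with open(spec_path, "w", encoding="utf-8") as fh:
        doc = asdict(spec)
        doc["samples"] = list(spec.samples)
        json.dump(doc, fh, indent=1, sort_keys=True)
    return {
        "reference": ref_path,
        "targets": tsv_path,
        "fastqs": fastqs,
        "array": array_path,
        "ground_truth": truth_path,
        "spec": spec_path,
    }
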