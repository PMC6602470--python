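"""Run-level quality metrics and the machine-readable QC report.

All count identities (filter accounting, mapped + unmapped + ambiguous ==
passed, epiallele counts vs accepted spanning reads) are asserted on
every run before the report is written — a violated identity is a hard
failure naming the broken invariant, never a warning.
"""

from __future__ import annotations

import json
from collections import Counter

import pandas as pd

from .align import FilterStats, StrandedAlignment, UnmappedRead
from .calling import ConversionEstimate, MethylationMatrix
from .targets import RestrictionSite, TargetRegion

SCHEMA_VERSION = "1.0"

UNMAPPED_REASONS = ("low-score", "ambiguous", "length")


class QCInvariantError(AssertionError):
    """A count identity that must hold on every run was violated."""


def coverage_matrix(
    alignments,
    samples: list[str],
    targets: list[TargetRegion],
) -> pd.DataFrame:
    """Sample x target table of accepted alignments, zero-filled."""
    counts = Counter((a.sample_id, a.target_id) for a in alignments)
    tids = [t.target_id for t in targets]
    data = [[counts.get((s, tid), 0) for tid in tids] for s in samples]
    return pd.DataFrame(
        data, index=pd.Index(samples, name="sample_id"), columns=tids
    )


def off_target_summary(
    unmapped: list[UnmappedRead],
    passed_per_sample: dict[str, int],
) -> pd.DataFrame:
    """Per-sample unmapped/ambiguous accounting with fractions of passed.

    Without genome-wide mapping, "off-target" reduces to reads that fail
    to place on any amplicon; fractions are missing when a sample passed
    zero reads.
    """
    reasons = Counter((u.sample_id, u.reason) for u in unmapped)
    rows = []
    for s in sorted(passed_per_sample):
        passed = passed_per_sample[s]
        row: dict = {"sample_id": s, "passed_filters": passed}
        total = 0
        for reason in UNMAPPED_REASONS:
            n = reasons.get((s, reason), 0)
            total += n
            row[f"n_{reason}"] = n
            row[f"frac_{reason}"] = (n / passed) if passed else None
        row["n_unmapped_total"] = total
        row["frac_unmapped_total"] = (total / passed) if passed else None
        rows.append(row)
    return pd.DataFrame(rows)


def read_length_histogram(reads_per_sample: dict[str, list[int]]) -> dict:
    return {
        s: dict(sorted(Counter(lengths).items()))
        for s, lengths in reads_per_sample.items()
    }


def assemble_report(
    *,
    filter_stats: dict[str, FilterStats],
    unmapped: list[UnmappedRead],
    alignments: list[StrandedAlignment],
    targets: list[TargetRegion],
    spanning_counts: pd.DataFrame,
    pattern_table: pd.DataFrame,
    accepted_spanning: dict[tuple[str, str], int],
    conversion: dict[str, ConversionEstimate],
    read_lengths: dict[str, list[int]],
    parameters: dict,
    version: str,
    timestamp: str,
) -> dict:
    """Build and validate the QC report document.

    ``accepted_spanning`` counts, per (sample, target), the spanning reads
    whose epiallele pattern was accepted; it must equal the pattern-table
    column sums.
    """
    samples = sorted(filter_stats)
    mapped = Counter(a.sample_id for a in alignments)
    unmapped_by = Counter((u.sample_id, u.reason) for u in unmapped)

    per_sample = {}
    for s in samples:
        fs = filter_stats[s]
        n_mapped = mapped.get(s, 0)
        n_low = unmapped_by.get((s, "low-score"), 0)
        n_amb = unmapped_by.get((s, "ambiguous"), 0)
        n_len = unmapped_by.get((s, "length"), 0)
        if n_mapped + n_low + n_amb + n_len != fs.n_passed:
            raise QCInvariantError(
                f"sample {s}: mapped + unmapped + ambiguous "
                f"({n_mapped}+{n_low + n_len}+{n_amb}) != passed_filters "
                f"({fs.n_passed})"
            )
        conv = conversion.get(s)
        per_sample[s] = {
            "total_reads": fs.n_input,
            "passed_filters": fs.n_passed,
            "dropped_too_short": fs.drop_too_short,
            "dropped_too_long": fs.drop_too_long,
            "dropped_low_quality": fs.drop_low_quality,
            "mapped": n_mapped,
            "unmapped_low_score": n_low,
            "unmapped_length": n_len,
            "ambiguous": n_amb,
            "mapping_efficiency": (n_mapped / fs.n_passed) if fs.n_passed else None,
            "conversion_rate": conv.rate if conv else None,
            "read_length_histogram": {
                str(k): v
                for k, v in sorted(Counter(read_lengths.get(s, [])).items())
            },
        }

    # epiallele counts must census exactly the accepted spanning reads
    for (s, tid), expected in sorted(accepted_spanning.items()):
        col = f"count_{s}"
        got = 0
        if not pattern_table.empty and col in pattern_table.columns:
            got = int(
                pattern_table.loc[pattern_table["target_id"] == tid, col].sum()
            )
        if got != expected:
            raise QCInvariantError(
                f"sample {s}, target {tid}: pattern counts sum to {got}, "
                f"accepted spanning reads = {expected}"
            )

    cov = coverage_matrix(alignments, samples, targets)
    report = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": version,
        "generated_at": timestamp,
        "parameters": parameters,
        "samples": per_sample,
        "coverage": {s: {t: int(cov.loc[s, t]) for t in cov.columns} for s in cov.index},
        "spanning_reads": {
            s: {t: int(spanning_counts.loc[s, t]) for t in spanning_counts.columns}
            for s in spanning_counts.index
        },
    }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_coverage_heatmap_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t")


def lollipop_json(
    matrix: MethylationMatrix,
    targets: list[TargetRegion],
    array_betas: pd.DataFrame | None = None,
    restriction_sites: list[RestrictionSite] | None = None,
) -> dict:
    """Plot-ready per-CpG methylation structure for a lollipop rendering.

    One circle per CpG at its genomic coordinate, colored by the sample's
    methylation fraction; optional array values form an outer ring and
    restriction sites are tick marks.  Rendering is the caller's job.
    """
    sites_by_target: dict[str, list] = {}
    frac = matrix.fraction
    for tid, p in matrix.sites:
        sites_by_target.setdefault(tid, []).append(p)
    out: dict = {"samples": matrix.samples, "targets": {}}
    rs_by_target: dict[str, list[RestrictionSite]] = {}
    for site in restriction_sites or []:
        rs_by_target.setdefault(site.target_id, []).append(site)
    for t in targets:
        entry: dict = {
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "fwd_primer_span": list(t.fwd_primer_span),
            "rev_primer_span": list(t.rev_primer_span),
            "cpgs": [],
            "restriction_sites": [
                {
                    "enzyme": s.enzyme_name,
                    "position": s.position,
                    "genomic_position": t.start + s.position + 1,
                    "overlapping_cpgs": s.overlapping_cpgs,
                }
                for s in rs_by_target.get(t.target_id, [])
            ],
        }
        for p in sites_by_target.get(t.target_id, []):
            gpos = t.genomic_cpg_pos(p)
            cpg = {
                "pos": p,
                "genomic_pos": gpos,
                "fractions": {},
                "array_betas": {},
            }
            for s in matrix.samples:
                f = frac.loc[s, (t.target_id, p)]
                cpg["fractions"][s] = None if pd.isna(f) else float(f)
            if array_betas is not None and (t.chrom, gpos) in array_betas.index:
                for s in array_betas.columns:
                    b = array_betas.loc[(t.chrom, gpos), s]
                    cpg["array_betas"][s] = None if pd.isna(b) else float(b)
            entry["cpgs"].append(cpg)
        out["targets"][t.target_id] = entry
    return out
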