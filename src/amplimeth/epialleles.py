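"""Epiallele (per-molecule methylation pattern) analysis.

An epiallele is the ordered methylation state of one DNA molecule across
all CpGs of a target.  Only reads spanning every callable CpG of the
target, with no ambiguous call, contribute a pattern; this keeps the
pattern table a faithful census of whole molecules rather than a mosaic
of fragments.  Patterns are strings over {M, U}, one character per
non-primer CpG in positional order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import StrandedAlignment
from .calling import CallState, CpGCall
from .targets import TargetRegion


@dataclass
class PatternResult:
    """Outcome of pattern extraction for one read."""

    pattern: str | None
    reject_reason: str | None  # None | "not-spanning" | "ambiguous-call"

    @property
    def accepted(self) -> bool:
        return self.pattern is not None


def extract_pattern(calls: list[CpGCall], target: TargetRegion) -> PatternResult:
    """Build the M/U pattern for one read, or reject it.

    Accepted only when every callable CpG of the target has a call and
    none is AMBIGUOUS.  Order-insensitive in the input call list.
    """
    wanted = target.callable_cpgs()
    by_pos = {c.cpg_pos: c.state for c in calls}
    if any(p not in by_pos for p in wanted):
        return PatternResult(None, "not-spanning")
    states = [by_pos[p] for p in wanted]
    if any(s is CallState.AMBIGUOUS for s in states):
        return PatternResult(None, "ambiguous-call")
    return PatternResult(
        "".join("M" if s is CallState.METH else "U" for s in states), None
    )


def summarize_patterns(
    observations,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate distinct patterns per target with per-sample counts.

    ``observations`` yields (sample_id, target_id, pattern) triples.
    Returns a tidy frame with columns target_id, pattern, count_<sample>,
    freq_<sample>, count_all, freq_all; rows ordered by total count
    descending, ties broken by pattern string.  Frequencies are within
    (sample, target); the all-samples aggregate pools reads.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    sample_order: list[str] = list(samples) if samples else []
    seen = set(sample_order)
    for sample_id, target_id, pattern in observations:
        if sample_id not in seen:
            seen.add(sample_id)
            sample_order.append(sample_id)
        cell = counts.setdefault((target_id, pattern), {})
        cell[sample_id] = cell.get(sample_id, 0) + 1

    rows = []
    for (target_id, pattern), per_sample in counts.items():
        row = {"target_id": target_id, "pattern": pattern}
        for s in sample_order:
            row[f"count_{s}"] = per_sample.get(s, 0)
        row["count_all"] = sum(per_sample.values())
        rows.append(row)
    cols = (
        ["target_id", "pattern"]
        + [f"count_{s}" for s in sample_order]
        + ["count_all"]
    )
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        for s in sample_order:
            df[f"freq_{s}"] = pd.Series(dtype=float)
        df["freq_all"] = pd.Series(dtype=float)
        return df
    df = df.sort_values(
        ["count_all", "pattern"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    for s in sample_order:
        totals = df.groupby("target_id")[f"count_{s}"].transform("sum")
        df[f"freq_{s}"] = (df[f"count_{s}"] / totals.where(totals > 0)).fillna(0.0)
    tot_all = df.groupby("target_id")["count_all"].transform("sum")
    df["freq_all"] = df["count_all"] / tot_all.where(tot_all > 0)
    return df


def is_spanning(aln: StrandedAlignment, target: TargetRegion) -> bool:
    """Spanning = the aligned interval contains the whole inner span.

    Using the inner (between-primer) span rather than the full target
    means primer-clipped amplicon reads still count as spanning."""
    lo, hi = target.inner_span
    return aln.ref_start <= lo and aln.ref_end >= hi


def count_spanning_reads(
    alignments,
    targets: list[TargetRegion],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Sample x target table of reads spanning the full inner span."""
    tmap = {t.target_id: t for t in targets}
    sample_order: list[str] = list(samples) if samples else []
    seen = set(sample_order)
    counts: dict[tuple[str, str], int] = {}
    for aln in alignments:
        if aln.sample_id not in seen:
            seen.add(aln.sample_id)
            sample_order.append(aln.sample_id)
        if is_spanning(aln, tmap[aln.target_id]):
            key = (aln.sample_id, aln.target_id)
            counts[key] = counts.get(key, 0) + 1
    tids = [t.target_id for t in targets]
    data = [[counts.get((s, tid), 0) for tid in tids] for s in sample_order]
    return pd.DataFrame(
        data, index=pd.Index(sample_order, name="sample_id"), columns=tids
    )


def write_patterns_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# epiallele patterns over non-primer CpGs, ordered by position\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def patternmap_json(df: pd.DataFrame) -> dict:
    """Plot-ready pattern x sample abundance structure."""
    samples = [c[len("count_"):] for c in df.columns
               if c.startswith("count_") and c != "count_all"]
    out: dict = {"samples": samples, "targets": {}}
    for target_id, sub in df.groupby("target_id", sort=False):
        out["targets"][target_id] = [
            {
                "pattern": row["pattern"],
                "counts": {s: int(row[f"count_{s}"]) for s in samples},
                "frequencies": {s: float(row[f"freq_{s}"]) for s in samples},
                "count_all": int(row["count_all"]),
                "freq_all": float(row["freq_all"]),
            }
            for _, row in sub.iterrows()
        ]
    return out
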