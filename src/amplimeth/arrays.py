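"""Integration of array-based methylation data with sequencing results.

Array platforms (Infinium beadchips, RRBS summaries, ...) report a beta
value in [0,1] per interrogated CpG.  Matching to sequencing-derived
fractions is by exact genomic coordinate of the CpG's forward-strand C —
not probe identifier — so any platform can be supplied once its
coordinates are expressed on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .calling import MethylationMatrix
from .targets import TargetRegion

logger = logging.getLogger(__name__)


class ArrayFormatError(ValueError):
    pass


@dataclass
class ArrayDataset:
    """Per-CpG, per-sample beta values.

    ``betas`` is indexed by (chrom, pos) — pos is the 1-based C position —
    with one column per sample; ``probe_ids`` maps each site to its probe.
    """

    betas: pd.DataFrame
    probe_ids: pd.Series
    n_invalid: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.betas.columns)


def parse_array_file(path) -> ArrayDataset:
    """Parse a TSV of probe_id, chrom, pos, then one beta column per sample.

    Betas outside [0,1] or unparseable become missing (logged); duplicate
    (chrom, pos) keys are a validation error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError as exc:
        raise ArrayFormatError(f"{path}: empty array file") from exc
    required = ["probe_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ArrayFormatError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ArrayFormatError(f"{path}: no sample columns")
    if df.empty:
        raise ArrayFormatError(f"{path}: no data rows")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        keys = df.loc[dup, ["chrom", "pos"]].values.tolist()
        raise ArrayFormatError(f"{path}: duplicate (chrom, pos) keys {keys[:5]}")
    betas = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    out_of_range = (betas < 0) | (betas > 1)
    n_invalid = int(betas.isna().sum().sum() + out_of_range.sum().sum()
                    - df[sample_cols].isna().sum().sum())
    betas = betas.mask(out_of_range)
    if n_invalid:
        logger.warning("%s: %d invalid beta values set to missing", path, n_invalid)
    idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
    betas.index = idx
    probe_ids = pd.Series(df["probe_id"].values, index=idx, name="probe_id")
    return ArrayDataset(betas=betas, probe_ids=probe_ids, n_invalid=n_invalid)


def match_cpgs(
    array: ArrayDataset,
    matrix: MethylationMatrix,
    targets: list[TargetRegion],
) -> tuple[pd.DataFrame, dict]:
    """Join array betas to unmasked sequencing fractions by coordinate.

    Returns a tidy frame (target_id, chrom, pos, sample_id, seq_fraction,
    array_beta) — one row per matched CpG and shared sample where both
    values are present — plus a matching report with unmatched counts.
    """
    tmap = {t.target_id: t for t in targets}
    frac = matrix.fraction
    seq_coord: dict[tuple[str, int], tuple[str, int]] = {}
    for tid, p in matrix.sites:
        t = tmap[tid]
        seq_coord[(t.chrom, t.genomic_cpg_pos(p))] = (tid, p)

    shared = [s for s in matrix.samples if s in array.samples]
    array_keys = set(array.betas.index)
    matched_keys = [k for k in seq_coord if k in array_keys]

    rows = []
    for chrom, gpos in sorted(matched_keys):
        tid, p = seq_coord[(chrom, gpos)]
        for s in shared:
            sf = frac.loc[s, (tid, p)]
            ab = array.betas.loc[(chrom, gpos), s]
            if pd.isna(sf) or pd.isna(ab):
                continue
            rows.append((tid, chrom, gpos, s, float(sf), float(ab)))
    pairs = pd.DataFrame(
        rows,
        columns=["target_id", "chrom", "pos", "sample_id", "seq_fraction", "array_beta"],
    )
    report = {
        "n_pairs": len(pairs),
        "n_matched_cpgs": len(matched_keys),
        "n_unmatched_probes": len(array_keys - set(seq_coord)),
        "n_unmatched_seq_cpgs": len(set(seq_coord) - array_keys),
        "shared_samples": shared,
        "array_only_samples": [s for s in array.samples if s not in matrix.samples],
        "seq_only_samples": [s for s in matrix.samples if s not in array.samples],
    }
    return pairs, report


def _pearson(x: pd.Series, y: pd.Series) -> tuple[float | None, str | None]:
    if len(x) < 3:
        return None, "too-few-pairs"
    if x.nunique() < 2 or y.nunique() < 2:
        return None, "degenerate"
    r = float(stats.pearsonr(x, y).statistic)
    # exactly collinear inputs should report exactly +/-1; the dot-product
    # formulation can land a couple of ulps short
    if 1.0 - abs(r) < 1e-12:
        r = 1.0 if r > 0 else -1.0
    return r, None


def correlate(pairs: pd.DataFrame) -> dict:
    """Pearson correlation between sequencing fractions and array betas.

    Emits the pooled coefficient over all pairs, per-sample coefficients
    (across CpGs), and per-CpG coefficients (across samples); any vector
    with fewer than 3 pairs or zero variance yields a missing value with
    a reason.
    """
    pooled_r, pooled_reason = (
        _pearson(pairs["seq_fraction"], pairs["array_beta"])
        if len(pairs)
        else (None, "too-few-pairs")
    )
    per_sample = {}
    for s, sub in pairs.groupby("sample_id", sort=True):
        r, reason = _pearson(sub["seq_fraction"], sub["array_beta"])
        per_sample[s] = {"r": r, "n": len(sub), "reason": reason}
    per_cpg = {}
    for (chrom, pos), sub in pairs.groupby(["chrom", "pos"], sort=True):
        r, reason = _pearson(sub["seq_fraction"], sub["array_beta"])
        per_cpg[f"{chrom}:{pos}"] = {"r": r, "n": len(sub), "reason": reason}
    return {
        "pooled": {"r": pooled_r, "n": len(pairs), "reason": pooled_reason},
        "per_sample": per_sample,
        "per_cpg": per_cpg,
    }


def write_correlation_tsv(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("level\tkey\tr\tn\treason\n")
        p = report["pooled"]
        fh.write(_row("pooled", "all", p))
        for key, rec in report["per_sample"].items():
            fh.write(_row("sample", key, rec))
        for key, rec in report["per_cpg"].items():
            fh.write(_row("cpg", key, rec))


def _row(level: str, key: str, rec: dict) -> str:
    r = "NA" if rec["r"] is None else f"{rec['r']:.6g}"
    reason = rec["reason"] or ""
    return f"{level}\t{key}\t{r}\t{rec['n']}\t{reason}\n"


def write_scatter_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")
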