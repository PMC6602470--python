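# Methods

## Scope and model

amplimeth analyzes amplicon-based targeted bisulfite sequencing. Its unit
of analysis is a *target*: one amplicon with known (or derivable) sequence,
a forward and a reverse PCR primer, and the CpG sites between them. The
pipeline assumes amplicon data throughout — every read is expected to come
from one of the supplied targets, so alignment is per-target rather than
genome-wide, and reads that fit no target are accounted for (with a
reason) instead of being placed elsewhere.

Methylation is modeled at forward-strand CpG dinucleotides only. Evidence
from the two DNA strands of a CpG is merged onto the forward C position:
the lollipop-style outputs present one value per CpG site, and per-strand
counts exist only internally. CpG methylation is assumed symmetric
(relevant to the simulator; real hemimethylation would appear as
intermediate fractions). Non-CpG cytosine methylation is assumed absent
and is exploited for conversion QC; CHH/CHG calling is out of scope.

## Coordinates

Internal coordinates are 0-based half-open everywhere. The target TSV uses
1-based inclusive genomic coordinates, tabular methylation outputs use
1-based positions (Bismark-coverage convention), and BED exports are
0-based half-open — each format keeps its dominant dialect.

## Primer localization

Primers are located inside the target sequence by ungapped sliding-window
search. Scoring tolerates bisulfite artifacts: on the forward search a
target C may be matched by primer T; on the reverse-complement search a
target G may be matched by primer A. A placement is accepted at ≥ 80%
identity (exact + tolerated matches over primer length); ties go to the
leftmost placement. An unlocatable primer leaves an empty span and the
inner region falls back to the target end, with a logged warning — the run
proceeds because a missing primer annotation should degrade, not abort, an
otherwise valid panel. Indel-containing primer placements are not
searched; amplification primers match their template essentially exactly,
so substitution tolerance suffices. CpGs whose C or G falls inside a
primer span are excluded from calling and from epiallele strings: those
bases are synthesized into the primer, not copied from the template, and
carry no methylation signal.

## Four-strand alignment

Reference variants per target: OT = C→T(S), OB = C→T(R), CTOT = G→A(R),
CTOB = G→A(S), where R is the reverse complement of the forward sequence
S. A read is C→T converted for OT/OB and G→A converted for CTOT/CTOB, and
scored against every variant of every target with semi-global alignment:
the read aligns end to end, reference overhangs are free, match +1,
mismatch −1, and an affine gap of length k costs 3 + k (a flat opening
charge of 3 plus 1 per base). The pairwise DP is delegated to
`Bio.Align.PairwiseAligner` (open −4 on the first gap base, extend −1,
free end-deletions); scoring-only passes over all variants select the
winner and a traceback is computed only for it.

Decisions not fixed by the chemistry, and how they were made:

- **Acceptance threshold.** A placement is valid when score ≥ 0.6 × read
  length. Amplicon reads should match their template near-perfectly after
  conversion; 0.6 rejects random placements (expected score < 0 for
  unrelated sequence) while tolerating a realistic error load.
- **Ties.** If the best score is achieved by more than one (target,
  strand), the read is discarded as ambiguous and counted in QC. Silent
  misassignment would corrupt epiallele tables, and genuine ties are rare
  on real panels; note that short fully-methylated fragments can be
  *inherently* ambiguous (the methylated OT and CTOB products of a
  fragment whose only cytosines are CpGs are the same sequence), which is
  a property of the chemistry, not an implementation artifact.
- **Directionality.** Non-directional (all four strands) is the default;
  `--strand-mode directional` restricts candidates to OT/OB.
- **Length guard.** Reads longer than 1.2 × the longest target cannot be
  amplicon products and are reported unmapped with reason "length".

Aligned pairs store the original (unconverted) read bases projected to
forward orientation — reverse-complemented for OB/CTOT placements — so the
calling step never needs strand-specific sequence logic beyond choosing
the evidence position.

## Read filtering and calling

Whole-read filters: length within [20, 1000] and mean Phred ≥ 20 by
default. Per-base gating happens at calling time: an evidence base with
Phred < 20 yields an AMBIGUOUS call. AMBIGUOUS calls (also produced by
deletions and unexpected bases) are counted but never enter the
methylation fraction. Fractions are masked when informative coverage
(meth + unmeth) is below `min_coverage`, default 10 — a common floor for
amplicon methylation reporting; counts remain visible for masked sites.

The conversion rate is estimated per sample from cytosines outside CpG
context, which are assumed unmethylated: top-strand reads are scored at
forward non-CpG Cs (C unconverted / T converted at p), bottom-strand reads
at bottom-strand cytosines, i.e. forward non-CpG Gs (G / A at the forward
G position). Samples with no observations report a missing rate.

## Epialleles

A read contributes an epiallele only if its alignment covers the whole
inner span, every callable CpG received a call, and none is AMBIGUOUS;
rejections are classified (not-spanning vs ambiguous-call). Requiring the
*inner* span rather than the full target means primer-clipped reads still
count as spanning — the biology lives between the primers. Patterns are
ordered by total count descending, ties broken lexicographically, and no
low-frequency pruning is applied: the table is a complete census, and
display-level pruning belongs to the consumer.

## Array integration

Matching is by exact genomic coordinate of the CpG's forward-strand C, not
by probe identifier, so Infinium, RRBS or any other platform can be
supplied once coordinates are expressed at the forward C. Probes
interrogating the reverse-strand C must be reported at the forward
coordinate by the data provider. Pearson r is emitted pooled over all
(CpG, sample) pairs and also per sample and per CpG, since a single
headline number hides which axis drives agreement. A coefficient needs ≥ 3
pairs and non-zero variance in both vectors; failures report a reason
(`too-few-pairs`, `degenerate`) instead of a number. Exactly collinear
inputs are snapped to ±1.0 when the computed r is within 1e-12, guarding
against the dot-product formulation landing a couple of ulps short.

## Simulator

The simulator emulates the amplicon TBS study design end to end and is the
oracle for the test suite. Per target it builds a random CG-free sequence,
plants exactly the requested number of CpGs in the inner region (never in
the 20 nt CpG-free primers, and spaced ≥ 2 apart so sites never overlap),
and embeds the targets in a single contig separated by CG-free spacers.
Molecules are drawn from a per-target epiallele mixture; mixture
frequencies are realized by largest-remainder allocation (order shuffled)
rather than i.i.d. sampling, so a 0.7/0.3 mixture at n = 1000 yields
exactly 700/300 molecules and noise-free runs recover planted quantities
exactly. Bisulfite chemistry: methylated CpG cytosines survive; every
other cytosine on the emitting strand converts independently with the
configured efficiency (default 1.0). Reads are emitted uniformly over the
allowed strands, with optional uniform substitution errors (default 0),
constant Phred 40, optional truncation (producing non-spanning reads), and
optional jitter on the array betas derived from the planted truth. A
single numpy Generator keyed by `rng_seed` drives every draw, and FASTQ.gz
files are written with a fixed gzip mtime, so simulation output is
byte-reproducible.

What the simulator does **not** emulate — hence what passing tests do not
show about real data: PCR amplification bias and chimeras, indel
sequencing errors, quality decay along reads, hemimethylation,
non-CpG methylation, primer synthesis errors, and sample contamination.
Results on real libraries depend on those factors; the tests establish
correctness of the computation, not robustness to every laboratory
artifact.

## Determinism and degenerate inputs

The analysis pipeline draws no random numbers, iterates in input order,
and breaks all ties deterministically, so re-runs on identical inputs are
byte-identical apart from the QC report's timestamp. Degenerate inputs are
defined rather than fatal: targets with zero CpGs yield empty pattern
strings, samples with zero passed reads report missing fractions and
missing mapping efficiency, targets with no non-CpG cytosines report a
missing conversion rate, and an empty read set produces all-zero tables.
QC count identities (filter accounting; mapped + unmapped + ambiguous =
passed; epiallele counts = accepted spanning reads) are asserted on every
run before the report is written.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use panels of 1–3 targets of
160–180 nt with 4–7 CpGs, 1–5 samples, and 100–1000 reads per sample and
target — ample for exact recovery checks and for binomial error bounds at
the precision reported, while keeping a full run in tens of seconds.
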