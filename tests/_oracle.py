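"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the semi-global
scorer is a plain affine-gap dynamic program, and the four-strand
enumeration below it re-derives the converted references from first
principles.
"""

NEG = float("-inf")

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def semiglobal_score(ref, read, match=1, mismatch=-1, gap_open=-4, gap_ext=-1):
    """Best semi-global score: read fully aligned, free reference ends,
    affine gaps (first gap base gap_open, further bases gap_ext)."""
    n, m = len(ref), len(read)
    if m == 0:
        return 0.0
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read (consumes ref)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in ref (consumes read)
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            prev = max(M[i - 1][j], X[i - 1][j], 0.0 if i == 1 else NEG)
            cand = []
            if prev > NEG:
                cand.append(prev + gap_open)
            if Y[i - 1][j] > NEG:
                cand.append(Y[i - 1][j] + gap_ext)
            Y[i][j] = max(cand) if cand else NEG
            if j >= 1:
                s = match if read[i - 1] == ref[j - 1] else mismatch
                prev = max(
                    M[i - 1][j - 1],
                    X[i - 1][j - 1],
                    Y[i - 1][j - 1],
                    0.0 if i == 1 else NEG,
                )
                M[i][j] = prev + s if prev > NEG else NEG
                cand = []
                prev = max(M[i][j - 1], Y[i][j - 1])
                if prev > NEG:
                    cand.append(prev + gap_open)
                if X[i][j - 1] > NEG:
                    cand.append(X[i][j - 1] + gap_ext)
                X[i][j] = max(cand) if cand else NEG
    return max(max(M[m][j], Y[m][j], X[m][j]) for j in range(n + 1))


def four_strand_refs(seq: str) -> dict[str, str]:
    r = rc(seq)
    return {
        "OT": seq.replace("C", "T"),
        "OB": r.replace("C", "T"),
        "CTOT": r.replace("G", "A"),
        "CTOB": seq.replace("G", "A"),
    }


def best_placements(read: str, target_seqs: dict[str, str]):
    """Exhaustive best (target, strand) set over all four variants.

    Returns (best_score, [(target_id, strand), ...]) with every pair
    achieving the best score listed.
    """
    read_ct = read.replace("C", "T")
    read_ga = read.replace("G", "A")
    best = NEG
    winners = []
    for tid, seq in target_seqs.items():
        for strand, ref in four_strand_refs(seq).items():
            q = read_ct if strand in ("OT", "OB") else read_ga
            s = semiglobal_score(ref, q)
            if s > best:
                best, winners = s, [(tid, strand)]
            elif s == best:
                winners.append((tid, strand))
    return best, winners
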