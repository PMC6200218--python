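"""Independent brute-force oracles used only by tests.

The local-alignment oracle is a plain-Python exhaustive affine-gap dynamic
program (three-state Gotoh), written without reference to the package's
seeded aligner: it scores every cell, so its optimum is the true local
optimum for the scoring scheme (match +1, mismatch -2, gap of length L
costing open + extend*L).
"""

from __future__ import annotations


def sw_best_score(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Optimal local alignment score by exhaustive dynamic programming."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    prev_h = [0] * (m + 1)
    prev_f = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        cur_h = [0] * (m + 1)
        cur_f = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(cur_h[j - 1] + gap_open + gap_extend, e + gap_extend)
            f = max(prev_h[j] + gap_open + gap_extend, prev_f[j] + gap_extend)
            s = match if qc == subject[j - 1] else mismatch
            h = max(0, prev_h[j - 1] + s, e, f)
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, prev_f = cur_h, cur_f
    return best


def gene_relation_oracle(
    ins_start: int,
    ins_end: int,
    gene_start: int,
    gene_end: int,
    gene_strand: str,
    parts: list[tuple[str, int, int]],
    window: int = 100,
) -> str:
    """Direct interval-logic oracle for gene association of one layout."""
    exonic = {"five_prime_UTR", "CDS", "three_prime_UTR"}
    if ins_start < gene_end and gene_start < ins_end:
        hit_kinds = {
            kind for kind, s, e in parts if ins_start < e and s < ins_end
        }
        if hit_kinds & exonic:
            return "exon"
        if "intron" in hit_kinds:
            return "intron"
    if ins_end <= gene_start:
        dist = gene_start - ins_end
        side = "left"
    elif ins_start >= gene_end:
        dist = ins_start - gene_end
        side = "right"
    else:
        return "exon"  # partial overlap always touches a part
    if dist > window:
        return "none"
    upstream = (side == "left") == (gene_strand == "+")
    return "upstream_le100" if upstream else "downstream_le100"
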