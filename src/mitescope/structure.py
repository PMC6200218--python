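"""Structural characterization of MITEs and de novo family discovery.

Covers the element-level structure work: terminal inverted repeat (TIR)
detection, target-site-duplication (TSD) calling against superfamily rules,
position frequency matrices with per-column information content (sequence-logo
arithmetic), haplotype diversity of family members, majority-rule consensus
building, and a de novo scan for TIR+TSD-bounded repeat families not present
in a known catalog — the procedure that surfaces a novel short Stowaway-like
family from a genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from Bio import Align

from ._util import AMBIGUITY, matches_iupac, revcomp
from .align import evalue, local_align
from .catalog import FamilyCatalog, Superfamily, TSDRule, tsd_rule
from .search import InsertionRecord

__all__ = [
    "TIRAnnotation", "TSDCall", "PositionFrequencyMatrix", "DiversityStat",
    "CandidateFamily", "find_tir", "call_tsd", "build_pfm",
    "information_content", "haplotype_diversity", "build_consensus",
    "discover_families",
]

BASES = "ACGT"


@dataclass
class TIRAnnotation:
    tir_len: int
    mismatches: int
    left_seq: str
    right_seq: str

    def __post_init__(self) -> None:
        if len(self.left_seq) != self.tir_len or len(self.right_seq) != self.tir_len:
            raise ValueError("TIR sequences must have length tir_len")
        diff = sum(a != b for a, b in zip(revcomp(self.right_seq), self.left_seq))
        if diff > self.mismatches:
            raise ValueError("right_seq must reverse-complement left_seq "
                             "within the stated mismatch count")


@dataclass
class TSDCall:
    left_tsd: str
    right_tsd: str
    length: int
    matches_superfamily_rule: bool
    short_flank: bool = False


def find_tir(
    element_seq: str, min_len: int = 8, max_len: int = 30, max_mismatch: int = 2
) -> TIRAnnotation | None:
    """Best-supported terminal inverted repeat of the element, or None.

    Compares the length-L prefix with the reverse complement of the length-L
    suffix for every L in [min_len, min(max_len, len//2)].  Among lengths with
    at most ``max_mismatch`` mismatches the reported TIR maximizes
    L - 3*mismatches (ties to the longer L): extending into flanking sequence
    gains one matching position a quarter of the time but costs three
    otherwise, so chance extension past the true repeat is score-negative and
    an exact planted TIR is returned at its planted length.  Strand-symmetric.
    """
    seq = element_seq.upper()
    if len(seq) < 2 * min_len:
        raise ValueError("element shorter than twice the minimum TIR length")
    top = min(max_len, len(seq) // 2)
    best: tuple[int, int] | None = None  # (score, L)
    best_mm = 0
    for L in range(top, min_len - 1, -1):
        mm = sum(a != b for a, b in zip(seq[:L], revcomp(seq[-L:])))
        if mm > max_mismatch:
            continue
        score = L - 3 * mm
        if best is None or (score, L) > best:
            best = (score, L)
            best_mm = mm
    if best is None:
        return None
    L = best[1]
    return TIRAnnotation(tir_len=L, mismatches=best_mm,
                         left_seq=seq[:L], right_seq=seq[-L:])


def call_tsd(
    record: InsertionRecord,
    superfamily: Superfamily,
    family_pattern: str | None = None,
) -> TSDCall:
    """Call the TSD of a retrieved insertion from its immediate flanks.

    Fixed-length rules compare the k-mer just left of the element with the
    k-mer just right of it (k = rule length); the call matches the rule when
    the two k-mers are identical and fit the IUPAC pattern.  Variable-length
    rules take the longest exact left/right duplication whose length falls in
    the rule's range.  Flanks shorter than 10 bp yield a non-matching call
    flagged ``short_flank``.
    """
    rule = tsd_rule(superfamily, family_pattern)
    return call_tsd_rule(record.flank5, record.flank3, rule)


def call_tsd_rule(flank5: str, flank3: str, rule: TSDRule) -> TSDCall:
    if len(flank5) < 10 or len(flank3) < 10:
        return TSDCall("", "", 0, False, short_flank=True)
    flank5, flank3 = flank5.upper(), flank3.upper()
    if rule.is_fixed:
        k = len(rule.pattern)
        left, right = flank5[-k:], flank3[:k]
        ok = left == right and matches_iupac(left, rule.pattern)
        return TSDCall(left, right, k, ok)
    for k in rule.lengths():  # longest first
        if flank5[-k:] == flank3[:k]:
            return TSDCall(flank5[-k:], flank3[:k], k, True)
    return TSDCall("", "", 0, False)


@dataclass
class PositionFrequencyMatrix:
    """Per-position nucleotide counts over a set of aligned sequences.

    ``counts`` is (L, 4) over A/C/G/T; Ns (padding) are excluded from counts,
    so each column sum plus its N-exclusions equals ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (positions, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) > self.n_sequences).any():
            raise ValueError("column sums cannot exceed n_sequences")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def information(self) -> np.ndarray:
        return np.array([information_content(self, i + 1) for i in range(len(self))])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tT\tinformation_bits\n")
            ic = self.information()
            for i, row in enumerate(self.counts):
                fh.write(f"{i + 1}\t" + "\t".join(map(str, row)) + f"\t{ic[i]:.4f}\n")


def build_pfm(seqs: list[str], pad_char: str = "N") -> PositionFrequencyMatrix:
    """Tabulate per-position base counts; unequal lengths are right-padded."""
    if not seqs:
        raise ValueError("need at least one sequence")
    L = max(len(s) for s in seqs)
    counts = np.zeros((L, 4), dtype=int)
    for s in seqs:
        s = s.upper().ljust(L, pad_char)
        for i, b in enumerate(s):
            j = BASES.find(b)
            if j >= 0:
                counts[i, j] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs))


def information_content(pfm: PositionFrequencyMatrix, position: int) -> float:
    """Logo column height in bits: R = 2 - H, H the Shannon entropy of the
    observed base frequencies at the (1-based) position.  In [0, 2]; no
    small-sample correction is applied.
    """
    col = pfm.counts[position - 1]
    total = col.sum()
    if total == 0:
        return 0.0
    f = col[col > 0] / total
    H = -(f * np.log2(f)).sum()
    return float(2.0 - H)


@dataclass
class DiversityStat:
    n: int
    haplotype_freqs: list[float]
    Hd: float


def haplotype_diversity(seqs: list[str]) -> DiversityStat:
    """Haplotype diversity Hd = (n/(n-1)) * (1 - sum p_i^2).

    Haplotypes are distinct sequence strings; Hd is the probability that two
    sequences drawn without replacement are different haplotypes (0 for a
    single haplotype or n = 1, 1 when all sequences are distinct).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    n = len(seqs)
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s.upper()] = counts.get(s.upper(), 0) + 1
    freqs = sorted((c / n for c in counts.values()), reverse=True)
    if n == 1:
        return DiversityStat(1, freqs, 0.0)
    hd = (n / (n - 1)) * (1.0 - sum(p * p for p in freqs))
    return DiversityStat(n, freqs, hd)


# ---------------------------------------------------------------------------
# consensus building
# ---------------------------------------------------------------------------

def _star_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner

def build_consensus(member_seqs: list[str]) -> str:
    """Majority-rule consensus via a center-star alignment.

    The longest member is the star center; every other member is globally
    aligned to it and votes per center column.  A gap majority drops the
    column; base ties become the IUPAC ambiguity code of the tied set.
    Insertions relative to the center are ignored.
    """
    if not member_seqs:
        raise ValueError("need at least one member sequence")
    members = [s.upper() for s in member_seqs]
    center = max(members, key=len)
    L = len(center)
    votes: list[dict[str, int]] = [dict() for _ in range(L)]
    aligner = _star_aligner()
    for seq in members:
        if seq == center:
            for i, b in enumerate(seq):
                votes[i][b] = votes[i].get(b, 0) + 1
            continue
        aln = aligner.align(center, seq)[0]
        cpos = 0
        cseq, mseq = str(aln[0]), str(aln[1])
        for cb, mb in zip(cseq, mseq):
            if cb == "-":
                continue  # insertion in member, ignored
            votes[cpos][mb] = votes[cpos].get(mb, 0) + 1  # mb may be "-" (deletion)
            cpos += 1
    out = []
    for col in votes:
        total = sum(col.values())
        gaps = col.get("-", 0)
        if gaps * 2 > total:
            continue
        bases = {b: c for b, c in col.items() if b in BASES}
        if not bases:
            continue
        top = max(bases.values())
        tied = frozenset(b for b, c in bases.items() if c == top)
        out.append(AMBIGUITY[tied] if len(tied) > 1 else next(iter(tied)))
    return "".join(out)


# ---------------------------------------------------------------------------
# de novo family discovery
# ---------------------------------------------------------------------------

@dataclass
class CandidateFamily:
    consensus_seq: str
    element_len: int
    tir: TIRAnnotation | None
    tsd_pattern: str
    member_loci: list[tuple[str, int, int]]  # (chrom, start, end)
    copy_number: int = field(default=0)

    def __post_init__(self) -> None:
        self.copy_number = len(self.member_loci)


_DISCOVERY_RULES = (
    TSDRule(pattern="TA"),        # Stowaway-like, checked first (cheap)
    TSDRule(pattern="TWA"),       # Tourist-like
    TSDRule(length_range=(7, 10)),  # Mutator-like
)


def _tsd_bounded(seq: str, s: int, e: int) -> str | None:
    """The duplicated target site around [s, e) under any superfamily rule."""
    for rule in _DISCOVERY_RULES:
        if rule.is_fixed:
            k = len(rule.pattern)
            if s < k or e + k > len(seq):
                continue
            left, right = seq[s - k : s], seq[e : e + k]
            if left == right and matches_iupac(left, rule.pattern):
                return left
        else:
            for k in rule.lengths():
                if s < k or e + k > len(seq):
                    continue
                if seq[s - k : s] == seq[e : e + k]:
                    return seq[s - k : s]
    return None


def _identity(a: str, b: str) -> float:
    """Pairwise identity (strand-aware) from edit distance."""
    best = 0.0
    for bb in (b, revcomp(b)):
        d = edlib.align(a, bb, task="distance")["editDistance"]
        best = max(best, 1.0 - d / max(len(a), len(bb)))
    return best


def discover_families(
    genome: dict[str, str],
    known_catalog: FamilyCatalog | None = None,
    min_copies: int = 20,
    len_range: tuple[int, int] = (50, 800),
    min_tir: int = 8,
    identity_cluster: float = 0.80,
    max_tir_mismatch: int = 2,
    known_max_evalue: float = 1e-3,
) -> list[CandidateFamily]:
    """De novo discovery of TIR+TSD-bounded repeat families.

    1. Scan each chromosome for segments whose terminal ``min_tir``-mers are
       reverse complements (seeded by an exact k-mer index), whose length is
       within ``len_range``, which pass :func:`find_tir`, and which are
       bounded by a duplicated target site under a superfamily rule.
    2. Single-linkage cluster candidate segments at >= ``identity_cluster``
       identity (either strand).
    3. Drop clusters whose consensus matches a known catalog consensus at
       e-value <= ``known_max_evalue``.
    4. Report clusters with at least ``min_copies`` members.
    """
    from bisect import bisect_left, bisect_right

    lo, hi = len_range
    candidates: list[tuple[str, int, int, str]] = []  # chrom, start, end, tsd
    k = min(min_tir, 8)
    max_offset = 2  # seed anchors slid inward so a terminal mutation cannot hide a copy
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        index: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)  # positions ascending
        seen_intervals: set[tuple[int, int]] = set()
        for a in range(n - k + 1):
            anchor = seq[a : a + k]
            if "N" in anchor:
                continue
            positions = index.get(revcomp(anchor))
            if not positions:
                continue
            # anchor sits at element offset d (0..max_offset); its reverse
            # complement then ends d bases before the element end, so a match
            # at pos implies e = pos + k + d and s = a - d.
            p_lo = bisect_left(positions, a + lo - k - max_offset)
            p_hi = bisect_right(positions, a + hi - k)
            for pos in positions[p_lo:p_hi]:
                for d in range(max_offset + 1):
                    s, e = a - d, pos + k + d
                    if s < 0 or e > n or not (lo <= e - s <= hi):
                        continue
                    if (s, e) in seen_intervals:
                        continue
                    tsd = _tsd_bounded(seq, s, e)
                    if tsd is None:
                        continue
                    segment = seq[s:e]
                    tir = find_tir(segment, min_len=min_tir,
                                   max_mismatch=max_tir_mismatch)
                    if tir is None:
                        continue
                    seen_intervals.add((s, e))
                    candidates.append((chrom, s, e, tsd))

    if not candidates:
        return []

    # single-linkage clustering on pairwise identity
    seqs = [genome[c][s:e] for c, s, e, _ in candidates]
    n_cand = len(candidates)
    parent = list(range(n_cand))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_cand):
        for j in range(i + 1, n_cand):
            # cheap length pre-filter: identity bound from length difference
            if min(len(seqs[i]), len(seqs[j])) / max(len(seqs[i]), len(seqs[j])) < identity_cluster:
                continue
            if _identity(seqs[i], seqs[j]) >= identity_cluster:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[max(pi, pj)] = min(pi, pj)

    clusters: dict[int, list[int]] = {}
    for i in range(n_cand):
        clusters.setdefault(find(i), []).append(i)

    results: list[CandidateFamily] = []
    for root in sorted(clusters):
        idx = clusters[root]
        # collapse overlapping members at the same locus (nested or
        # boundary-extended TIR variants): prefer the cluster's modal length,
        # since a palindromic TSD lets chance TIR extension shift boundaries
        # at a few loci
        lengths = [candidates[i][2] - candidates[i][1] for i in idx]
        modal_len = max(set(lengths), key=lengths.count)
        chosen: list[int] = []
        for i in sorted(idx, key=lambda i: (
                abs((candidates[i][2] - candidates[i][1]) - modal_len),
                candidates[i][0], candidates[i][1])):
            ci, si, ei, _ = candidates[i]
            if any(cj == ci and sj < ei and si < ej
                   for cj, sj, ej in (candidates[j][:3] for j in chosen)):
                continue
            chosen.append(i)
        if len(chosen) < min_copies:
            continue
        # orient members to the first member's strand before consensus
        ref = seqs[chosen[0]]
        members = []
        for i in chosen:
            s = seqs[i]
            d_f = edlib.align(ref, s, task="distance")["editDistance"]
            d_r = edlib.align(ref, revcomp(s), task="distance")["editDistance"]
            members.append(s if d_f <= d_r else revcomp(s))
        consensus = build_consensus(members)
        # drop candidates matching the known catalog
        if known_catalog is not None and _matches_known(consensus, known_catalog,
                                                        known_max_evalue):
            continue
        tsds = [candidates[i][3] for i in chosen]
        pattern = max(set(tsds), key=tsds.count)
        results.append(
            CandidateFamily(
                consensus_seq=consensus,
                element_len=len(consensus),
                tir=find_tir(consensus, min_len=min_tir,
                             max_mismatch=max_tir_mismatch) if len(consensus) >= 2 * min_tir else None,
                tsd_pattern=pattern,
                member_loci=[candidates[i][:3] for i in chosen],
            )
        )
    results.sort(key=lambda c: -c.copy_number)
    return results


def _matches_known(consensus: str, catalog: FamilyCatalog, max_evalue: float) -> bool:
    clean = consensus.replace("N", "A")  # ambiguity codes never match in scoring
    for fam in catalog:
        if not fam.consensus_seq:
            continue
        for hit in local_align(clean, fam.consensus_seq, min_score=8, seed_len=8):
            if evalue(hit.score, len(consensus), len(fam.consensus_seq)) <= max_evalue:
                return True
    return False
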