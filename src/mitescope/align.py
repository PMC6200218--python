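"""Seeded local alignment with an analytic e-value.

The homology-retrieval contract is "near-full-length local alignment":
candidate loci are found by exact k-mer seeding (default k = 11), seeds are
grouped by diagonal into windows, and each window is resolved by an exact
affine-gap Smith-Waterman dynamic program, so every reported hit carries the
true optimal local score for its interval pair.

Scoring defaults: match +1, mismatch -2, gap open -5, gap extend -2; a gap of
length L costs open + extend*L.  Significance uses the Karlin-Altschul form
E = K*m*n*exp(-lambda*score) with lambda solved exactly for the ungapped
match/mismatch scheme at uniform base composition (for +1/-2 this gives
lambda = ln((3+sqrt(21))/2) ~ 1.3328) and a conservative K = 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._util import revcomp

__all__ = ["Scoring", "AlignmentHit", "local_align", "evalue", "karlin_lambda"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes; non-ACGT (incl. N) maps to 4, never matching."""
    arr = np.full(len(seq), 4, dtype=np.uint8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()

#: Karlin-Altschul K for the default scheme (conservative constant, documented)
KA_K = 0.3


def karlin_lambda(scoring: Scoring = DEFAULT_SCORING) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for the ungapped scheme.

    Uniform base composition: (4*exp(l*match) + 12*exp(l*mismatch)) / 16 = 1.
    Solved by bisection; for +1/-2 the closed form is ln((3+sqrt(21))/2).
    """
    m, x = scoring.match, scoring.mismatch
    if m <= 0 or x >= 0:
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * m) + 0.75 * math.exp(lam * x) - 1.0

    lo, hi = 1e-9, 10.0
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


_LAMBDA_DEFAULT = math.log((3.0 + math.sqrt(21.0)) / 2.0)


def evalue(
    score: int,
    query_len: int,
    genome_len: int,
    scoring: Scoring = DEFAULT_SCORING,
    K: float = KA_K,
) -> float:
    """Expected number of chance local alignments scoring >= ``score``.

    E = K * m * n * exp(-lambda * score); monotonically decreasing in score,
    linear in either sequence length.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    lam = _LAMBDA_DEFAULT if scoring == DEFAULT_SCORING else karlin_lambda(scoring)
    return K * query_len * genome_len * math.exp(-lam * score)


@dataclass
class AlignmentHit:
    """One local alignment of a query (consensus) against a subject interval.

    Subject coordinates are 0-based half-open on the forward strand of the
    subject that was searched; query coordinates are on the query as given.
    """

    chrom: str
    subject_start: int
    subject_end: int
    strand: str
    query_start: int
    query_end: int
    score: int
    identity: float
    evalue: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.subject_end <= self.subject_start:
            raise ValueError("subject_end must exceed subject_start")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@njit(cache=True)
def _sw_kernel(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap Smith-Waterman with traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_match, aln_cols);
    all-zero score returns (0, ...) sentinel.
    """
    n, m = len(q), len(s)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (consumes s)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in subject (consumes q)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    eptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 if E extended from E
    fptr = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                eptr[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                fptr[i, j] = 1
            else:
                F[i, j] = f_open
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i, j = bi, bj
    n_match = 0
    cols = 0
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            cols += 1
            ext = eptr[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            ext = fptr[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, n_match, cols


def smith_waterman(
    query: str, subject: str, scoring: Scoring = DEFAULT_SCORING
) -> tuple[int, int, int, int, int, int, int]:
    """Exact optimal local alignment (score, q0, q1, s0, s1, n_match, cols)."""
    return _sw_kernel(
        encode(query),
        encode(subject),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )


def _seed_windows(
    query: str, subject: str, k: int, band: int
) -> list[tuple[int, int]]:
    """Candidate subject windows from exact k-mer seeds grouped by diagonal."""
    qn, sn = len(query), len(subject)
    index: dict[str, list[int]] = {}
    for i in range(qn - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    seeds: list[tuple[int, int]] = []  # (diagonal, subject pos)
    for j in range(sn - k + 1):
        kmer = subject[j : j + k]
        hits = index.get(kmer)
        if hits:
            for qpos in hits:
                seeds.append((j - qpos, j))
    if not seeds:
        return []
    # cluster: same diagonal band, subject positions within 2*query_len
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for d, j in seeds:
        placed = False
        if clusters:
            last = clusters[-1]
            if abs(d - last[-1][0]) <= band and abs(j - last[-1][1]) <= 2 * qn:
                last.append((d, j))
                placed = True
        if not placed:
            clusters.append([(d, j)])
    windows = []
    for cl in clusters:
        lo = max(0, min(j for _, j in cl) - qn)
        hi = min(sn, max(j for _, j in cl) + k + qn)
        windows.append((lo, hi))
    # merge overlapping windows
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def local_align(
    query: str,
    subject: str,
    scoring: Scoring = DEFAULT_SCORING,
    seed_len: int = 11,
    band: int = 50,
    min_score: int = 16,
    max_hits_per_window: int = 8,
    chrom: str = "",
    strand: str = "+",
) -> list[AlignmentHit]:
    """Maximal-scoring local alignments by seed-and-extend.

    A window with several distinct copies of the query yields several hits:
    after each optimal alignment the aligned subject interval is masked and the
    window realigned until the score falls below ``min_score``.  Overlapping
    hits are resolved by containment, keeping the higher score.  A query
    sharing no ``seed_len``-mer with the subject yields an empty list.
    """
    query = query.upper()
    subject = subject.upper()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    hits: list[AlignmentHit] = []
    for lo, hi in _seed_windows(query, subject, seed_len, band):
        win = encode(subject[lo:hi])
        qcodes = encode(query)
        for _ in range(max_hits_per_window):
            score, q0, q1, s0, s1, n_match, cols = _sw_kernel(
                qcodes,
                win,
                scoring.match,
                scoring.mismatch,
                scoring.gap_open,
                scoring.gap_extend,
            )
            if score < min_score or s1 <= s0:
                break
            hits.append(
                AlignmentHit(
                    chrom=chrom,
                    subject_start=lo + s0,
                    subject_end=lo + s1,
                    strand=strand,
                    query_start=q0,
                    query_end=q1,
                    score=int(score),
                    identity=n_match / cols if cols else 0.0,
                )
            )
            win[s0:s1] = 5  # mask; code 5 never matches
    # containment resolution, best score first; ties by genomic order
    hits.sort(key=lambda h: (-h.score, h.subject_start, h.subject_end))
    kept: list[AlignmentHit] = []
    for h in hits:
        contained = any(
            (k.subject_start <= h.subject_start and h.subject_end <= k.subject_end)
            or (h.subject_start <= k.subject_start and k.subject_end <= h.subject_end)
            for k in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.subject_start, h.subject_end))
    return kept
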