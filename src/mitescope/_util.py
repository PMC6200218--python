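"""Small shared helpers: DNA alphabet, reverse complement, IUPAC matching."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

# IUPAC nucleotide codes -> the set of plain bases each matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# reverse lookup: frozenset of bases -> ambiguity code
AMBIGUITY = {frozenset(v): k for k, v in IUPAC.items()}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff ``seq`` matches ``pattern`` position-by-position (same length)."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq.upper(), pattern.upper()))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. DNA of the given length with expected GC fraction ``gc``."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return "".join(rng.choice(list(DNA), size=length, p=p))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions only (no indels), so planted-copy identity is exactly
    1 - realized substitution fraction.  The realized fraction is capped at
    rate + 0.05, truncating the binomial upper tail so that every emitted
    copy keeps identity >= 1 - rate - 0.05 by construction.
    """
    if rate <= 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    cap = int((rate + 0.05) * len(seq))
    if len(hits) > cap:
        hits = rng.choice(hits, size=cap, replace=False)
    for i in hits:
        choices = [b for b in DNA if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)
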