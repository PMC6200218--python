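"""Homology retrieval of MITE insertions from a genome.

Each family's consensus is used as a local-alignment query against every
chromosome, on both strands.  Hits are kept when (1) the e-value is at most
``max_evalue`` (default 1e-3) and (2) the alignment reaches to within
``end_tol`` (default 20 nt) of *both* consensus termini — so elements
truncated by up to 20 nt at an end are still retrieved as nearly intact,
while fragments missing more than that at either end are rejected.  500 bp of
flanking host sequence is captured on each side for locus identity, TSD
calling and annotation.

Assembly duplicates are removed by exact string identity of element plus both
flanks (only true assembly-level copies collide on 1 kb of i.i.d. flank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from ._util import revcomp
from .align import DEFAULT_SCORING, AlignmentHit, Scoring, evalue, local_align
from .catalog import MITEFamily

__all__ = ["InsertionRecord", "retrieve_insertions", "deduplicate",
           "write_records_tsv", "write_records_bed", "read_records_tsv"]

FLANK_LEN = 500


@dataclass
class InsertionRecord:
    """One retrieved MITE copy with genome-forward sequences.

    ``element_seq`` and both flanks are on the forward strand of the
    chromosome regardless of the hit strand; ``hit.strand`` records element
    orientation.  ``end_gap5``/``end_gap3`` count consensus bases missing at
    the element's own 5'/3' termini.
    """

    family: str
    hit: AlignmentHit
    element_seq: str
    flank5: str
    flank3: str
    flank5_truncated: bool
    flank3_truncated: bool
    end_gap5: int
    end_gap3: int
    tsd_call: object | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.element_seq) != self.hit.subject_end - self.hit.subject_start:
            raise ValueError("element_seq length must match hit interval")
        if len(self.flank5) > FLANK_LEN or len(self.flank3) > FLANK_LEN:
            raise ValueError("flanks must be <= 500 bp")

    @property
    def chrom(self) -> str:
        return self.hit.chrom

    @property
    def start(self) -> int:
        return self.hit.subject_start

    @property
    def end(self) -> int:
        return self.hit.subject_end


def retrieve_insertions(
    genome: Mapping[str, str],
    family: MITEFamily,
    max_evalue: float = 1e-3,
    end_tol: int = 20,
    flank_len: int = FLANK_LEN,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[InsertionRecord]:
    """Retrieve near-full-length copies of ``family`` from ``genome``.

    ``genome`` maps chromosome name to forward-strand sequence.  Returns
    records sorted by (chrom, start); both strands are searched.
    """
    if not family.consensus_seq:
        raise ValueError(f"family {family.name} has no consensus sequence")
    consensus = family.consensus_seq
    qlen = len(consensus)
    genome_len = sum(len(s) for s in genome.values())
    records: list[InsertionRecord] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        hits: list[AlignmentHit] = []
        for strand, query in (("+", consensus), ("-", revcomp(consensus))):
            for h in local_align(query, seq, scoring=scoring, chrom=chrom, strand=strand):
                h.evalue = evalue(h.score, qlen, genome_len, scoring)
                hits.append(h)
        # resolve +/- containment overlaps, best score first
        hits.sort(key=lambda h: (-h.score, h.subject_start))
        kept: list[AlignmentHit] = []
        for h in hits:
            contained = any(
                (k.subject_start <= h.subject_start and h.subject_end <= k.subject_end)
                or (h.subject_start <= k.subject_start and k.subject_end <= h.subject_end)
                for k in kept
            )
            if not contained:
                kept.append(h)
        for h in kept:
            if h.evalue > max_evalue:
                continue
            if h.strand == "+":
                gap5, gap3 = h.query_start, qlen - h.query_end
            else:  # query was the reverse complement: termini swap
                gap5, gap3 = qlen - h.query_end, h.query_start
            if gap5 > end_tol or gap3 > end_tol:
                continue
            s, e = h.subject_start, h.subject_end
            f5 = seq[max(0, s - flank_len) : s]
            f3 = seq[e : e + flank_len]
            records.append(
                InsertionRecord(
                    family=family.name,
                    hit=h,
                    element_seq=seq[s:e],
                    flank5=f5,
                    flank3=f3,
                    flank5_truncated=len(f5) < flank_len,
                    flank3_truncated=len(f3) < flank_len,
                    end_gap5=gap5,
                    end_gap3=gap3,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def deduplicate(records: list[InsertionRecord]) -> list[InsertionRecord]:
    """Drop all but one of any records with identical element + flank strings.

    The survivor is the one first in genomic order (lowest (chrom, start)).
    Idempotent; output sorted by (chrom, start).
    """
    by_key: dict[str, InsertionRecord] = {}
    for rec in sorted(records, key=lambda r: (r.chrom, r.start)):
        key = rec.element_seq + "|" + rec.flank5 + "|" + rec.flank3
        if key not in by_key:
            by_key[key] = rec
    return sorted(by_key.values(), key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "family", "chrom", "start", "end", "strand", "score", "identity",
    "evalue", "end_gap5", "end_gap3", "flank5_truncated", "flank3_truncated",
    "element_seq", "flank5", "flank3",
]


def write_records_tsv(records: list[InsertionRecord], path: str | Path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.family}\t{r.chrom}\t{r.start}\t{r.end}\t{r.hit.strand}\t"
                f"{r.hit.score}\t{r.hit.identity:.4f}\t{r.hit.evalue:.3g}\t"
                f"{r.end_gap5}\t{r.end_gap3}\t{int(r.flank5_truncated)}\t"
                f"{int(r.flank3_truncated)}\t{r.element_seq}\t{r.flank5}\t{r.flank3}\n"
            )


def read_records_tsv(path: str | Path) -> list[InsertionRecord]:
    records = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            if line.startswith("#"):
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            hit = AlignmentHit(
                chrom=row["chrom"],
                subject_start=int(row["start"]),
                subject_end=int(row["end"]),
                strand=row["strand"],
                query_start=0,
                query_end=0,
                score=int(row["score"]),
                identity=float(row["identity"]),
                evalue=float(row["evalue"]),
            )
            records.append(
                InsertionRecord(
                    family=row["family"],
                    hit=hit,
                    element_seq=row["element_seq"],
                    flank5=row["flank5"],
                    flank3=row["flank3"],
                    flank5_truncated=bool(int(row["flank5_truncated"])),
                    flank3_truncated=bool(int(row["flank3_truncated"])),
                    end_gap5=int(row["end_gap5"]),
                    end_gap3=int(row["end_gap3"]),
                )
            )
    return records


def write_records_bed(records: list[InsertionRecord], path: str | Path) -> None:
    """BED6: 0-based half-open, name = family, score = int(identity * 1000)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t"
                f"{int(round(r.hit.identity * 1000))}\t{r.hit.strand}\n"
            )


def write_elements_fasta(records: list[InsertionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f">{r.family}|{r.chrom}:{r.start}-{r.end}({r.hit.strand})\n")
            seq = r.element_seq if r.hit.strand == "+" else revcomp(r.element_seq)
            fh.write(seq + "\n")
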