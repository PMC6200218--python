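"""Genomic-context classification of MITE insertions.

Each insertion is annotated in two complementary ways:

* **sequence homology** — the 5' flank, 3' flank and element body are each
  used as local-alignment queries against the reference sequence sets (gene
  models, a TE library with class I / class II labels, ncRNA); hits are
  filtered at a stringent e-value (default 1e-10), and the single best hit
  (lowest e-value, ties broken by higher score then lexicographic target id)
  fixes the category.  No hit means ``unknown``.
* **interval logic** — the insertion's coordinates are compared with gene
  model intervals to classify gene association: exon overlap beats intron
  overlap, and an insertion within 100 bp (inclusive) of a gene boundary is
  counted as upstream/downstream association by gene strand.

The two agree on planted genomes; they are both reported because homology is
what a reference database supports and interval logic is what gene
coordinates support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .align import evalue, local_align
from .search import InsertionRecord
from .simulate import GeneModel, SyntheticGenome

__all__ = [
    "RefEntry", "ReferenceSet", "AnnotationCall",
    "annotate_insertion", "classify_gene_association", "locate_in_transcript",
]

CATEGORIES = ("protein_coding_gene", "TE_classI", "TE_classII", "ncRNA", "unknown")

EXONIC_KINDS = ("five_prime_UTR", "CDS", "three_prime_UTR")


@dataclass
class RefEntry:
    target_id: str
    category: str  # protein_coding_gene | TE_classI | TE_classII | ncRNA
    seq: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES[:-1]:
            raise ValueError(f"bad category {self.category!r}")
        self.seq = self.seq.upper()


@dataclass
class ReferenceSet:
    entries: list[RefEntry] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(e.seq) for e in self.entries)

    @classmethod
    def from_synthetic(cls, genome: SyntheticGenome) -> "ReferenceSet":
        """Reference entries from a simulated genome.

        Gene entries are the pre-insertion genomic spans (unspliced, so intron
        flanks hit them); TE entries are the pre-insertion host sequences with
        their class labels.  Using pre-insertion sequences mirrors a curated
        library, whose entries do not carry the nested insertions of any one
        assembly.
        """
        entries = [
            RefEntry(g.gene_id, "protein_coding_gene", g.ref_seq)
            for g in genome.genes
        ] + [
            RefEntry(t.te_id, f"TE_{t.te_class}", t.library_seq)
            for t in genome.te_hosts
        ]
        return cls(entries=entries, gene_models=list(genome.genes))

    @classmethod
    def from_gff3_fasta(
        cls,
        gene_gff3: str | Path,
        genome_fasta: str | Path,
        te_gff3: str | Path | None = None,
    ) -> "ReferenceSet":
        """Load gene models (and optionally TE intervals) from GFF3 + FASTA."""
        import gffutils
        from pyfaidx import Fasta

        fasta = Fasta(str(genome_fasta))
        db = gffutils.create_db(
            str(gene_gff3), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        genes: list[GeneModel] = []
        entries: list[RefEntry] = []
        for gene in db.features_of_type("gene"):
            parts: list[tuple[str, int, int]] = []
            for kind in ("five_prime_UTR", "CDS", "intron", "three_prime_UTR"):
                for feat in db.children(gene, featuretype=kind):
                    parts.append((kind, feat.start - 1, feat.end))
            parts.sort(key=lambda p: p[1])
            seq = str(fasta[gene.seqid][gene.start - 1 : gene.end])
            genes.append(
                GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end,
                          gene.strand, parts, ref_seq=seq.upper())
            )
            entries.append(RefEntry(gene.id, "protein_coding_gene", seq))
        if te_gff3 is not None:
            te_db = gffutils.create_db(
                str(te_gff3), ":memory:", merge_strategy="create_unique",
                keep_order=True,
            )
            for te in te_db.features_of_type("transposable_element"):
                cls_attr = te.attributes.get("class", ["classII"])[0]
                seq = str(fasta[te.seqid][te.start - 1 : te.end])
                entries.append(RefEntry(te.id, f"TE_{cls_attr}", seq))
        return cls(entries=entries, gene_models=genes)


@dataclass
class AnnotationCall:
    category: str
    target_id: str | None
    best_evalue: float | None
    gene_relation: str  # intron | exon | upstream_le100 | downstream_le100 | none
    distance_to_gene: int | None
    #: best hit per query kind (flank5/flank3/body): (target_id, evalue)
    query_hits: dict[str, tuple[str, float]] = field(default_factory=dict)


def _best_hit(query: str, refs: ReferenceSet, max_evalue: float):
    """Best (evalue, -score, target_id, category) hit of one query, or None."""
    best = None
    total = refs.total_length
    for entry in refs.entries:
        for hit in local_align(query, entry.seq):
            ev = evalue(hit.score, len(query), total)
            if ev > max_evalue:
                continue
            key = (ev, -hit.score, entry.target_id)
            if best is None or key < best[0]:
                best = (key, entry)
    return best


def annotate_insertion(
    record: InsertionRecord,
    refs: ReferenceSet,
    max_evalue: float = 1e-10,
) -> AnnotationCall:
    """Classify one insertion by its best reference hit plus interval logic.

    An empty reference set (or no hit at the e-value cutoff) yields category
    ``unknown``; gene relation is still computed from gene model intervals.
    """
    queries = {
        "flank5": record.flank5,
        "flank3": record.flank3,
        "body": record.element_seq,
    }
    pooled = None
    query_hits: dict[str, tuple[str, float]] = {}
    for name, seq in queries.items():
        if not seq:
            continue
        best = _best_hit(seq, refs, max_evalue)
        if best is not None:
            key, entry = best
            query_hits[name] = (entry.target_id, key[0])
            if pooled is None or key < pooled[0]:
                pooled = best
    relation, distance = classify_gene_association(record, refs.gene_models)
    if pooled is None:
        return AnnotationCall("unknown", None, None, relation, distance, query_hits)
    key, entry = pooled
    return AnnotationCall(
        category=entry.category,
        target_id=entry.target_id,
        best_evalue=key[0],
        gene_relation=relation,
        distance_to_gene=distance,
        query_hits=query_hits,
    )


def classify_gene_association(
    record,
    gene_models: list[GeneModel],
    window: int = 100,
) -> tuple[str, int | None]:
    """Gene relation of an insertion interval: (relation, distance).

    Exon overlap (any transcribed non-intron part) wins over intron overlap;
    otherwise an insertion at most ``window`` bp (inclusive) from the nearest
    gene boundary is upstream/downstream by gene strand; else ``none``.
    Distance is 0 for overlaps, else base pairs between element boundary and
    gene boundary in half-open arithmetic; None when no gene is on the
    chromosome.
    """
    chrom, start, end = record.chrom, record.start, record.end
    exon_hit = intron_hit = False
    best_dist: int | None = None
    best_rel = "none"
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if start < g.end and g.start < end:  # overlaps the gene span
            for kind, s, e in g.parts:
                if start < e and s < end:
                    if kind in EXONIC_KINDS:
                        exon_hit = True
                    elif kind == "intron":
                        intron_hit = True
            best_dist = 0
            continue
        dist = g.start - end if end <= g.start else start - g.end
        if best_dist is None or dist < best_dist:
            best_dist = dist
        if dist <= window:
            element_is_left = end <= g.start
            upstream = element_is_left == (g.strand == "+")
            rel = "upstream_le100" if upstream else "downstream_le100"
            if best_rel == "none" or dist <= (best_dist or dist):
                best_rel = rel
    if exon_hit:
        return "exon", 0
    if intron_hit:
        return "intron", 0
    return best_rel, best_dist


def locate_in_transcript(
    interval: tuple[int, int],
    transcript_parts: list[tuple[str, int, int]],
    spanning_fraction: float = 0.10,
) -> str:
    """Transcript region containing an insertion: 5'UTR, CDS, 3'UTR or spanning.

    ``transcript_parts`` are (kind, start, end) in the same coordinate space as
    ``interval``.  The call is the region holding the insertion midpoint,
    except when the insertion crosses a region boundary with more than
    ``spanning_fraction`` of its length on each side, which is ``spanning``.
    """
    start, end = interval
    if end <= start:
        raise ValueError("empty interval")
    name_map = {
        "five_prime_UTR": "five_prime_utr",
        "CDS": "cds",
        "three_prime_UTR": "three_prime_utr",
    }
    length = end - start
    overlaps: dict[str, int] = {}
    for kind, s, e in transcript_parts:
        if kind not in name_map:
            continue
        ov = min(end, e) - max(start, s)
        if ov > 0:
            overlaps[name_map[kind]] = overlaps.get(name_map[kind], 0) + ov
    deep = [k for k, ov in overlaps.items() if ov > spanning_fraction * length]
    if len(deep) >= 2:
        return "spanning"
    mid = (start + end) // 2
    for kind, s, e in transcript_parts:
        if kind in name_map and s <= mid < e:
            return name_map[kind]
    if overlaps:
        return max(overlaps, key=overlaps.get)
    raise ValueError("insertion does not overlap the transcript")
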