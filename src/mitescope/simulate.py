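"""Synthetic allopolyploid genomes with planted MITE insertions.

The simulator emulates the situation the pipeline is built for: a
multi-chromosome genome split into labeled sub-genomes (A/B/D), carrying gene
models (5'UTR / CDS with at least one intron / 3'UTR), large synthetic host
TEs (class I / class II, 3-16 kb), and planted MITE copies at controlled
per-site divergence.  Each copy is inserted with its target-site duplication
(TSD) written on both sides, exactly as a cut-and-paste insertion into a
target site would leave it, and every copy is recorded in a ground-truth
table (family, coordinates, strand, TSD, genomic context, lineage).

The background is i.i.d. nucleotides at a configurable GC content, so any
sequence similarity between unrelated loci is chance alone; this keeps
false-positive analysis of the downstream search interpretable.

``derive_polyploid`` merges two parental genomes into an allopolyploid child:
each parental insertion is inherited with a given probability, otherwise it is
excised cleanly, leaving a single TSD copy at the empty site (the simulator's
documented excision convention); fresh child-unique insertions are then added.
Lineage labels (inherited / parent_unique / child_unique) make the child an
oracle for common-insertion analysis.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._util import IUPAC, mutate, random_dna, revcomp
from .catalog import MITEFamily, TSDRule

__all__ = [
    "SyntheticGenomeSpec",
    "TruthRecord",
    "TruthSet",
    "SyntheticGenome",
    "GeneModel",
    "TEHost",
    "generate_genome",
    "derive_polyploid",
    "sample_tsd",
]

CONTEXTS = (
    "intergenic",
    "TE_classI",
    "TE_classII",
    "gene_intron",
    "gene_exon",
    "gene_5utr",
    "gene_3utr",
    "upstream_le100",
    "downstream_le100",
)


@dataclass
class GeneModel:
    """A gene with strand-aware parts given as genomic (kind, start, end)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parts: list[tuple[str, int, int]]  # five_prime_UTR/CDS/intron/three_prime_UTR
    #: genomic span sequence before any MITE was planted (the reference entry)
    ref_seq: str = ""


@dataclass
class TEHost:
    te_id: str
    chrom: str
    start: int
    end: int
    te_class: str  # "classI" | "classII"
    #: host sequence before any MITE was nested into it (the library entry)
    library_seq: str = ""


@dataclass
class TruthRecord:
    family: str
    chrom: str
    subgenome: str
    start: int
    end: int
    strand: str
    planted_tsd: str
    context: str
    lineage: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)
    chrom_subgenome: dict[str, str] = field(default_factory=dict)
    #: parental insertions lost on the way to a derived polyploid
    parent_unique: list[TruthRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: (r.chrom, r.start, r.end, r.family))
        seen = set()
        for r in self.records:
            key = (r.chrom, r.start, r.end, r.family)
            if key in seen:
                raise ValueError(f"duplicate truth record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def lineage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.lineage or "unassigned"] = counts.get(r.lineage or "unassigned", 0) + 1
        return counts


@dataclass
class SyntheticGenomeSpec:
    subgenome_labels: list[str] = field(default_factory=lambda: ["A", "B"])
    n_chromosomes: int = 2  # per sub-genome; named "<group><label>"
    chromosome_length: int = 200_000
    gc_content: float = 0.46
    #: (family, copies, per-site divergence rate) triples
    families_to_plant: list[tuple[MITEFamily, int, float]] = field(default_factory=list)
    #: context -> fraction; remainder of mass is intergenic
    nesting_fractions: dict[str, float] = field(default_factory=dict)
    genes_per_chromosome: int = 5
    te_hosts_per_chromosome: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        total = 0.0
        for ctx, frac in self.nesting_fractions.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("nesting fractions must be in [0, 1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError("nesting fractions must sum to <= 1")
        for fam, copies, rate in self.families_to_plant:
            if copies < 0:
                raise ValueError("copies must be >= 0")
            if not 0.0 <= rate < 1.0:
                raise ValueError("divergence_rate must be in [0, 1)")
            if not fam.consensus_seq:
                raise ValueError(f"family {fam.name} lacks a consensus sequence")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    chrom_subgenome: dict[str, str]
    genes: list[GeneModel]
    te_hosts: list[TEHost]
    truth: TruthSet
    families: dict[str, MITEFamily]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    # ---------------- writers (plain text formats) ----------------

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_chrom_metadata(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tsubgenome\tlength\n")
            for name in sorted(self.sequences):
                fh.write(
                    f"{name}\t{self.chrom_subgenome[name]}\t{len(self.sequences[name])}\n"
                )

    def write_genes_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(
                    f"{g.chrom}\tmitescope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                fh.write(
                    f"{g.chrom}\tmitescope\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n"
                )
                for i, (kind, s, e) in enumerate(g.parts):
                    fh.write(
                        f"{g.chrom}\tmitescope\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}"
                        f"\t.\tID={g.gene_id}.1.{kind}.{i};Parent={g.gene_id}.1\n"
                    )

    def write_tes_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in sorted(self.te_hosts, key=lambda t: (t.chrom, t.start)):
                fh.write(
                    f"{t.chrom}\tmitescope\ttransposable_element\t{t.start + 1}\t"
                    f"{t.end}\t.\t+\t.\tID={t.te_id};class={t.te_class}\n"
                )

    def write_te_library_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.te_hosts:
                fh.write(f">{t.te_id} class={t.te_class}\n{t.library_seq}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        write_truth_tsv(self.truth, path)


def write_truth_tsv(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family\tchrom\tsubgenome\tstart\tend\tstrand\tplanted_tsd\t"
            "context\tlineage\n"
        )
        for r in truth.records:
            fh.write(
                f"{r.family}\t{r.chrom}\t{r.subgenome}\t{r.start}\t{r.end}\t"
                f"{r.strand}\t{r.planted_tsd}\t{r.context}\t{r.lineage or ''}\n"
            )


def read_truth_tsv(path: str | Path, chrom_subgenome: dict[str, str] | None = None) -> TruthSet:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(
                TruthRecord(
                    family=row["family"],
                    chrom=row["chrom"],
                    subgenome=row["subgenome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    planted_tsd=row["planted_tsd"],
                    context=row["context"],
                    lineage=row["lineage"] or None,
                )
            )
    return TruthSet(records=records, chrom_subgenome=chrom_subgenome or {})


def sample_tsd(rule: TSDRule, rng: np.random.Generator) -> str:
    """Draw a concrete TSD under a rule.

    Fixed IUPAC patterns sample each ambiguous position uniformly from its
    base set; the 7-10 bp unconstrained rule uses a uniform random 9-mer;
    other length ranges draw the length uniformly.
    """
    if rule.pattern is not None:
        return "".join(
            b if b in "ACGT" else rng.choice(list(IUPAC[b])) for b in rule.pattern
        )
    lo, hi = rule.length_range
    k = 9 if (lo, hi) == (7, 10) else int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=k))


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------


def _place_intervals(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: list[int],
    occupied: list[tuple[int, int]],
    margin: int = 300,
) -> list[tuple[int, int]]:
    """Non-overlapping random intervals, margin-separated from ``occupied``.

    Each interval is placed uniformly within the free gaps that can hold it
    (largest intervals first, so fragmentation cannot starve them); results
    are returned in the order of ``lengths``.
    """
    taken = sorted((s - margin, e + margin) for s, e in occupied)
    placed: list[tuple[int, int] | None] = [None] * len(lengths)
    for idx in sorted(range(len(lengths)), key=lambda i: -lengths[i]):
        length = lengths[idx]
        # merge taken intervals, then enumerate free gaps within the margins
        merged: list[list[int]] = []
        for s, e in sorted(taken):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps: list[tuple[int, int]] = []
        prev = margin
        for s, e in merged:
            if s > prev:
                gaps.append((prev, min(s, chrom_len - margin)))
            prev = max(prev, e)
        if prev < chrom_len - margin:
            gaps.append((prev, chrom_len - margin))
        fits = [(lo, hi) for lo, hi in gaps if hi - lo >= length]
        if not fits:
            raise RuntimeError("could not place feature: chromosome too crowded")
        weights = np.array([hi - lo - length + 1 for lo, hi in fits], dtype=float)
        lo, hi = fits[int(rng.choice(len(fits), p=weights / weights.sum()))]
        start = int(rng.integers(lo, hi - length + 1))
        placed[idx] = (start, start + length)
        taken.append((start - margin, start + length + margin))
    return placed  # type: ignore[return-value]


def _make_gene(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    """Fixed gene architecture: UTR5(200) CDS(400) intron(500) CDS(400) UTR3(300)."""
    lens5 = [("five_prime_UTR", 200), ("CDS", 400), ("intron", 500), ("CDS", 400), ("three_prime_UTR", 300)]
    if strand == "-":
        lens5 = lens5[::-1]
    parts = []
    pos = start
    for kind, length in lens5:
        parts.append((kind, pos, pos + length))
        pos += length
    return GeneModel(gene_id, chrom, start, pos, strand, parts)


GENE_SPAN = 1800  # total genomic span of the fixed gene architecture


class _Assembler:
    """Applies insertions to one chromosome while shifting tracked intervals.

    Insertion at point p with element E and TSD t rewrites
    ``seq[:p-k] + t + E + t + seq[p:]`` (k = len(t)): the left TSD copy
    overwrites the k host bases before p, so coordinates < p are unchanged and
    coordinates >= p shift right by len(E) + k.  The element occupies
    [p, p+len(E)) in the new coordinates.
    """

    def __init__(self, seq: str):
        self.seq = seq
        # pending: (point, element_seq, tsd, payload dict)
        self.pending: list[tuple[int, str, str, dict]] = []

    def add(self, point: int, element: str, tsd: str, payload: dict) -> None:
        self.pending.append((point, element, tsd, payload))

    def used_points(self) -> list[int]:
        return [p for p, _, _, _ in self.pending]

    def apply(
        self, track: list[list[int]]
    ) -> tuple[str, list[dict]]:
        """Build the final sequence.

        ``track`` is a list of [start, end] interval pairs mutated in place to
        final coordinates (start shifts when >= p; end shifts when > p, so an
        insertion inside an interval extends it).  Returns the new sequence and
        the payloads with final element coordinates filled in.
        """
        self.pending.sort(key=lambda t: t[0])
        pieces: list[str] = []
        prev = 0
        offset = 0
        out: list[dict] = []
        for p, element, tsd, payload in self.pending:
            k = len(tsd)
            pieces.append(self.seq[prev : p - k])
            pieces.append(tsd)
            pieces.append(element)
            pieces.append(tsd)
            prev = p
            point = p + offset  # insertion point in current (shifted) coordinates
            payload = dict(payload)
            payload["start"] = point
            payload["end"] = point + len(element)
            out.append(payload)
            shift = len(element) + k
            for iv in track:
                if iv[0] >= point:
                    iv[0] += shift
                if iv[1] > point:
                    iv[1] += shift
            offset += shift
        pieces.append(self.seq[prev:])
        return "".join(pieces), out


def _pick_context(
    rng: np.random.Generator, nesting: dict[str, float]
) -> str:
    contexts = list(nesting.keys())
    probs = [nesting[c] for c in contexts]
    rest = 1.0 - sum(probs)
    if rest > 1e-12 or not contexts:
        contexts.append("intergenic")
        probs.append(max(rest, 0.0))
    probs = np.asarray(probs) / sum(probs)
    return contexts[int(rng.choice(len(contexts), p=probs))]


def _sample_point(
    rng: np.random.Generator,
    context: str,
    chrom_len: int,
    genes: list[GeneModel],
    tes: list[TEHost],
    used: list[int],
    tsd_len: int,
    min_sep: int = 40,
    tries: int = 400,
    avoid: list[tuple[int, int]] | None = None,
) -> int | None:
    """An insertion point realizing ``context`` in pre-insertion coordinates."""
    feature_zones = [(g.start - 150, g.end + 150) for g in genes] + [
        (t.start, t.end) for t in tes
    ]
    for _ in range(tries):
        if context == "intergenic":
            p = int(rng.integers(600, chrom_len - 600))
            if any(lo <= p < hi for lo, hi in feature_zones):
                continue
        elif context in ("TE_classI", "TE_classII"):
            cls = context.removeprefix("TE_")
            pool = [t for t in tes if t.te_class == cls]
            if not pool:
                return None
            t = pool[int(rng.integers(len(pool)))]
            p = int(rng.integers(t.start + 120, t.end - 120))
        elif context in ("gene_intron", "gene_exon", "gene_5utr", "gene_3utr"):
            kind = {
                "gene_intron": "intron",
                "gene_exon": "CDS",
                "gene_5utr": "five_prime_UTR",
                "gene_3utr": "three_prime_UTR",
            }[context]
            if not genes:
                return None
            g = genes[int(rng.integers(len(genes)))]
            parts = [(s, e) for k, s, e in g.parts if k == kind]
            s, e = parts[int(rng.integers(len(parts)))]
            p = int(rng.integers(s + 15, e - 15))
        elif context in ("upstream_le100", "downstream_le100"):
            if not genes:
                return None
            g = genes[int(rng.integers(len(genes)))]
            left = (context == "upstream_le100") == (g.strand == "+")
            if left:
                # distance after insertion = gene_start + tsd_len - p
                p = int(rng.integers(g.start - 90 + tsd_len, g.start - 1))
            else:
                p = int(rng.integers(g.end + 2, g.end + 90))
        else:  # pragma: no cover
            raise ValueError(context)
        if p < tsd_len + 1 or p >= chrom_len - 1:
            continue
        if any(abs(p - u) < min_sep for u in used):
            continue
        if avoid and any(lo - min_sep <= p < hi + min_sep for lo, hi in avoid):
            continue
        return p
    return None


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build a genome per the spec; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [
        f"{group}{label}"
        for label in spec.subgenome_labels
        for group in range(1, spec.n_chromosomes + 1)
    ]
    chrom_subgenome = {
        name: name[-1] if name[-1] in "ABD" else "unknown" for name in chrom_names
    }

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    te_hosts: list[TEHost] = []
    per_chrom_genes: dict[str, list[GeneModel]] = {}
    per_chrom_tes: dict[str, list[TEHost]] = {}

    for name in chrom_names:
        seq = random_dna(rng, spec.chromosome_length, spec.gc_content)
        sequences[name] = seq
        occupied: list[tuple[int, int]] = []
        gene_ivs = _place_intervals(
            rng, spec.chromosome_length, [GENE_SPAN] * spec.genes_per_chromosome, occupied
        )
        occupied += gene_ivs
        # hosts are 3-16 kb, capped so they cannot crowd out small test chromosomes
        te_hi = max(3_001, min(16_001, spec.chromosome_length // 8))
        te_lens = [
            int(rng.integers(3_000, te_hi)) for _ in range(spec.te_hosts_per_chromosome)
        ]
        te_ivs = _place_intervals(rng, spec.chromosome_length, te_lens, occupied)
        cg = []
        for i, (s, _e) in enumerate(gene_ivs):
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(f"gene_{name}_{i}", name, s, strand)
            gene.ref_seq = seq[gene.start : gene.end]
            cg.append(gene)
        ct = []
        for i, (s, e) in enumerate(te_ivs):
            cls = "classII" if i % 2 == 0 else "classI"
            ct.append(TEHost(f"te_{name}_{i}", name, s, e, cls, library_seq=seq[s:e]))
        per_chrom_genes[name] = cg
        per_chrom_tes[name] = ct
        genes += cg
        te_hosts += ct

    # ---- plan insertions per chromosome ----
    assemblers = {name: _Assembler(sequences[name]) for name in chrom_names}
    for fam, copies, rate in spec.families_to_plant:
        rule = fam.rule
        for _ in range(copies):
            context = _pick_context(rng, spec.nesting_fractions)
            tsd = sample_tsd(rule, rng)
            placed = False
            order = rng.permutation(len(chrom_names))
            for ci in order:
                name = chrom_names[int(ci)]
                p = _sample_point(
                    rng,
                    context,
                    spec.chromosome_length,
                    per_chrom_genes[name],
                    per_chrom_tes[name],
                    assemblers[name].used_points(),
                    len(tsd),
                )
                if p is None:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                element = mutate(rng, fam.consensus_seq, rate)
                if strand == "-":
                    element = revcomp(element)
                assemblers[name].add(
                    p,
                    element,
                    tsd,
                    {
                        "family": fam.name,
                        "strand": strand,
                        "planted_tsd": tsd,
                        "context": context,
                        "chrom": name,
                    },
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"requested copies of {fam.name} exceed available placement "
                    f"space for context {context!r}"
                )

    # ---- apply insertions, shifting feature coordinates ----
    records: list[TruthRecord] = []
    for name in chrom_names:
        track: list[list[int]] = []
        handles: list[tuple[object, str | int]] = []
        for g in per_chrom_genes[name]:
            iv = [g.start, g.end]
            track.append(iv)
            handles.append((g, "span"))
            for idx, (kind, s, e) in enumerate(g.parts):
                piv = [s, e]
                track.append(piv)
                handles.append((g, idx))
        for t in per_chrom_tes[name]:
            iv = [t.start, t.end]
            track.append(iv)
            handles.append((t, "span"))
        new_seq, payloads = assemblers[name].apply(track)
        sequences[name] = new_seq
        # write shifted coordinates back
        for iv, (obj, which) in zip(track, handles):
            if which == "span":
                obj.start, obj.end = iv
            else:
                kind, _s, _e = obj.parts[which]
                obj.parts[which] = (kind, iv[0], iv[1])
        for pl in payloads:
            records.append(
                TruthRecord(
                    family=pl["family"],
                    chrom=name,
                    subgenome=chrom_subgenome[name],
                    start=pl["start"],
                    end=pl["end"],
                    strand=pl["strand"],
                    planted_tsd=pl["planted_tsd"],
                    context=pl["context"],
                )
            )

    truth = TruthSet(records=records, chrom_subgenome=dict(chrom_subgenome))
    return SyntheticGenome(
        sequences=sequences,
        chrom_subgenome=dict(chrom_subgenome),
        genes=genes,
        te_hosts=te_hosts,
        truth=truth,
        families={f.name: f for f, _c, _r in spec.families_to_plant},
    )


def derive_polyploid(
    parent1: SyntheticGenome,
    parent2: SyntheticGenome | None,
    inherit_fraction: float,
    n_new: int,
    seed: int,
    new_family_pool: list[str] | None = None,
) -> SyntheticGenome:
    """Merge parents into an allopolyploid child.

    Every parental chromosome is carried over.  Each parental insertion is
    retained with probability ``inherit_fraction`` (lineage ``inherited``);
    otherwise it is excised, removing the element plus one TSD copy so exactly
    one TSD remains at the empty site, and the lost record is kept under
    ``truth.parent_unique`` (lineage ``parent_unique``, parental coordinates).
    ``n_new`` fresh intergenic insertions are then planted (lineage
    ``child_unique``) drawing families from ``new_family_pool`` (default: all
    parental families).
    """
    if not 0.0 <= inherit_fraction <= 1.0:
        raise ValueError("inherit_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    parents = [parent1] + ([parent2] if parent2 is not None else [])
    names = [c for p in parents for c in p.sequences]
    if len(set(names)) != len(names):
        raise ValueError("parental chromosome names must be disjoint")

    sequences: dict[str, str] = {}
    chrom_subgenome: dict[str, str] = {}
    genes: list[GeneModel] = []
    te_hosts: list[TEHost] = []
    families: dict[str, MITEFamily] = {}
    inherited: list[TruthRecord] = []
    lost: list[TruthRecord] = []

    for parent in parents:
        families.update(parent.families)
        chrom_subgenome.update(parent.chrom_subgenome)
        for chrom, seq in parent.sequences.items():
            recs = [r for r in parent.truth.records if r.chrom == chrom]
            keep_mask = rng.random(len(recs)) < inherit_fraction
            # excise non-inherited, ascending, tracking the shift
            pieces: list[str] = []
            prev = 0
            offset = 0
            shifts: list[tuple[int, int]] = []  # (orig position, cumulative shift after)
            for r, keep in zip(recs, keep_mask):
                if keep:
                    continue
                k = len(r.planted_tsd)
                pieces.append(seq[prev : r.start])
                prev = r.end + k  # drop element + right TSD copy
                offset -= (r.end - r.start) + k
                shifts.append((r.start, offset))
                lost.append(replace(r, lineage="parent_unique"))
            pieces.append(seq[prev:])
            sequences[chrom] = "".join(pieces)

            def shifted(pos: int) -> int:
                off = 0
                for orig, cum in shifts:
                    if pos >= orig:
                        off = cum
                    else:
                        break
                return pos + off

            for r, keep in zip(recs, keep_mask):
                if keep:
                    inherited.append(
                        replace(
                            r,
                            start=shifted(r.start),
                            end=shifted(r.start) + (r.end - r.start),
                            lineage="inherited",
                        )
                    )
            for g in parent.genes:
                if g.chrom != chrom:
                    continue
                genes.append(
                    GeneModel(
                        g.gene_id,
                        chrom,
                        shifted(g.start),
                        shifted(g.end),
                        g.strand,
                        [(k, shifted(s), shifted(e)) for k, s, e in g.parts],
                        ref_seq=g.ref_seq,
                    )
                )
            for t in parent.te_hosts:
                if t.chrom != chrom:
                    continue
                te_hosts.append(
                    TEHost(
                        t.te_id, chrom, shifted(t.start), shifted(t.end),
                        t.te_class, t.library_seq,
                    )
                )

    # ---- plant fresh child-unique insertions (intergenic) ----
    pool = new_family_pool or sorted(families)
    chrom_names = sorted(sequences)
    per_chrom_genes = {c: [g for g in genes if g.chrom == c] for c in chrom_names}
    per_chrom_tes = {c: [t for t in te_hosts if t.chrom == c] for c in chrom_names}
    assemblers = {c: _Assembler(sequences[c]) for c in chrom_names}
    existing = {
        c: [[r.start, r.end] for r in inherited if r.chrom == c] for c in chrom_names
    }
    child_new_handles: dict[str, list[TruthRecord]] = {c: [] for c in chrom_names}
    for i in range(n_new):
        fam = families[pool[int(rng.integers(len(pool)))]]
        tsd = sample_tsd(fam.rule, rng)
        placed = False
        order = rng.permutation(len(chrom_names))
        for ci in order:
            chrom = chrom_names[int(ci)]
            p = _sample_point(
                rng,
                "intergenic",
                len(sequences[chrom]),
                per_chrom_genes[chrom],
                per_chrom_tes[chrom],
                assemblers[chrom].used_points(),
                len(tsd),
                avoid=[(s, e) for s, e in existing[chrom]],
            )
            if p is None:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            element = fam.consensus_seq
            if strand == "-":
                element = revcomp(element)
            assemblers[chrom].add(
                p, element, tsd,
                {"family": fam.name, "strand": strand, "planted_tsd": tsd,
                 "context": "intergenic", "chrom": chrom},
            )
            placed = True
            break
        if not placed:
            raise RuntimeError("no space left for new child insertions")

    records: list[TruthRecord] = []
    for chrom in chrom_names:
        track: list[list[int]] = []
        handles: list[tuple[object, str | int]] = []
        for g in per_chrom_genes[chrom]:
            track.append([g.start, g.end])
            handles.append((g, "span"))
            for idx in range(len(g.parts)):
                _k, s, e = g.parts[idx]
                track.append([s, e])
                handles.append((g, idx))
        for t in per_chrom_tes[chrom]:
            track.append([t.start, t.end])
            handles.append((t, "span"))
        inh = [r for r in inherited if r.chrom == chrom]
        for r in inh:
            track.append([r.start, r.end])
            handles.append((r, "rec"))
        new_seq, payloads = assemblers[chrom].apply(track)
        sequences[chrom] = new_seq
        for iv, (obj, which) in zip(track, handles):
            if which == "span":
                obj.start, obj.end = iv
            elif which == "rec":
                obj.start, obj.end = iv
            else:
                kind, _s, _e = obj.parts[which]
                obj.parts[which] = (kind, iv[0], iv[1])
        for pl in payloads:
            records.append(
                TruthRecord(
                    family=pl["family"],
                    chrom=chrom,
                    subgenome=chrom_subgenome[chrom],
                    start=pl["start"],
                    end=pl["end"],
                    strand=pl["strand"],
                    planted_tsd=pl["planted_tsd"],
                    context="intergenic",
                    lineage="child_unique",
                )
            )
    records += inherited

    truth = TruthSet(
        records=records,
        chrom_subgenome=dict(chrom_subgenome),
        parent_unique=lost,
    )
    return SyntheticGenome(
        sequences=sequences,
        chrom_subgenome=chrom_subgenome,
        genes=genes,
        te_hosts=te_hosts,
        truth=truth,
        families=families,
    )
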