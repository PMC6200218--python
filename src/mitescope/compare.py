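"""Distribution tables, summary fractions and cross-genome common insertions.

``tabulate`` bins insertions by family x sub-genome x homoeologous chromosome
group; ``summarize`` turns a table (or the packaged copy-number catalog) into
the summary fractions the analysis reports (per-family, per-superfamily and
per-sub-genome percentages of the grand total); ``match_common_insertions``
pairs insertions between two genomes by their flanking sequences — two
insertions at the orthologous locus share both flanks — giving the fraction
of a family's insertions common to both genomes (i.e. inherited rather than
lineage-specific).

Percent rounding is half-up with the report's configured precision; the
defaults mirror the published usage (two decimals for superfamily fractions,
one for family fractions, integers for sub-genome fractions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .align import local_align
from .catalog import FamilyCatalog, SPECIES_COLUMNS
from .search import InsertionRecord

__all__ = [
    "DistributionTable", "SummaryReport", "CommonInsertionReport",
    "tabulate", "summarize", "summarize_catalog_column", "catalog_grand_total",
    "match_common_insertions", "round_half_up",
]

SUBGENOMES = ("A", "B", "D", "unknown")
_CHROM_RE = re.compile(r"^([1-7])([ABD])")


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def chrom_group(chrom: str) -> tuple[str, str]:
    """(group, subgenome-from-name) parsed from a chromosome name.

    Names matching /^[1-7][ABD]/ parse to their group number and sub-genome
    letter; anything else is ("unknown", "unknown").
    """
    m = _CHROM_RE.match(chrom)
    if m:
        return m.group(1), m.group(2)
    return "unknown", "unknown"


@dataclass
class DistributionTable:
    """counts[family][subgenome][group] with an 'unknown' bin on both axes."""

    genome_label: str = ""
    counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def add(self, family: str, subgenome: str, group: str, n: int = 1) -> None:
        if subgenome not in SUBGENOMES:
            subgenome = "unknown"
        self.counts.setdefault(family, {}).setdefault(subgenome, {})
        self.counts[family][subgenome][group] = (
            self.counts[family][subgenome].get(group, 0) + n
        )

    @property
    def grand_total(self) -> int:
        return sum(
            n
            for by_sg in self.counts.values()
            for by_grp in by_sg.values()
            for n in by_grp.values()
        )

    def family_total(self, family: str) -> int:
        return sum(
            n for by_grp in self.counts.get(family, {}).values()
            for n in by_grp.values()
        )

    def subgenome_total(self, subgenome: str) -> int:
        return sum(
            n
            for by_sg in self.counts.values()
            for n in by_sg.get(subgenome, {}).values()
        )

    def group_total(self, group: str) -> int:
        return sum(
            by_grp.get(group, 0)
            for by_sg in self.counts.values()
            for by_grp in by_sg.values()
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"family": fam, "subgenome": sg, "group": grp, "count": n}
            for fam, by_sg in sorted(self.counts.items())
            for sg, by_grp in sorted(by_sg.items())
            for grp, n in sorted(by_grp.items())
        ]
        return pd.DataFrame(rows, columns=["family", "subgenome", "group", "count"])


def tabulate(
    records: Sequence,
    chrom_subgenome: Mapping[str, str],
    genome_label: str = "",
) -> DistributionTable:
    """Bin records (anything with .family and .chrom) into a DistributionTable.

    The sub-genome comes from the metadata mapping (chromosomes absent from it
    go to the 'unknown' bin); the homoeologous group is parsed from the
    chromosome name.
    """
    table = DistributionTable(genome_label=genome_label)
    for rec in records:
        group, _ = chrom_group(rec.chrom)
        subgenome = chrom_subgenome.get(rec.chrom, "unknown")
        table.add(rec.family, subgenome, group)
    return table


@dataclass
class SummaryReport:
    grand_total: int
    family_totals: dict[str, int]
    family_percent: dict[str, float]  # raw (unrounded) percentages
    superfamily_totals: dict[str, int]
    superfamily_percent: dict[str, float]
    subgenome_totals: dict[str, int] = field(default_factory=dict)
    subgenome_percent: dict[str, float] = field(default_factory=dict)
    group_totals: dict[str, int] = field(default_factory=dict)
    undefined_percentages: bool = False  # empty input: percents reported as 0

    #: default report precisions (decimal places), half-up rounding
    FAMILY_DECIMALS = 1
    SUPERFAMILY_DECIMALS = 2
    SUBGENOME_DECIMALS = 0

    def rounded_family_percent(self, family: str, decimals: int | None = None) -> float:
        return round_half_up(
            self.family_percent[family],
            self.FAMILY_DECIMALS if decimals is None else decimals,
        )

    def rounded_superfamily_percent(self, sf: str, decimals: int | None = None) -> float:
        return round_half_up(
            self.superfamily_percent[sf],
            self.SUPERFAMILY_DECIMALS if decimals is None else decimals,
        )

    def rounded_subgenome_percent(self, sg: str, decimals: int | None = None) -> float:
        return round_half_up(
            self.subgenome_percent[sg],
            self.SUBGENOME_DECIMALS if decimals is None else decimals,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"grouping": "family", "key": k, "total": v,
             "percent": self.family_percent[k]}
            for k, v in sorted(self.family_totals.items())
        ] + [
            {"grouping": "superfamily", "key": k, "total": v,
             "percent": self.superfamily_percent[k]}
            for k, v in sorted(self.superfamily_totals.items())
        ] + [
            {"grouping": "subgenome", "key": k, "total": v,
             "percent": self.subgenome_percent.get(k, 0.0)}
            for k, v in sorted(self.subgenome_totals.items())
        ]
        return pd.DataFrame(rows, columns=["grouping", "key", "total", "percent"])


def _percents(totals: dict[str, int], grand: int) -> tuple[dict[str, float], bool]:
    if grand == 0:
        return {k: 0.0 for k in totals}, True
    return {k: 100.0 * v / grand for k, v in totals.items()}, False


def summarize(
    table: DistributionTable,
    catalog: FamilyCatalog | None = None,
) -> SummaryReport:
    """Summary fractions over a distribution table.

    Superfamily assignment comes from the catalog when given (families absent
    from it count under 'Unknown').
    """
    family_totals = {f: table.family_total(f) for f in sorted(table.counts)}
    grand = sum(family_totals.values())
    sf_totals: dict[str, int] = {}
    for fam, n in family_totals.items():
        sf = "Unknown"
        if catalog is not None and fam in catalog:
            sf = catalog[fam].superfamily.value
        sf_totals[sf] = sf_totals.get(sf, 0) + n
    sg_totals = {
        sg: table.subgenome_total(sg)
        for sg in SUBGENOMES
        if table.subgenome_total(sg) > 0
    }
    groups = {str(g): table.group_total(str(g)) for g in range(1, 8)}
    groups = {g: n for g, n in groups.items() if n > 0}
    fam_pct, undef = _percents(family_totals, grand)
    sf_pct, _ = _percents(sf_totals, grand)
    sg_pct, _ = _percents(sg_totals, grand)
    return SummaryReport(
        grand_total=grand,
        family_totals=family_totals,
        family_percent=fam_pct,
        superfamily_totals=sf_totals,
        superfamily_percent=sf_pct,
        subgenome_totals=sg_totals,
        subgenome_percent=sg_pct,
        group_totals=groups,
        undefined_percentages=undef,
    )


def summarize_catalog_column(catalog: FamilyCatalog, species_column: str) -> SummaryReport:
    """Summary fractions for one species column of the copy-number catalog."""
    if species_column not in SPECIES_COLUMNS:
        raise ValueError(f"unknown species column {species_column!r}")
    if catalog.copy_numbers is None:
        raise ValueError("catalog has no copy-number table")
    col = catalog.copy_numbers[species_column]
    family_totals = {f: int(col[f]) for f in col.index}
    grand = int(col.sum())
    sf_totals: dict[str, int] = {}
    for fam in catalog:
        sf_totals[fam.superfamily.value] = (
            sf_totals.get(fam.superfamily.value, 0) + family_totals.get(fam.name, 0)
        )
    fam_pct, undef = _percents(family_totals, grand)
    sf_pct, _ = _percents(sf_totals, grand)
    return SummaryReport(
        grand_total=grand,
        family_totals=family_totals,
        family_percent=fam_pct,
        superfamily_totals=sf_totals,
        superfamily_percent=sf_pct,
        undefined_percentages=undef,
    )


def catalog_grand_total(catalog: FamilyCatalog) -> int:
    """Total insertions across all species columns of the copy-number table."""
    if catalog.copy_numbers is None:
        raise ValueError("catalog has no copy-number table")
    return int(catalog.copy_numbers[list(SPECIES_COLUMNS)].to_numpy().sum())


# ---------------------------------------------------------------------------
# common-insertion analysis
# ---------------------------------------------------------------------------

@dataclass
class CommonInsertionReport:
    pairs: list[tuple[int, int]]  # indices into the eligible X / Y record lists
    n_common: int
    n_unique_x: int
    n_unique_y: int
    n_excluded_x: int
    n_excluded_y: int

    @property
    def shared_fraction_x(self) -> float:
        denom = self.n_common + self.n_unique_x
        return self.n_common / denom if denom else 0.0

    @property
    def shared_fraction_y(self) -> float:
        denom = self.n_common + self.n_unique_y
        return self.n_common / denom if denom else 0.0


def _flank_match(
    a: str, b: str, min_identity: float, min_overlap: int, side: str, slop: int = 15
) -> float:
    """Best junction-anchored local-alignment identity of two flanks, or -1.

    A shared locus implies the flanks agree *at the element junction*: a 5'
    flank match must reach the right end of both flanks (within ``slop`` bp,
    absorbing TSD/boundary wobble) and a 3' flank match the left end.  Without
    the anchor, any same-family insertion within a flank's reach of a vacated
    site would be mistaken for the same locus.  Arguments are canonicalized so
    the measure is symmetric in x and y.
    """
    if b < a:
        a, b = b, a
    best = -1.0
    for hit in local_align(a, b):
        span = hit.subject_end - hit.subject_start
        if span < min_overlap or hit.identity < min_identity:
            continue
        if side == "5":
            anchored = (hit.query_end >= len(a) - slop
                        and hit.subject_end >= len(b) - slop)
        else:
            anchored = hit.query_start <= slop and hit.subject_start <= slop
        if anchored:
            best = max(best, hit.identity)
    return best


def match_common_insertions(
    records_x: Sequence[InsertionRecord],
    records_y: Sequence[InsertionRecord],
    min_flank_identity: float = 0.90,
    min_flank_overlap: int = 50,
    seed_len: int = 21,
    seed_window: int = 120,
) -> CommonInsertionReport:
    """Pair insertions of one family across two genomes by flank identity.

    Records x and y match when they are the same family and both flank pairs
    (5' with 5', 3' with 3') locally align at >= ``min_flank_identity`` over
    >= ``min_flank_overlap`` bp, anchored at the element junction.  Candidate
    pairs are found by shared ``seed_len``-mers within the junction-proximal
    ``seed_window`` bp of the 5' flanks, verified by alignment, and resolved
    greedily best-identity-first so each record joins at most one pair.
    Records with flanks shorter than ``min_flank_overlap`` are excluded and
    counted separately.
    """

    def eligible(recs):
        keep, dropped = [], 0
        for r in recs:
            if len(r.flank5) >= min_flank_overlap and len(r.flank3) >= min_flank_overlap:
                keep.append(r)
            else:
                dropped += 1
        return keep, dropped

    xs, excl_x = eligible(records_x)
    ys, excl_y = eligible(records_y)

    # candidate pairs by shared k-mers in the junction-proximal 5'-flank
    # window; seeded from both sides so the candidate set is symmetric
    def _candidates(index_recs, probe_recs):
        index: dict[str, set[int]] = {}
        for j, r in enumerate(index_recs):
            f = r.flank5[-seed_window:]
            for i in range(0, len(f) - seed_len + 1, seed_len):  # strided
                index.setdefault(f[i : i + seed_len], set()).add(j)
        out: set[tuple[int, int]] = set()
        for i, r in enumerate(probe_recs):
            f = r.flank5[-seed_window:]
            for p in range(len(f) - seed_len + 1):
                for j in index.get(f[p : p + seed_len], ()):
                    out.add((i, j))
        return out

    pair_cands = _candidates(ys, xs) | {
        (i, j) for j, i in _candidates(xs, ys)
    }

    scored: list[tuple[float, int, int]] = []
    for i, j in sorted(pair_cands):
        rx, ry = xs[i], ys[j]
        if ry.family != rx.family:
            continue
        id5 = _flank_match(rx.flank5, ry.flank5, min_flank_identity,
                           min_flank_overlap, side="5")
        if id5 < 0:
            continue
        id3 = _flank_match(rx.flank3, ry.flank3, min_flank_identity,
                           min_flank_overlap, side="3")
        if id3 < 0:
            continue
        scored.append((min(id5, id3), i, j))

    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_x: set[int] = set()
    used_y: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _ident, i, j in scored:
        if i in used_x or j in used_y:
            continue
        used_x.add(i)
        used_y.add(j)
        pairs.append((i, j))

    return CommonInsertionReport(
        pairs=pairs,
        n_common=len(pairs),
        n_unique_x=len(xs) - len(pairs),
        n_unique_y=len(ys) - len(pairs),
        n_excluded_x=excl_x,
        n_excluded_y=excl_y,
    )
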