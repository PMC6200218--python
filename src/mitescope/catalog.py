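"""MITE family catalog: domain types, superfamily TSD rules, and I/O.

A MITE family is identified by a consensus sequence and a target-site
duplication (TSD) preference determined by its superfamily:

* *Stowaway*-like elements duplicate the dinucleotide ``TA``,
* *Tourist*-like elements duplicate ``TWA`` (W = A or T),
* *Mutator*-like elements create long, sequence-unconstrained TSDs of 7-10 bp,
* families of unknown superfamily carry a family-specific pattern in the
  catalog, or are unconstrained when none is recorded.

The packaged catalog transcribes the published per-species copy-number table
for 36 wheat MITE families (four species: hexaploid bread wheat, tetraploid
wild emmer, and the diploid D- and A-genome donors).  Those copy numbers are
an authoritative fixture used for summarization arithmetic; they are never
recomputed here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Superfamily",
    "TSDRule",
    "MITEFamily",
    "FamilyCatalog",
    "tsd_rule",
    "load_family_catalog",
    "write_family_catalog",
    "load_packaged_catalog",
    "load_packaged_subgenome_counts",
    "SPECIES_COLUMNS",
]

#: copy-number columns in catalog TSVs, in fixed order
SPECIES_COLUMNS = (
    "copies_Taestivum",
    "copies_Tturgidum",
    "copies_Aetauschii",
    "copies_Turartu",
)


class Superfamily(enum.Enum):
    STOWAWAY = "Stowaway"
    TOURIST = "Tourist"
    MUTATOR = "Mutator"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class TSDRule:
    """TSD preference: either a fixed IUPAC pattern or a length range.

    Exactly one of ``pattern`` / ``length_range`` is set.  ``pattern`` is an
    IUPAC DNA string matched position-by-position; ``length_range`` is an
    inclusive (lo, hi) bp range with no base constraint.
    """

    pattern: str | None = None
    length_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if (self.pattern is None) == (self.length_range is None):
            raise ValueError("exactly one of pattern / length_range required")

    @property
    def is_fixed(self) -> bool:
        return self.pattern is not None

    def lengths(self) -> range:
        """Candidate TSD lengths under this rule, longest first."""
        if self.pattern is not None:
            k = len(self.pattern)
            return range(k, k - 1, -1)
        lo, hi = self.length_range
        return range(hi, lo - 1, -1)


def tsd_rule(superfamily: Superfamily, family_pattern: str | None = None) -> TSDRule:
    """TSD rule for a superfamily.

    For unknown superfamilies the family-specific catalog pattern applies when
    present; otherwise the rule is an unconstrained 2-10 bp duplication.
    """
    if superfamily is Superfamily.STOWAWAY:
        return TSDRule(pattern="TA")
    if superfamily is Superfamily.TOURIST:
        return TSDRule(pattern="TWA")
    if superfamily is Superfamily.MUTATOR:
        return TSDRule(length_range=(7, 10))
    if superfamily is Superfamily.UNKNOWN:
        if family_pattern:
            return TSDRule(pattern=family_pattern)
        return TSDRule(length_range=(2, 10))
    raise ValueError(f"unknown superfamily: {superfamily!r}")


@dataclass
class MITEFamily:
    name: str
    superfamily: Superfamily
    consensus_len: int
    tsd_pattern: str | None = None
    consensus_seq: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.consensus_seq is not None:
            self.consensus_seq = self.consensus_seq.upper()
            if len(self.consensus_seq) != self.consensus_len:
                raise ValueError(
                    f"{self.name}: consensus_len {self.consensus_len} != "
                    f"sequence length {len(self.consensus_seq)}"
                )

    @property
    def rule(self) -> TSDRule:
        return tsd_rule(self.superfamily, self.tsd_pattern)


@dataclass
class FamilyCatalog:
    families: list[MITEFamily] = field(default_factory=list)
    #: per-species copy numbers, indexed by family name (fixture arithmetic only)
    copy_numbers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate family name(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def __getitem__(self, name: str) -> MITEFamily:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.families)

    def by_superfamily(self, superfamily: Superfamily) -> list[MITEFamily]:
        return [f for f in self.families if f.superfamily is superfamily]


def load_family_catalog(
    tsv_path: str | Path, consensus_fasta: str | Path | None = None
) -> FamilyCatalog:
    """Load a catalog from a TSV (plus optional consensus FASTA keyed by name).

    The TSV carries family, superfamily, consensus_len_bp, tsd_pattern, and the
    four per-species copy-number columns.  A family whose consensus is absent
    from the FASTA (or when no FASTA is given) is still loaded and usable for
    fixture arithmetic; it just cannot be used as a homology-search query.
    """
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if df["family"].duplicated().any():
        dupes = sorted(df.loc[df["family"].duplicated(), "family"])
        raise ValueError(f"duplicate family name(s) in {tsv_path}: {dupes}")

    consensi: dict[str, str] = {}
    if consensus_fasta is not None:
        consensi = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(consensus_fasta), "fasta")
        }

    families: list[MITEFamily] = []
    copy_rows: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        name = row["family"]
        copies: dict[str, int] = {}
        for col in SPECIES_COLUMNS:
            if col not in row:
                continue
            raw = row[col]
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(
                    f"malformed copy number {raw!r} for family {name!r}, "
                    f"column {col!r}"
                ) from None
            if value < 0:
                raise ValueError(f"negative copy number for family {name!r}: {value}")
            copies[col] = value
        seq = consensi.get(name)
        consensus_len = int(row["consensus_len_bp"]) if row["consensus_len_bp"] else (
            len(seq) if seq else 0
        )
        families.append(
            MITEFamily(
                name=name,
                superfamily=Superfamily(row["superfamily"]),
                consensus_len=consensus_len,
                tsd_pattern=row.get("tsd_pattern") or None,
                consensus_seq=seq,
                notes=row.get("notes", ""),
            )
        )
        copy_rows[name] = copies

    copy_df = None
    if copy_rows and any(copy_rows.values()):
        copy_df = pd.DataFrame.from_dict(copy_rows, orient="index").astype(int)
        copy_df.index.name = "family"
    return FamilyCatalog(families=families, copy_numbers=copy_df)


def write_family_catalog(
    catalog: FamilyCatalog,
    tsv_path: str | Path,
    consensus_fasta: str | Path | None = None,
) -> None:
    """Write a catalog back to TSV (+ FASTA for families with a consensus)."""
    rows = []
    for fam in catalog.families:
        row = {
            "family": fam.name,
            "superfamily": fam.superfamily.value,
            "consensus_len_bp": fam.consensus_len,
            "tsd_pattern": fam.tsd_pattern or "",
            "notes": fam.notes,
        }
        for col in SPECIES_COLUMNS:
            if catalog.copy_numbers is not None and col in catalog.copy_numbers:
                row[col] = int(catalog.copy_numbers.loc[fam.name, col])
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if consensus_fasta is not None:
        with open(consensus_fasta, "w") as fh:
            for fam in catalog.families:
                if fam.consensus_seq:
                    fh.write(f">{fam.name}\n{fam.consensus_seq}\n")


def _packaged(name: str):
    return resources.files("mitescope.data").joinpath(name)


def load_packaged_catalog() -> FamilyCatalog:
    """The packaged 36-family wheat MITE catalog (copy-number fixture)."""
    with resources.as_file(_packaged("wheat_mite_catalog.tsv")) as path:
        return load_family_catalog(path)


def load_packaged_subgenome_counts() -> pd.DataFrame:
    """Published per-sub-genome insertion counts (genome, family, subgenome, count).

    ``family == "ALL"`` rows are whole-genome sub-genome totals; named-family
    rows are that family's sub-genome breakdown.
    """
    with resources.as_file(_packaged("subgenome_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t")
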