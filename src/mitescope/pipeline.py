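"""Pipeline orchestration: simulate -> scan -> structure -> annotate -> summarize.

A :class:`PipelineConfig` (usually loaded from a YAML file) either describes a
synthetic genome to generate or points at an existing genome FASTA plus a
family catalog.  ``run_pipeline`` executes the stages in order, writes every
stage's outputs as plain TSV/FASTA/GFF3/BED under the output directory, and
finishes with a JSON run manifest recording parameters, seed and per-stage
record counts, so any stage can be re-run standalone and a fixed config+seed
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._util import random_dna
from .annotate import ReferenceSet, annotate_insertion
from .catalog import (FamilyCatalog, MITEFamily, Superfamily,
                      load_family_catalog, write_family_catalog)
from .compare import summarize, tabulate
from .search import (deduplicate, retrieve_insertions, write_records_bed,
                     write_records_tsv)
from .simulate import SyntheticGenome, SyntheticGenomeSpec, generate_genome
from .structure import call_tsd

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    # either a simulation block ...
    simulate: dict | None = None
    # ... or paths to an existing genome + catalog
    genome_fasta: Path | None = None
    chrom_metadata: Path | None = None
    catalog_tsv: Path | None = None
    consensus_fasta: Path | None = None
    max_evalue: float = 1e-3
    end_tol: int = 20
    flank_len: int = 500
    annotate: bool = True

    def validate(self) -> None:
        if (self.simulate is None) == (self.genome_fasta is None):
            raise ValueError("config needs exactly one of 'simulate' or 'genome_fasta'")
        for label, path in (("genome_fasta", self.genome_fasta),
                            ("chrom_metadata", self.chrom_metadata),
                            ("catalog_tsv", self.catalog_tsv),
                            ("consensus_fasta", self.consensus_fasta)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path}")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.end_tol < 0 or self.flank_len < 0:
            raise ValueError("end_tol and flank_len must be non-negative")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(
        outdir=Path(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        genome_fasta=Path(raw["genome_fasta"]) if "genome_fasta" in raw else None,
        chrom_metadata=Path(raw["chrom_metadata"]) if "chrom_metadata" in raw else None,
        catalog_tsv=Path(raw["catalog_tsv"]) if "catalog_tsv" in raw else None,
        consensus_fasta=Path(raw["consensus_fasta"]) if "consensus_fasta" in raw else None,
        max_evalue=float(raw.get("max_evalue", 1e-3)),
        end_tol=int(raw.get("end_tol", 20)),
        flank_len=int(raw.get("flank_len", 500)),
        annotate=bool(raw.get("annotate", True)),
    )


def _families_from_sim_block(block: dict, seed: int) -> list[tuple[MITEFamily, int, float]]:
    """Families to plant; consensus sequences are drawn from the run seed when
    not supplied explicitly."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA]))
    plan = []
    for fam_cfg in block.get("families", []):
        seq = fam_cfg.get("consensus")
        length = int(fam_cfg.get("length", len(seq) if seq else 150))
        if seq is None:
            seq = random_dna(rng, length)
        fam = MITEFamily(
            name=fam_cfg["name"],
            superfamily=Superfamily(fam_cfg.get("superfamily", "Stowaway")),
            consensus_len=len(seq),
            tsd_pattern=fam_cfg.get("tsd_pattern"),
            consensus_seq=seq,
        )
        plan.append((fam, int(fam_cfg.get("copies", 0)),
                     float(fam_cfg.get("divergence", 0.0))))
    return plan


def _simulate_stage(config: PipelineConfig, outdir: Path) -> tuple[SyntheticGenome, FamilyCatalog]:
    block = dict(config.simulate or {})
    plan = _families_from_sim_block(block, config.seed)
    spec = SyntheticGenomeSpec(
        subgenome_labels=list(block.get("subgenome_labels", ["A", "B"])),
        n_chromosomes=int(block.get("n_chromosomes", 1)),
        chromosome_length=int(block.get("chromosome_length", 120_000)),
        gc_content=float(block.get("gc_content", 0.46)),
        families_to_plant=plan,
        nesting_fractions=dict(block.get("nesting", {})),
        seed=config.seed,
    )
    genome = generate_genome(spec)
    genome.write_fasta(outdir / "genome.fa")
    genome.write_chrom_metadata(outdir / "chroms.tsv")
    genome.write_genes_gff3(outdir / "genes.gff3")
    genome.write_tes_gff3(outdir / "tes.gff3")
    genome.write_te_library_fasta(outdir / "te_library.fa")
    genome.write_truth_tsv(outdir / "truth.tsv")
    catalog = FamilyCatalog(families=[f for f, _c, _r in plan])
    write_family_catalog(catalog, outdir / "catalog.tsv", outdir / "catalog.fa")
    return genome, catalog


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json).

    On stage failure the exception propagates after the manifest is written
    with the failing stage recorded; outputs of completed stages remain on
    disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mitescope",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "max_evalue": config.max_evalue,
            "end_tol": config.end_tol,
            "flank_len": config.flank_len,
        },
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise err

    # ---- stage: genome ----
    try:
        if config.simulate is not None:
            genome, catalog = _simulate_stage(config, outdir)
            sequences = genome.sequences
            chrom_subgenome = genome.chrom_subgenome
        else:
            from pyfaidx import Fasta

            fasta = Fasta(str(config.genome_fasta))
            sequences = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
            chrom_subgenome = {}
            if config.chrom_metadata:
                with open(config.chrom_metadata) as fh:
                    next(fh)
                    for line in fh:
                        chrom, sg = line.split("\t")[:2]
                        chrom_subgenome[chrom] = sg.strip()
            genome = None
            catalog = load_family_catalog(config.catalog_tsv, config.consensus_fasta)
        manifest["stages"]["genome"] = {
            "n_chromosomes": len(sequences),
            "total_bp": sum(len(s) for s in sequences.values()),
            "n_families": len(catalog),
        }
    except Exception as err:  # noqa: BLE001 - manifest must record the stage
        fail("genome", err)

    # ---- stage: scan ----
    try:
        records = []
        for fam in catalog:
            if not fam.consensus_seq:
                continue
            recs = deduplicate(
                retrieve_insertions(
                    sequences, fam,
                    max_evalue=config.max_evalue,
                    end_tol=config.end_tol,
                    flank_len=config.flank_len,
                )
            )
            for r in recs:
                r.tsd_call = call_tsd(r, fam.superfamily, fam.tsd_pattern)
            records.extend(recs)
        records.sort(key=lambda r: (r.chrom, r.start, r.family))
        write_records_tsv(records, outdir / "insertions.tsv",
                          header_comment=f"mitescope scan seed={config.seed} "
                          f"max_evalue={config.max_evalue} end_tol={config.end_tol}")
        write_records_bed(records, outdir / "insertions.bed")
        manifest["stages"]["scan"] = {
            "n_records": len(records),
            "n_tsd_rule_matches": sum(
                1 for r in records
                if r.tsd_call is not None and r.tsd_call.matches_superfamily_rule
            ),
        }
    except Exception as err:  # noqa: BLE001
        fail("scan", err)

    # ---- stage: annotate ----
    if config.annotate and genome is not None:
        try:
            refs = ReferenceSet.from_synthetic(genome)
            calls = [annotate_insertion(r, refs, max_evalue=1e-10) for r in records]
            with open(outdir / "annotation.tsv", "w") as fh:
                fh.write("family\tchrom\tstart\tend\tcategory\ttarget\t"
                         "evalue\tgene_relation\tdistance\n")
                for r, c in zip(records, calls):
                    ev = "" if c.best_evalue is None else f"{c.best_evalue:.3g}"
                    dist = "" if c.distance_to_gene is None else c.distance_to_gene
                    fh.write(f"{r.family}\t{r.chrom}\t{r.start}\t{r.end}\t"
                             f"{c.category}\t{c.target_id or ''}\t{ev}\t"
                             f"{c.gene_relation}\t{dist}\n")
            by_cat: dict[str, int] = {}
            for c in calls:
                by_cat[c.category] = by_cat.get(c.category, 0) + 1
            manifest["stages"]["annotate"] = {
                "n_records": len(calls), "by_category": by_cat,
            }
        except Exception as err:  # noqa: BLE001
            fail("annotate", err)

    # ---- stage: summarize ----
    try:
        table = tabulate(records, chrom_subgenome, genome_label="pipeline")
        report = summarize(table, catalog)
        table.to_dataframe().to_csv(outdir / "distribution.tsv", sep="\t", index=False)
        report.to_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False)
        summary_json = {
            "grand_total": report.grand_total,
            "family_totals": report.family_totals,
            "superfamily_totals": report.superfamily_totals,
            "subgenome_totals": report.subgenome_totals,
        }
        (outdir / "summary.json").write_text(json.dumps(summary_json, indent=2))
        manifest["stages"]["summarize"] = {"grand_total": report.grand_total}
    except Exception as err:  # noqa: BLE001
        fail("summarize", err)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
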