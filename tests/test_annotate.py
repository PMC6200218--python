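"""Context annotation: homology category, gene association, transcript region."""

from __future__ import annotations

import numpy as np
import pytest

from mitescope.annotate import (ReferenceSet, annotate_insertion,
                                classify_gene_association,
                                locate_in_transcript)
from mitescope.catalog import MITEFamily, Superfamily
from mitescope.search import retrieve_insertions
from mitescope.simulate import SyntheticGenomeSpec, generate_genome

from ._oracles import gene_relation_oracle


class _Interval:
    """Minimal stand-in exposing the chrom/start/end surface of a record."""

    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


@pytest.fixture(scope="module")
def nested_genome(stowaway_family):
    spec = SyntheticGenomeSpec(
        subgenome_labels=["A"], n_chromosomes=2, chromosome_length=150_000,
        families_to_plant=[(stowaway_family, 120, 0.0)],
        nesting_fractions={"TE_classII": 0.3, "TE_classI": 0.2,
                           "gene_intron": 0.15, "gene_3utr": 0.1},
        seed=2001)
    return generate_genome(spec)


class TestAnnotateInsertion:
    def test_te_nested_insertions_get_te_category(self, nested_genome,
                                                  stowaway_family):
        """Category agreement with planted context is >= 99% at divergence 0,
        and class I / class II are never confused."""
        refs = ReferenceSet.from_synthetic(nested_genome)
        records = retrieve_insertions(nested_genome.sequences, stowaway_family)
        truth = {(r.chrom, r.start, r.end): r.context
                 for r in nested_genome.truth.records}
        te_total = te_correct = 0
        for rec in records:
            ctx = truth[(rec.chrom, rec.start, rec.end)]
            if not ctx.startswith("TE_"):
                continue
            te_total += 1
            call = annotate_insertion(rec, refs)
            if call.category == ctx:
                te_correct += 1
            assert call.category in (ctx, "unknown"), \
                "a class-I/class-II confusion is never acceptable"
        assert te_total > 0
        assert te_correct / te_total >= 0.99

    def test_intron_insertion_is_genic_with_intron_relation(self, nested_genome,
                                                            stowaway_family):
        refs = ReferenceSet.from_synthetic(nested_genome)
        records = retrieve_insertions(nested_genome.sequences, stowaway_family)
        truth = {(r.chrom, r.start, r.end): r.context
                 for r in nested_genome.truth.records}
        checked = 0
        for rec in records:
            if truth[(rec.chrom, rec.start, rec.end)] != "gene_intron":
                continue
            call = annotate_insertion(rec, refs)
            assert call.category == "protein_coding_gene"
            assert call.gene_relation == "intron"
            checked += 1
        assert checked > 0

    def test_background_insertion_is_unknown(self, clean_genome,
                                             stowaway_family):
        refs = ReferenceSet.from_synthetic(clean_genome)
        records = retrieve_insertions(clean_genome.sequences, stowaway_family)
        truth = {(r.chrom, r.start, r.end): r for r in clean_genome.truth.records}
        far = [r for r in records
               if truth[(r.chrom, r.start, r.end)].context == "intergenic"]
        # far-from-everything insertions: no reference entry within flank reach
        checked = 0
        for rec in far:
            near_feature = any(
                g.chrom == rec.chrom and rec.start - 600 < g.end
                and g.start < rec.end + 600 for g in clean_genome.genes
            ) or any(
                t.chrom == rec.chrom and rec.start - 600 < t.end
                and t.start < rec.end + 600 for t in clean_genome.te_hosts
            )
            if near_feature:
                continue
            call = annotate_insertion(rec, refs)
            assert call.category == "unknown"
            checked += 1
        assert checked > 0

    def test_empty_reference_set_gives_unknown(self, clean_genome,
                                               stowaway_family):
        records = retrieve_insertions(clean_genome.sequences, stowaway_family)
        call = annotate_insertion(records[0], ReferenceSet())
        assert call.category == "unknown"

    def test_reference_order_does_not_change_call(self, nested_genome,
                                                  stowaway_family):
        refs = ReferenceSet.from_synthetic(nested_genome)
        flipped = ReferenceSet(entries=list(reversed(refs.entries)),
                               gene_models=refs.gene_models)
        records = retrieve_insertions(nested_genome.sequences, stowaway_family)
        for rec in records[:25]:
            a = annotate_insertion(rec, refs)
            b = annotate_insertion(rec, flipped)
            assert (a.category, a.target_id) == (b.category, b.target_id)


class TestGeneAssociation:
    def test_boundary_rules(self, clean_genome):
        gene = clean_genome.genes[0]
        chrom = gene.chrom
        # 50 bp from the gene on its upstream side
        if gene.strand == "+":
            rec_up = _Interval(chrom, gene.start - 150, gene.start - 50)
            rec_exact = _Interval(chrom, gene.start - 200, gene.start - 100)
            rec_far = _Interval(chrom, gene.start - 300, gene.start - 150)
        else:
            rec_up = _Interval(chrom, gene.end + 50, gene.end + 150)
            rec_exact = _Interval(chrom, gene.end + 100, gene.end + 200)
            rec_far = _Interval(chrom, gene.end + 150, gene.end + 300)
        models = [gene]
        assert classify_gene_association(rec_up, models)[0] == "upstream_le100"
        # exactly 100 bp away counts as associated (inclusive boundary)
        assert classify_gene_association(rec_exact, models)[0] == "upstream_le100"
        assert classify_gene_association(rec_far, models)[0] == "none"

    def test_agrees_with_interval_oracle_on_random_layouts(self, clean_genome):
        """1000 random insertion/gene layouts against the brute-force oracle."""
        rng = np.random.default_rng(42)
        gene = clean_genome.genes[0]
        for _ in range(1000):
            length = int(rng.integers(50, 400))
            start = int(rng.integers(gene.start - 2000, gene.end + 2000))
            rec = _Interval(gene.chrom, start, start + length)
            got, _dist = classify_gene_association(rec, [gene])
            expected = gene_relation_oracle(
                rec.start, rec.end, gene.start, gene.end, gene.strand,
                gene.parts)
            assert got == expected, (rec.start, rec.end)


class TestLocateInTranscript:
    PARTS = [("five_prime_UTR", 0, 200), ("CDS", 200, 1000),
             ("three_prime_UTR", 1000, 1300)]

    @pytest.mark.parametrize("interval, expected", [
        ((1050, 1200), "three_prime_utr"),
        ((300, 450), "cds"),
        ((10, 150), "five_prime_utr"),
        ((150, 260), "spanning"),      # >10% of length on each side
        ((195, 300), "cds"),           # only 5 bp before the boundary
    ])
    def test_region_calls(self, interval, expected):
        assert locate_in_transcript(interval, self.PARTS) == expected

    def test_planted_region_mix_recovered(self):
        """A 70/17/13 planted UTR3/UTR5/CDS mix is recovered within 3 points."""
        rng = np.random.default_rng(7)
        n = 400
        planted = rng.choice(["three_prime_utr", "five_prime_utr", "cds"],
                             size=n, p=[0.70, 0.17, 0.13])
        spans = {"five_prime_utr": (0, 200), "cds": (200, 1000),
                 "three_prime_utr": (1000, 1300)}
        calls = []
        for region in planted:
            lo, hi = spans[region]
            length = int(rng.integers(20, 60))
            start = int(rng.integers(lo, hi - length))
            calls.append(locate_in_transcript((start, start + length), self.PARTS))
        for region, expected_frac in [("three_prime_utr", 0.70),
                                      ("five_prime_utr", 0.17), ("cds", 0.13)]:
            got = calls.count(region) / n
            assert abs(got - expected_frac) <= 0.03

    def test_disjoint_interval_rejected(self):
        with pytest.raises(ValueError):
            locate_in_transcript((5000, 5100), self.PARTS)
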