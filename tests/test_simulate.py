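"""Synthetic genome construction, TSD conventions, inheritance model."""

from __future__ import annotations

import numpy as np
import pytest

from mitescope._util import revcomp
from mitescope.catalog import MITEFamily, Superfamily, TSDRule
from mitescope.simulate import (SyntheticGenomeSpec, derive_polyploid,
                                generate_genome, read_truth_tsv, sample_tsd)


def _element_matches(genome, record, consensus, max_mismatch_frac=0.0):
    seq = genome.sequences[record.chrom][record.start : record.end]
    expected = consensus if record.strand == "+" else revcomp(consensus)
    if len(seq) != len(expected):
        return False
    mm = sum(a != b for a, b in zip(seq, expected))
    return mm <= max_mismatch_frac * len(expected)


class TestGenerate:
    def test_undiverged_copies_flanked_by_ta_tsd(self, clean_genome, stowaway_family):
        assert len(clean_genome.truth) == 100
        for r in clean_genome.truth.records:
            assert r.planted_tsd == "TA"
            seq = clean_genome.sequences[r.chrom]
            assert seq[r.start - 2 : r.start] == "TA"
            assert seq[r.end : r.end + 2] == "TA"
            assert _element_matches(clean_genome, r, stowaway_family.consensus_seq)

    def test_no_copies_planted_nothing_retrievable(self, stowaway_family):
        from mitescope.search import retrieve_insertions

        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=60_000,
            families_to_plant=[(stowaway_family, 0, 0.0)], seed=77)
        genome = generate_genome(spec)
        assert len(genome.truth) == 0
        assert retrieve_insertions(genome.sequences, stowaway_family) == []

    def test_nesting_fraction_one_puts_all_in_te(self, stowaway_family):
        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=100_000,
            families_to_plant=[(stowaway_family, 30, 0.0)],
            nesting_fractions={"TE_classII": 1.0}, seed=78)
        genome = generate_genome(spec)
        assert all(r.context == "TE_classII" for r in genome.truth.records)
        for r in genome.truth.records:
            assert any(t.chrom == r.chrom and t.start <= r.start and r.end <= t.end
                       and t.te_class == "classII" for t in genome.te_hosts)

    def test_byte_identical_under_fixed_seed(self, stowaway_family):
        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=50_000,
            families_to_plant=[(stowaway_family, 20, 0.02)], seed=79)
        a, b = generate_genome(spec), generate_genome(spec)
        assert a.sequences == b.sequences
        assert [(r.chrom, r.start, r.end) for r in a.truth.records] == \
            [(r.chrom, r.start, r.end) for r in b.truth.records]

    def test_diverged_copies_keep_stated_identity(self, diverged_genome,
                                                  stowaway_family):
        """Realized element identity stays within divergence + 0.05 slack."""
        for r in diverged_genome.truth.records:
            assert _element_matches(diverged_genome, r,
                                    stowaway_family.consensus_seq,
                                    max_mismatch_frac=0.10)

    def test_truth_sorted_and_within_bounds(self, clean_genome):
        recs = clean_genome.truth.records
        assert recs == sorted(recs, key=lambda r: (r.chrom, r.start, r.end, r.family))
        for r in recs:
            assert 0 <= r.start < r.end <= len(clean_genome.sequences[r.chrom])

    def test_overfull_request_raises(self, stowaway_family):
        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=8_000,
            genes_per_chromosome=1, te_hosts_per_chromosome=0,
            families_to_plant=[(stowaway_family, 500, 0.0)], seed=80)
        with pytest.raises(RuntimeError, match="placement"):
            generate_genome(spec)

    def test_invalid_spec_rejected(self, stowaway_family):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(nesting_fractions={"TE_classII": 0.7,
                                                   "gene_intron": 0.6})
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(families_to_plant=[(stowaway_family, -1, 0.0)])
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(families_to_plant=[(stowaway_family, 1, 1.0)])

    def test_truth_tsv_round_trip(self, clean_genome, tmp_path):
        p = tmp_path / "truth.tsv"
        clean_genome.write_truth_tsv(p)
        back = read_truth_tsv(p, clean_genome.chrom_subgenome)
        assert len(back) == len(clean_genome.truth)
        for a, b in zip(back.records, clean_genome.truth.records):
            assert (a.chrom, a.start, a.end, a.family, a.planted_tsd,
                    a.context) == (b.chrom, b.start, b.end, b.family,
                                   b.planted_tsd, b.context)


class TestSampleTSD:
    def test_rules_produce_rule_conforming_tsds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert sample_tsd(TSDRule(pattern="TA"), rng) == "TA"
            twa = sample_tsd(TSDRule(pattern="TWA"), rng)
            assert twa[0] == "T" and twa[2] == "A" and twa[1] in "AT"
            mut = sample_tsd(TSDRule(length_range=(7, 10)), rng)
            assert len(mut) == 9 and set(mut) <= set("ACGT")


class TestDerivePolyploid:
    def test_inherit_all(self, clean_genome):
        child = derive_polyploid(clean_genome, None, 1.0, 0, seed=5)
        counts = child.truth.lineage_counts()
        assert counts == {"inherited": 100}
        assert child.truth.parent_unique == []

    def test_inherit_none(self, clean_genome):
        child = derive_polyploid(clean_genome, None, 0.0, 0, seed=5)
        assert "inherited" not in child.truth.lineage_counts()
        assert len(child.truth.parent_unique) == 100

    def test_inherited_count_binomial(self, inheritance_parent):
        """Retention is Bernoulli per insertion: count within 3 sd of B(500, .4)."""
        child = derive_polyploid(inheritance_parent, None, 0.4, 0, seed=6)
        n_inh = child.truth.lineage_counts()["inherited"]
        mean, sd = 500 * 0.4, np.sqrt(500 * 0.4 * 0.6)
        assert abs(n_inh - mean) <= 3 * sd

    def test_excision_leaves_exactly_one_tsd(self, clean_genome, stowaway_family):
        child = derive_polyploid(clean_genome, None, 0.0, 0, seed=7)
        # every parental element is gone; by construction the vacated site kept
        # one TSD copy, so the child is shorter by (element + tsd) per excision
        for chrom, seq in child.sequences.items():
            parent_seq = clean_genome.sequences[chrom]
            n_exc = sum(1 for r in clean_genome.truth.records if r.chrom == chrom)
            expected = len(parent_seq) - n_exc * (158 + 2)
            assert len(seq) == expected
        from mitescope.search import retrieve_insertions
        assert retrieve_insertions(child.sequences, stowaway_family) == []

    def test_child_coordinates_remain_valid(self, clean_genome, stowaway_family):
        child = derive_polyploid(clean_genome, None, 0.5, 40, seed=8)
        for r in child.truth.records:
            assert _element_matches(child, r, stowaway_family.consensus_seq)

    def test_two_parents_merge_chromosomes(self, clean_genome, tourist_family):
        spec = SyntheticGenomeSpec(
            subgenome_labels=["D"], n_chromosomes=1, chromosome_length=80_000,
            families_to_plant=[(tourist_family, 20, 0.0)], seed=81)
        other = generate_genome(spec)
        child = derive_polyploid(clean_genome, other, 1.0, 0, seed=9)
        assert set(child.sequences) == set(clean_genome.sequences) | set(other.sequences)
        assert len(child.truth) == 120

    def test_bad_fraction_rejected(self, clean_genome):
        with pytest.raises(ValueError):
            derive_polyploid(clean_genome, None, 1.5, 0, seed=1)
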