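"""TIR/TSD calling, logo arithmetic, diversity, consensus, discovery."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitescope._util import mutate, random_dna, revcomp
from mitescope.catalog import FamilyCatalog, Superfamily, TSDRule
from mitescope.search import retrieve_insertions
from mitescope.structure import (build_consensus, build_pfm, call_tsd,
                                 call_tsd_rule, discover_families, find_tir,
                                 haplotype_diversity, information_content)

dna = st.text(alphabet="ACGT", min_size=20, max_size=120)


class TestFindTIR:
    def test_planted_perfect_tir(self, novel_tir_family):
        ann = find_tir(novel_tir_family.consensus_seq)
        assert (ann.tir_len, ann.mismatches) == (11, 0)
        assert ann.left_seq == novel_tir_family.consensus_seq[:11]

    def test_one_mutation_in_suffix_counted(self, novel_tir_family):
        seq = list(novel_tir_family.consensus_seq)
        # mutate one base inside the right TIR copy
        pos = len(seq) - 6
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        ann = find_tir("".join(seq), max_mismatch=1)
        assert (ann.tir_len, ann.mismatches) == (11, 1)

    def test_random_sequences_rarely_qualify(self):
        """Chance TIRs in i.i.d. 200-mers stay below the analytic bound.

        P(a fixed length-L terminal pair matches with <= 2 mismatches) is
        sum_{k<=2} C(L,k) (3/4)^k (1/4)^(L-k); summed over L = 8..30 this is
        ~0.048, so the qualifying rate over 1000 draws must stay well under
        a conservative 1.5x of that bound.
        """
        from math import comb

        bound = sum(
            comb(L, k) * (3 / 4) ** k * (1 / 4) ** (L - k)
            for L in range(8, 31) for k in range(3)
        )
        rng = np.random.default_rng(1234)
        hits = sum(
            1 for _ in range(1000) if find_tir(random_dna(rng, 200)) is not None
        )
        assert hits / 1000 <= 1.5 * bound

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(core=dna)
    def test_strand_symmetric(self, core):
        seq = "GATCGATCGATC" + core + revcomp("GATCGATCGATC")
        fwd = find_tir(seq)
        rev = find_tir(revcomp(seq))
        assert (fwd is None) == (rev is None)
        if fwd is not None:
            assert (fwd.tir_len, fwd.mismatches) == (rev.tir_len, rev.mismatches)

    def test_too_short_element_rejected(self):
        with pytest.raises(ValueError):
            find_tir("ACGTACGT", min_len=8)


class TestCallTSD:
    def test_planted_stowaway_ta(self, clean_genome, stowaway_family):
        records = retrieve_insertions(clean_genome.sequences, stowaway_family)
        for r in records:
            call = call_tsd(r, Superfamily.STOWAWAY)
            assert (call.left_tsd, call.right_tsd) == ("TA", "TA")
            assert call.matches_superfamily_rule

    def test_mutator_nine_mer_recovered(self, tsd_genome, mutator_family):
        """All planted random 9-mer TSDs recovered exactly at divergence 0."""
        records = retrieve_insertions(tsd_genome.sequences, mutator_family)
        truth = {(r.chrom, r.start): r.planted_tsd
                 for r in tsd_genome.truth.records if r.family == mutator_family.name}
        assert len(records) == 200
        for r in records:
            call = call_tsd(r, Superfamily.MUTATOR)
            assert call.matches_superfamily_rule
            assert call.left_tsd == call.right_tsd == truth[(r.chrom, r.start)]

    def test_no_duplication_fails_rule(self):
        call = call_tsd_rule("A" * 20 + "GC", "TT" + "G" * 20,
                             TSDRule(pattern="TA"))
        assert not call.matches_superfamily_rule

    def test_short_flank_flagged(self):
        call = call_tsd_rule("TA", "TA", TSDRule(pattern="TA"))
        assert call.short_flank and not call.matches_superfamily_rule


class TestPFMAndDiversity:
    def test_counting(self):
        pfm = build_pfm(["TA", "TA", "TA"])
        assert pfm.counts.tolist() == [[0, 0, 0, 3], [3, 0, 0, 0]]
        pfm2 = build_pfm(["TA", "TT"])
        assert pfm2.counts[1].tolist() == [1, 0, 0, 1]

    def test_unequal_lengths_padded_with_n(self):
        pfm = build_pfm(["TAG", "TA"])
        # position 3 has one N exclusion: column sum 1 of 2 sequences
        assert pfm.counts[2].sum() == 1
        assert pfm.n_sequences == 2

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(0)
        seqs = [random_dna(rng, int(rng.integers(5, 12))) for _ in range(30)]
        pfm = build_pfm(seqs)
        for i in range(len(pfm)):
            n_excluded = sum(1 for s in seqs if len(s) <= i)
            assert pfm.counts[i].sum() + n_excluded == 30

    def test_information_content_boundaries(self):
        assert information_content(build_pfm(["A", "A", "A"]), 1) == 2.0
        assert information_content(build_pfm(["A", "C", "G", "T"]), 1) == 0.0
        assert information_content(build_pfm(["A", "A", "T", "T"]), 1) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=3, max_size=8),
                    min_size=1, max_size=20))
    def test_information_in_range_and_hd_in_range(self, seqs):
        pfm = build_pfm(seqs)
        for i in range(len(pfm)):
            assert 0.0 <= information_content(pfm, i + 1) <= 2.0
        assert 0.0 <= haplotype_diversity(seqs).Hd <= 1.0 + 1e-12

    def test_haplotype_diversity_values(self):
        assert haplotype_diversity(["ACGT"] * 4).Hd == 0.0
        assert haplotype_diversity(["AA", "AC", "AG", "AT"]).Hd == 1.0
        assert haplotype_diversity(["AA", "AA", "CC", "CC"]).Hd == \
            pytest.approx(2 / 3)
        assert haplotype_diversity(["AA"]).Hd == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])
        with pytest.raises(ValueError):
            haplotype_diversity([])


class TestConsensus:
    def test_identical_members_reproduce_member(self):
        seq = random_dna(np.random.default_rng(1), 80)
        assert build_consensus([seq] * 5) == seq

    def test_two_percent_divergence_fifty_members_recovers_original(self):
        rng = np.random.default_rng(2)
        original = random_dna(rng, 150)
        members = [mutate(rng, original, 0.02) for _ in range(50)]
        rebuilt = build_consensus(members)
        assert len(rebuilt) == len(original)
        mismatches = sum(a != b for a, b in zip(rebuilt, original))
        assert mismatches <= 1

    def test_tie_becomes_iupac_code(self):
        assert build_consensus(["AAA", "AGA"]) == "ARA"


class TestDiscovery:
    def test_planted_novel_family_found_exactly(self, novel_tir_family,
                                                stowaway_family):
        from mitescope.simulate import SyntheticGenomeSpec, generate_genome

        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=120_000,
            families_to_plant=[(novel_tir_family, 50, 0.0),
                               (stowaway_family, 30, 0.0)],
            seed=95)
        genome = generate_genome(spec)
        catalog = FamilyCatalog(families=[stowaway_family])
        found = discover_families(genome.sequences, catalog)
        assert len(found) == 1
        fam = found[0]
        assert fam.copy_number == 50
        assert fam.element_len == 60
        assert fam.tir is not None and fam.tir.tir_len == 11
        assert fam.tsd_pattern == "TA"
        truth_loci = {(r.chrom, r.start, r.end) for r in genome.truth.records
                      if r.family == "SynNovel"}
        assert set(fam.member_loci) == truth_loci

    def test_min_copies_threshold(self, novel_tir_family, stowaway_family):
        from mitescope.simulate import SyntheticGenomeSpec, generate_genome

        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=120_000,
            families_to_plant=[(novel_tir_family, 50, 0.0)], seed=95)
        genome = generate_genome(spec)
        assert discover_families(genome.sequences, None, min_copies=60) == []

    def test_catalog_only_genome_yields_nothing(self, stowaway_family):
        from mitescope.simulate import SyntheticGenomeSpec, generate_genome

        spec = SyntheticGenomeSpec(
            subgenome_labels=["A"], n_chromosomes=1, chromosome_length=100_000,
            families_to_plant=[(stowaway_family, 40, 0.0)], seed=96)
        genome = generate_genome(spec)
        catalog = FamilyCatalog(families=[stowaway_family])
        assert discover_families(genome.sequences, catalog) == []
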