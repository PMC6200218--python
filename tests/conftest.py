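"""Shared fixtures: deterministic consensus sequences and synthetic genomes.

Expensive genomes are session-scoped so several tests can reuse one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitescope._util import random_dna, revcomp
from mitescope.catalog import MITEFamily, Superfamily
from mitescope.simulate import SyntheticGenomeSpec, generate_genome


def make_consensus(seed: int, length: int) -> str:
    return random_dna(np.random.default_rng(seed), length)


@pytest.fixture(scope="session")
def stowaway_family() -> MITEFamily:
    return MITEFamily("SynStow", Superfamily.STOWAWAY, 158, "TA",
                      make_consensus(101, 158))


@pytest.fixture(scope="session")
def tourist_family() -> MITEFamily:
    return MITEFamily("SynTour", Superfamily.TOURIST, 280, "TWA",
                      make_consensus(102, 280))


@pytest.fixture(scope="session")
def mutator_family() -> MITEFamily:
    return MITEFamily("SynMut", Superfamily.MUTATOR, 350, None,
                      make_consensus(103, 350))


@pytest.fixture(scope="session")
def novel_tir_family() -> MITEFamily:
    """A 60-bp Stowaway-like element with an exact 11-bp TIR.

    The seed is chosen so the terminal inverted repeat does not extend by
    chance beyond 11 bp at <= 2 mismatches, keeping the TIR length sharp.
    """
    from mitescope.structure import find_tir

    for seed in range(300, 400):
        rng = np.random.default_rng(seed)
        tir = random_dna(rng, 11)
        seq = tir + random_dna(rng, 38) + revcomp(tir)
        ann = find_tir(seq)
        if ann is not None and ann.tir_len == 11 and ann.mismatches == 0:
            return MITEFamily("SynNovel", Superfamily.STOWAWAY, 60, "TA", seq)
    raise AssertionError("no suitable seed found")


@pytest.fixture(scope="session")
def clean_genome(stowaway_family):
    """100 undiverged Stowaway copies on a 2-chromosome A/B genome."""
    spec = SyntheticGenomeSpec(
        subgenome_labels=["A", "B"], n_chromosomes=1, chromosome_length=150_000,
        families_to_plant=[(stowaway_family, 100, 0.0)],
        nesting_fractions={"TE_classII": 0.15, "gene_intron": 0.1,
                           "gene_3utr": 0.1, "upstream_le100": 0.1},
        seed=1001,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def diverged_genome(stowaway_family):
    """500 Stowaway copies at 5% per-site divergence (recall/precision runs)."""
    spec = SyntheticGenomeSpec(
        subgenome_labels=["A", "B"], n_chromosomes=1, chromosome_length=350_000,
        families_to_plant=[(stowaway_family, 500, 0.05)],
        seed=1002,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def tsd_genome(stowaway_family, tourist_family, mutator_family):
    """200 undiverged copies of each superfamily rule on one genome."""
    spec = SyntheticGenomeSpec(
        subgenome_labels=["A", "B"], n_chromosomes=1, chromosome_length=400_000,
        families_to_plant=[(stowaway_family, 200, 0.0),
                           (tourist_family, 200, 0.0),
                           (mutator_family, 200, 0.0)],
        seed=1003,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def inheritance_parent(stowaway_family):
    """500-insertion parent genome for common-insertion analysis."""
    spec = SyntheticGenomeSpec(
        subgenome_labels=["A", "B"], n_chromosomes=1, chromosome_length=350_000,
        families_to_plant=[(stowaway_family, 500, 0.0)],
        seed=1004,
    )
    return generate_genome(spec)
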