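# Methods

This note documents the models, conventions and numerical choices behind
mitescope, in the order the pipeline runs them.

## The family catalog and TSD rules

A MITE family is a named consensus sequence with a superfamily and a
target-site-duplication (TSD) preference.  The superfamily fixes the rule:
*Stowaway* → the fixed dinucleotide `TA`; *Tourist* → the IUPAC pattern `TWA`
(W = A/T); *Mutator* → a sequence-unconstrained duplication of 7–10 bp;
families of unknown superfamily use their catalog-recorded pattern, or an
unconstrained 2–10 bp duplication when none is recorded.

The packaged catalog (`mitescope/data/wheat_mite_catalog.tsv`) transcribes the published
characterization of 36 wheat MITE families: consensus length, TSD preference
and copy number in each of four species (hexaploid bread wheat, tetraploid
wild emmer, the diploid D donor *Ae. tauschii* and the diploid A donor
*T. urartu*).  A companion table (`subgenome_counts.tsv`) records the
published per-sub-genome counts (whole-genome, *Thalos* and *Minos*
breakdowns).  These copy numbers are **inputs**: genome-scale totals cannot
be recomputed without the multi-gigabase wheat drafts, so every percentage
the package reports about wheat is division over this fixture, never a
rescan.  The percent columns printed alongside the original table are not
shipped — they are internally inconsistent with the table's own copy numbers
— and percentages are always recomputed from counts.  The *Inbar* consensus
length is stored as 58 bp; the conflicting 68 bp mention elsewhere in the
source material is kept in the fixture's notes column.  Consensus sequences
of the public families live in external repeat databases and are not
redistributed; the loader attaches any user-supplied consensus FASTA, and
all tests use synthetic consensi.

## Synthetic genomes

The simulator builds what the downstream stages need to be measurable:

* **Background** is i.i.d. nucleotides at a configurable GC content
  (default 0.46).  There is deliberately no repeat structure beyond what is
  planted, so any false positive is attributable to chance alone.
* **Chromosomes** are named `<group><subgenome>` (e.g. `3B`), giving each
  record a sub-genome label and homoeologous group for tabulation.
* **Genes** have a fixed architecture — 5'UTR (200 bp), CDS (400), intron
  (500), CDS (400), 3'UTR (300) — on a random strand; **host TEs** are 3–16 kb
  intervals labeled class I / class II (capped at 1/8 of the chromosome on
  small test chromosomes).  Both are placed uniformly in the free gaps with a
  300 bp margin, largest-first so fragmentation cannot starve a large host.
* **Insertions**: each planted copy is the family consensus mutated at the
  stated per-site substitution rate (no indels, so identity is exactly one
  minus the substitution fraction; the realized fraction is capped at
  rate + 0.05 so the stated identity floor holds for every copy), reverse
  complemented on the minus strand, and spliced in as
  `host[:p-k] + TSD + element + TSD + host[p:]` — the duplication overwrites
  the k host bases left of the insertion point, exactly the footprint a
  cut-and-paste insertion leaves.  Genomic contexts (intergenic, inside a
  class I/II host, intron/exon/UTR, ≤ 100 bp up/downstream of a gene) are
  sampled from the requested nesting fractions and recorded in the truth
  table.
* **Polyploid derivation** copies every parental chromosome; each parental
  insertion is retained with probability `inherit_fraction`, otherwise
  excised by removing the element plus one TSD copy, leaving a single TSD at
  the empty site.  The single-TSD excision is a simulator convention (how a
  vacated site looks in a real genome is not modeled); lost records are kept
  with lineage `parent_unique`, retained ones become `inherited`, and fresh
  intergenic insertions are added as `child_unique`.  These labels are the
  oracle for common-insertion analysis.

What the simulator does **not** emulate: real base composition and repeat
landscape (wheat is ~80% repeats; here the background is memoryless),
indel divergence, fragmented/nested TE decay products, segmental duplication
or recombination.  Passing tests therefore demonstrate the correctness of
the pipeline's logic under its stated model, not its performance on a real
wheat assembly, where repeat-induced ambiguity would dominate.

## Homology retrieval

Retrieval is seed-and-extend local alignment: exact 11-mer seeds between the
family consensus and the chromosome are grouped by diagonal (±50) into
windows, and each window is resolved by an exact affine-gap Smith–Waterman
DP (numba-compiled), so every reported hit carries the true optimal local
score for its window; a window holding several copies is realigned with the
previous hit masked until the score drops below threshold.  Scoring: match
+1, mismatch −2, gap of length L costs 5 + 2L.  Significance uses
E = K·m·n·exp(−λ·score) with λ solved from the ungapped Karlin–Altschul
identity at uniform composition (λ = ln((3+√21)/2) ≈ 1.3328 for +1/−2) and a
conservative K = 0.3.  On a 1 Mb genome with a 150 bp query the E ≤ 1e-3
cutoff corresponds to score ≥ 19.

A hit becomes an insertion record when E ≤ 1e-3 **and** the alignment reaches
within 20 nt of both consensus termini — elements truncated by up to 20 nt at
an end are kept as nearly intact, anything more truncated is rejected.  Both
strands are searched; sequences are stored genome-forward with the strand on
the hit.  500 bp flanks are captured per side (shorter at contig edges, with
a truncation flag, never dropped).  Assembly duplicates are removed by exact
string identity of element + both flanks, keeping the copy first in genomic
order; on 1 kb of i.i.d. flank only true assembly-level duplicates collide.

## Structural analysis

* **TIR detection** compares the length-L prefix against the reverse
  complement of the length-L suffix for L in [8, 30] and ≤ 2 mismatches, and
  reports the L maximizing L − 3·mismatches.  A pure "longest within the
  mismatch budget" rule always overshoots a planted TIR, because one or two
  chance-matching positions past the true repeat stay within budget; the
  penalized score makes chance extension strictly unfavorable (expected gain
  0.25·1 − 0.75·3 < 0 per base) while still tolerating genuine mismatched
  TIRs.
* **TSD calling** compares the k-mer immediately left of the element with
  the k-mer immediately right (k from the rule); variable rules take the
  longest exact duplication in range.  Flanks under 10 bp yield a
  `short_flank` non-call.  At divergence 0 recovery is exact; with diverged
  termini the local alignment may clip a mutated terminal base, shifting the
  flank window off the duplication — a real limitation of boundary-based TSD
  calling, reported honestly rather than patched.
* **Logos**: position frequency matrices count A/C/G/T per column with Ns
  (padding for unequal lengths) excluded; per-column information content is
  R = 2 − H bits with no small-sample correction (intended n is in the
  hundreds).  Both the frequency matrix and the information vector are
  emitted so either logo rendering is reproducible.
* **Haplotype diversity** is Hd = n/(n−1)·(1 − Σp²) over distinct sequence
  strings (0 when n = 1).
* **Consensus building** is a center-star scheme: the longest member anchors,
  every other member is globally aligned to it (Biopython pairwise aligner),
  columns vote by majority, base ties become IUPAC codes, gap-majority
  columns drop, and insertions relative to the center are ignored.  The
  contract is consensus recovery under simulated divergence, not equivalence
  with any particular multiple-alignment program.

## De novo family discovery

Candidate elements are segments whose terminal 8-mers are reverse
complements (found via a windowed k-mer index; the anchor is also slid up to
2 bp inward so one terminal mutation cannot hide a copy), whose length is
50–800 bp, which pass the TIR check, and which are bounded by a duplicated
target site under any superfamily rule — the cheap `TA` check runs first.
Candidates are single-linkage clustered at ≥ 80% identity (edlib edit
distance, either strand).  Within a cluster, overlapping variants at one
locus are collapsed preferring the cluster's modal length: with a
palindromic TSD like `TA`, a chance TIR extension across the duplication can
shift boundaries at a few loci, and the modal length recovers the planted
boundary.  Clusters matching a known-catalog consensus at E ≤ 1e-3 are
dropped; survivors with ≥ 20 copies are reported with a consensus, TIR
annotation and observed TSD.  The parameters (min copies, cluster identity)
are this package's choices — the discovery procedure is a reconstruction of
an under-specified "computer-assisted" search.

## Annotation

Each insertion is annotated twice.  Homology: 5' flank, 3' flank and element
body are independent local-alignment queries against the reference entries
(gene pre-mRNA spans, host-TE library with class labels, ncRNA) at E ≤ 1e-10;
the single best hit — lowest e-value, ties to higher score, then
lexicographic target id, so reference order can never change a call — fixes
the category, no hit means `unknown`.  The flanks are queried separately
rather than concatenated (a merged query could seed chimeric alignments);
the body decides "inside a reference", the flanks decide adjacency, and all
per-query best hits are reported.  For simulated genomes the reference
entries are the **pre-insertion** gene/TE sequences, mirroring a curated
library whose entries do not carry one assembly's nested insertions.
Interval logic: exon overlap (any transcribed part) beats intron overlap;
otherwise an insertion within 100 bp — boundary inclusive, half-open
arithmetic from element boundary to gene boundary — is upstream/downstream
by gene strand.  Transcript-level location is the region holding the
insertion midpoint (5'UTR / CDS / 3'UTR), or `spanning` when more than 10%
of the insertion lies on each side of a region boundary.

## Distribution tables and common insertions

Records are binned by family × sub-genome × homoeologous group; the
sub-genome comes from the chromosome metadata (absent chromosomes go to an
`unknown` bin) and the group from names matching `/^[1-7][ABD]/`.  Summary
percentages are plain division by the grand total, with half-up rounding at
the report's configured precision — two decimals for superfamily fractions,
one for family fractions, integers for sub-genome fractions, matching the
mixed precision of the published values.

Common-insertion analysis pairs same-family records across two genomes when
both flank pairs align at ≥ 90% identity over ≥ 50 bp, **anchored at the
element junction** (a 5'-flank match must reach the right end of both
flanks, a 3'-flank match the left end, with 15 bp slop).  The anchor is
essential: without it, a new insertion of the same family landing within a
flank's reach of a vacated site shares host sequence with the old record and
is miscounted as the same locus; with it, the estimated shared fraction
tracks the true inherited fraction to within ±0.01 in simulation.  Candidate
pairs come from shared 21-mers in the junction-proximal 120 bp of the 5'
flanks, indexed from both sides so the measure is symmetric; verified pairs
are resolved greedily, best identity first, each record in at most one pair.
The identity/overlap thresholds are package choices, robust to 5% divergence
while keeping the chance-match probability on i.i.d. background negligible.

## Pipeline and determinism

All stages run from a single YAML config; every intermediate artifact is a
plain-text TSV/FASTA/GFF3/BED with a header naming the producing stage, and
a JSON manifest records version, parameters, seed and per-stage record
counts.  All randomness flows from one integer seed through
`numpy.random.default_rng` / `SeedSequence`, so a fixed config + seed
reproduces every output byte for byte.  Default problem sizes in the test
suite and acceptance script (genomes of 0.1–0.8 Mb, 50–500 planted copies,
200 copies per TSD rule, four inheritance fractions at n = 500) were chosen
as the smallest scales at which the binomial noise on the measured rates is
well inside the asserted bounds.

## Known limitations

* The aligner requires one exact 11-mer seed; homology below ~85% identity
  or shorter than the seed can be missed.  This matches the near-full-length
  retrieval contract but is not a general-purpose sensitive aligner.
* Nested insertions of the same family closer than a flank length can
  confuse locus identity in genomes far denser than the simulated ones.
* The e-value constant K is a documented conservative default, not fitted;
  e-values are comparable within this package, not across tools.
* Discovery assumes intact termini at most 2 bp eroded; heavily decayed
  families fall below the copy-number threshold by design.
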