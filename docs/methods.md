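# Methods

## The discovery model

The pipeline treats a candidate species-diagnostic primer as a 30-mer that
is (i) present exactly once in its own species' contig set, (ii) absent from
every other species under alignment-aware thresholds, and (iii) usable as a
PCR primer by composition. The choice k = 30 is deliberate: longer than the
usual 18–24-base primer so that a single oligo can carry the whole
species-specificity burden, while short enough that exact counting over
transcriptome-scale contig sets stays trivial.

Counting is forward-strand only and exact; windows containing N are skipped
(an oligo cannot contain an ambiguous base). Reverse-complement collisions
are deliberately left to the specificity screen, which searches both strands
— the same division of labour as a mapper/BLAST-based workflow. A
`canonical` switch exists for canonicalised counting but is off by default.

## Redundancy clustering

Assemblies carry near-duplicate contigs (allelic variants, fragmented
isoforms). Before counting, each species' contigs are collapsed by greedy
clustering: longest first (ties broken by id), each contig joins the first
representative it matches at ≥ 95% identity, where identity is computed by
semi-global alignment of the shorter sequence within the longer
(edit-distance based, via edlib) and measured against the shorter sequence's
length — the short-sequence-coverage convention of transcript-redundancy
tools. N counts as a mismatch. Word size or coverage pre-filters are
unnecessary at the scales this tool targets; correctness is what matters,
and the greedy order makes results deterministic.

## Gene selection (optional)

When a reference FASTA of intronless genes is supplied (protein or
nucleotide, autodetected by alphabet), contigs are assigned to their
best-scoring reference by local alignment — six-frame translated alignment
with BLOSUM62, gap open 11 / extend 1 for protein references; +2/−3
nucleotide scoring otherwise. Assignments below 40% identity or 50%
reference coverage are dropped; one best hit per contig is kept.

Paralogy is flagged per (gene, species): if a second contig scores within a
ratio r of the best (default r = 0.8), the species' relationship to that
gene is ambiguous and all its assignments there are excluded; otherwise only
the best contig is kept. **Calibration note:** r should match the divergence
regime of the paralogs one wants to catch. Duplicates at ~90% nucleotide
identity score roughly 0.72–0.87 of their template against an external
reference under BLOSUM62, so r = 0.7 is the appropriate setting when such
old duplicates matter; the 0.8 default targets recent, near-identical
duplicates. False flags are impossible for species contributing a single
contig to a gene, so lowering r is cheap.

Genes represented in fewer than two species after flag removal are dropped.
The whole module is optional — the pipeline runs directly on user contig
sets — because the intronless restriction exists only to keep genomic PCR
product sizes equal to transcript-predicted sizes.

## Composition filters

All rules are evaluated on every candidate (no short-circuit) and reported
by name, so the output shows which rule dominates the funnel.

| rule | condition (removal) | default |
| --- | --- | --- |
| TM | Tm outside [67, 82] °C | `gc_basic`: 81.5 + 0.41·%GC − 675/N |
| GC_FULL | G+C count outside [11, 17] per 30-mer | |
| GC_HALF | either 15-mer half outside [4, 10] | |
| END_BOTH_AT | both terminal bases in {A, T} | |
| END_GC_RUN | ≥ 3 G/C in *both* 5-base end windows | window 5 |
| END_AT_RUN | ≥ 3 A/T in *both* 5-base end windows | window 5 |
| HOMOPOLYMER | single-base run ≥ 4 | |
| DINUC_REPEAT | ≥ 3 tandem copies of XY (X≠Y) | |

Numerical conventions worth stating: the Tm formula is the classic
GC-fraction estimate, scale-consistent with the 67–82 °C band at N = 30; the
method label is recorded in output metadata and the implementation is
pluggable. Since any 5-base window contains ≥ 3 G/C or ≥ 3 A/T, the two
end-window rules can only pass when the two ends are enriched for *opposite*
classes; this is intended (it rejects oligos with two weak or two over-strong
ends). For odd k the two "halves" are the first and last ⌊k/2⌋ bases, the
middle base in neither. Homopolymeric dinucleotides (XX) are excluded from
the repeat rule as the run rule's territory. For non-30-mer oligos (partner
primers), the count-based GC bounds rescale proportionally to length.

## Specificity screen

Stage 1 (exact) removes a candidate when its full-length sequence occurs
more than once in its own species (both strands) or when any 26 consecutive
bases occur verbatim in another species. It is implemented with sorted
2-bit-packed window tables per species and is the cheap bulk filter.

Stage 2 (local) is a short-query BLAST analogue: exact 7-base seeds, both
strands, ungapped extension at +1 match / −3 mismatch. On every seeded
diagonal the *optimal* ungapped segment is computed (a vectorised maximum-
subarray over the ≤ 30-column diagonal band); this is the alignment an
X-drop extension converges to, and never shorter than what an X-drop with
any finite drop-off would report. Alignment length is counted in aligned
columns (the BLAST convention). Removal rules:

* **SAME_EXTRA** — any same-species alignment of ≥ 24 columns besides the
  candidate's own source locus (the full-length self-hit is unavoidable and
  excluded; a second near-full-length hit counts as multiple mapping).
* **OTHER_LOCAL** — any other-species alignment of ≥ 26 columns (> 25 bp).

Candidates are screened in batches vectorised across candidates; the batch
path is asserted (in tests) to agree hit-for-hit with the single-candidate
reference path.

Known limitations: extension is ungapped, so a > 25-column *gapped*
cross-species match whose ungapped pieces all stay below the thresholds
would be missed — at these lengths such a hit is also a poor PCR binding
site, but it is a real blind spot. Seeding requires a 7-base exact run, so
alignments whose mismatches are spread so densely that no 7-run exists
(≥ ~4 mismatches inside 24 columns) are invisible to both this screen and
to comparable seed-based tools.

## Partner proposal and in-silico PCR

For a surviving candidate, partner windows of 24–40 bases are enumerated on
its source contig in both orientations (candidate as forward or reverse
primer) with implied product sizes in [80, 800] bp, ranked by product size
closest to the middle of that range and then by Tm proximity to the
candidate. Each window must pass the length-rescaled composition filters
and, by default (`require_partner_filters`), the full two-stage specificity
screen; surviving windows are assembled into pairs and kept only if the
in-silico PCR judges them SPECIFIC on the same universe. At most
`max_proposals` pairs are returned and at most `max_screened_windows`
windows are screened.

The binding model is the standard in-silico PCR convention: Hamming
distance (no indels) ≤ 2 mismatches per primer with the 3'-terminal 3 bases
exact; all convergent site pairs with product ≤ 800 bp are reported, a
species with none gets an empty prediction. Verdicts: **SPECIFIC** iff
exactly one species amplifies and it is the target; **NONSPECIFIC** if any
non-target amplifies; **NO_AMPLIFICATION** otherwise.

Design note: requiring the partner itself to pass the cross-species screen
is stricter than biologically necessary — a conserved partner still yields a
species-specific assay because the diagnostic primer controls specificity,
and published assays of this kind typically use conserved partners. With
the default flag on, partner proposal on *closely related* species sets can
therefore legitimately return nothing; set `require_partner_filters = false`
to allow conserved partners (pairs are still validated by in-silico PCR).

## Synthetic data generator

The generator emulates the pipeline's intended input: per-gene ancestral
random sequences, mutated independently per species by substitutions only
(uniform over the three alternatives), one contig per gene per species.
`divergence` is the expected per-site distance of each species from the
ancestor (scalar or per-species vector; the realised pairwise distance
between two species is correspondingly larger). Substitution-only mutation
keeps planted coordinates valid. All randomness flows from a single seeded
numpy `default_rng` (PCG64), so a given SimSpec reproduces byte-identical
FASTA anywhere.

Planted signal:

* **markers** — random composition-passing 30-mers overwritten into one
  species, accepted by rejection sampling only if they occur exactly once in
  the whole dataset (both strands) and survive the actual specificity
  screen; a bounded number of failed attempts raises with advice to use
  longer genes.
* **decoys** — a marker whose first L ∈ {24, 25, 26, 30} bases are copied
  into a second species (or a second site of the same species), with the
  flanking base on each side of the copy forced to mismatch so the shared
  block cannot extend by chance; the truth table records the expected fate
  (L ≤ 25 survives; L ≥ 26 removed as OTHER_EXACT; same-species 24–29 gives
  SAME_EXTRA, 30 gives SAME_MULTIMAP), and the generator verifies the
  expectation against the real screen before accepting the plant.
* **paralogs** — a within-species duplicate of a gene at 90% nucleotide
  identity with substitutions redrawn when they would create a new in-frame
  stop codon, so the duplicate still aligns full-length to the gene's
  translation and score-ratio flagging can see it.

What the generator does **not** emulate: indels, expression-dependent
coverage, isoforms, assembly artifacts and sequencing error. Passing the
planted-truth tests therefore demonstrates the correctness of the decision
logic at its thresholds, not robustness to misassembly; on real data the
clustering stage and the screen's mismatch tolerance absorb some, not all,
of those effects.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at up to
5 species × 50 genes × 1.5 kb (k = 30), the scale at which all stages
together complete in a few minutes on one core; the divergence sweep uses
3 species × 20 genes × 1.2 kb over divergences 0–0.20. Candidate output
order is always (species, contig, offset); manifests record a configuration
hash and per-stage counts, and identical config + seed reproduce all
outputs byte-identically. Intermediate files carry a one-line header with
stage name and k so stages cannot be silently mixed.
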