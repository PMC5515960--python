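# Methods

This note records the models, conventions, numerical choices and known
limitations behind `natseek`, in the order the pipeline runs.

## Coordinates and strand handling

All interval logic uses 0-based, half-open coordinates with a mandatory
strand; GFF3/GTF conversion (1-based closed → internal) happens only at
the I/O boundary. Unstranded (`.`) features are rejected rather than
guessed: the entire method is strand-specific, and a mis-assigned strand
would silently turn a sense transcript into an antisense call. The
nucleotide alphabet is ACGTN, uppercased on entry; N never base-pairs and
counts as a mismatch in every comparison.

## Transcript units

Genes and assembled transcripts merge into a unit when their *spans*
overlap by ≥ 1 bp on the same strand, taken to transitive closure.
Span-level (intron-inclusive) overlap is deliberate: an intron-only
overlap still marks a single transcribed locus, and read-pileup views of
loci treat them as spans. Abutting intervals do not merge (overlap means
shared bases). Unit ids are assigned in (scaffold, start, strand) order,
so clustering is invariant to input order.

## cis-NAT admission and classification

A candidate antisense unit is a unit with no predicted-gene member; units
containing a gene are sense-side loci. Admission requires the overlap to
reach 10% of the length of *at least one* partner. The source rule speaks
of "either transcript", which we read as the weaker (OR) condition; the
stricter AND reading is available via `overlap_rule="both"`. Overlap is
computed on spans; exon-level overlap was considered and rejected as the
default for the same reason as in unitization.

Classification checks containment first (identical spans degenerate to
N > S); otherwise exactly one end of the sense transcript is overlapped,
and the 5′ end means divergent, the 3′ end convergent. Because
containment is resolved first, "both ends overlapped without containment"
cannot occur and there are no ties. The classification is symmetric under
mirroring the locus (coordinates reflected, strands flipped).

## trans-NAT search

The complementarity search replaces an external BLASTN step with an
exact 12-mer seed over the reverse-complemented partner, extended across
*isolated* single mismatches while the region identity stays ≥ 0.8
(configurable; the identity floor is a permissive choice, since the
printed criteria act on length and coverage, not e-values). Regions are
gap-free by definition: both spans have equal length. The "100-nt pair"
rule is strict (> 100 nt), and "high-coverage" means the region exceeds
50% of at least one sequence (`coverage_rule` mirrors the cis choice).

Duplex annealing replaces a thermodynamic folding step with a
deterministic local alignment (match +1, mismatch −1, gap open −2, gap
extend −0.5) of the seed's neighborhood (±100 nt) against the reverse
complement of the partner's. Two post-processing rules make the annealed
region physically sensible:

* **Minimum helix (3 bp).** Interior paired runs shorter than 3 columns
  are absorbed into the surrounding unpaired stretch. A lone base pair
  inside a loop cannot nucleate a helix; without this rule the aligner
  can shred one large bubble into several small ones via spurious 1–2 bp
  matches and evade the bubble criterion.
* **Block trimming.** The annealed region is the maximal-scoring
  contiguous run of columns (+1 paired / −1 unpaired). This trims weak,
  noisy extension of the local alignment into random flanking sequence,
  which would otherwise inflate the region length and import artificial
  bubbles.

A bubble is a maximal interior run of unpaired columns; terminal
overhangs are not bubbles. The duplex passes when the annealed block
shares at least one base with the seed on both sequences and every bubble
is ≤ 10% of the block's column length (bubble included).

"Located remotely" is implemented as: different transcript units and zero
genomic span overlap; a minimum-distance knob exists but defaults to 0,
as no quantitative definition is printed anywhere we could adopt.

## Non-coding filter cascade

Boundary semantics are exact and tested: length 200 fails (keep requires
> 200 nt); an ORF of exactly 100 aa passes (removal requires > 100); a
CPC score of exactly 0 fails (keep requires < 0, the stricter of the two
printed readings); an e-value exactly at a cutoff disqualifies. The ORF
scan covers the three forward frames of the transcript's own strand —
coding potential is read 5′→3′ — counting ATG-initiated, stop-terminated
frames with the standard code, stop excluded; codons containing N
translate to X and are never stops. Evidence tables stand in for external
database searches; a missing table is a vacuous pass with a warning, or a
hard error in strict mode. Because cis-NAT entities are transcript units,
a unit's sequence is its strand-oriented span sequence and its evidence
is aggregated over member transcripts (minimum e-value, maximum coding
score — the worst case for the candidate). Evaluation stops at the first
failing step, which is what makes the per-step funnel counts meaningful.

## Expression and SAT characterization

RPKM uses the standard 10⁹ · reads / (library · length) scaling (the
convention is not printed in the source analysis; precomputed RPKM input
bypasses it). Presence is RPKM ≥ 2, inclusive at the boundary, and the
three-stage Venn partition requires exactly three stages. Unit-level
expression aggregates member transcripts by element-wise maximum —
presence of any member marks the locus present; antisense units are
almost always single-member, where this is the identity.

Profile normalization is log2(x + 1) followed by division by the
profile's mean or maximum (log base and pseudocount are our choice; they
affect relative profiles only, not correlation signs). Pearson
significance uses t = r / √((1 − r²)/(N − 2)) with a one-tailed
(directional) p in the direction of the observed r; a two-tailed flag
exists. Perfect correlation reports t = ±∞, p = 0; zero-variance profiles
raise rather than emit NaN silently, and the pair-table writer flags them
in a note column. N is always an explicit argument (profiles may carry
stage means or replicate points; nothing is assumed).

## Enrichment

The hypergeometric upper tail is inclusive, P(X ≥ x) (an exclusive-tail
flag exists), computed via `scipy.stats.hypergeom.sf` and verified in
tests against exact rational enumeration for populations ≤ 60 and
against a large-margin printed bound. FDR is Benjamini–Hochberg over
*all* tested categories; the "≥ 4 mapped STs" rule is applied afterwards
as a reporting filter, since the source's ordering of the two steps is
unstated. The draw count N defaults to the number of distinct STs tested
and is overridable, because annotated-subset analyses are ambiguous about
it.

## Synthetic data generator

The generator emulates a small multi-scaffold genome (6 × 30 kb by
default, uniform ACGT at GC 50%, with a GC knob) with stranded genes
(some intron-bearing), sense transcript copies, and planted structures:

* three cis SAT pairs per configuration (overlap fractions drawn in
  0.3–0.7 of the NAT, partial-overlap geometry mirrored for minus-strand
  genes);
* multiplex motifs giving 1:n, n:1 and n:n relationships (a NAT bridging
  two genes, a chain of three genes with two bridging NATs);
* remote complements for trans pairs, embedded in spliced transcript
  sequence with forced-mismatch fences at both ends so planted run
  lengths are exact, plus interior-insertion bubbles (12 nt passing,
  30 nt failing the 10% rule);
* one decoy class per criterion, each violating exactly one rule by a
  stated margin: 5% overlap, 150 nt length, 151-aa ORF, nr hit at 1e-5,
  CPC +1.8, housekeeping hit at 1e-12, small-RNA hit at 1e-15, 90-nt
  complement, 20%-coverage complement, ~15% bubble;
* a three-stage expression matrix with stage-specific presence patterns,
  strongly correlated/anti-correlated ST–NAT profile pairs (multiplicative
  jitter at σ = 0.04), and generic lognormal-like presence elsewhere;
* one deliberately over-represented annotation category.

Planted non-coding antisense transcripts are post-processed to hold no
ORF above 100 aa (in-frame stops are inserted deterministically), so the
ORF filter is exercised only by its dedicated decoy. Planted antisense
transcripts are single-exon, making spliced and span sequences coincide —
the one simplification that unit-level filtering relies on. The same
seed yields a byte-identical bundle.

What the generator does **not** emulate: read-level noise and coverage
gaps (transcripts are exact), GC heterogeneity between classes,
alternative isoforms of NATs, fragmented NAT assemblies, and genuine
coding sequence statistics. Passing the recovery suite therefore shows
the pipeline implements its stated rules exactly on clean inputs; it does
not certify behavior on noisy real assemblies, where threshold choices
dominate.

## Problem sizes and calibration

The default fixture holds ~41 genes and ~44 transcripts on a 180-kb
genome; the full pipeline runs in a few seconds. The correlation
attenuation study uses 1000 bivariate-normal pairs at N = 3 per profile:
the sample mean of r recovers the planted ρ = ±0.9 to within 0.1 (small-N
attenuation brings ±0.9 to about ±0.82). The enrichment null calibration
draws the tested set uniformly 1000 times against 50 categories of 200
genes in a population of 4000 with 600 draws — margins chosen large so
tail discreteness does not mask the nominal level; the observed rate of
p < 0.05 is ≈ 4.5%.

## Known limitations

* Cis catalog entities are units, so two same-strand overlapping
  antisense transcripts merge into one NAT locus; fragmented assemblies
  will undercount NATs (and the 1:n validation caveat of the underlying
  method applies).
* The duplex model is an alignment, not thermodynamics: no ΔG, no
  temperature, and bubble geometry is approximated by alignment columns.
* The complementarity search's identity floor and seed length bound the
  detectable divergence between trans partners; highly diverged duplexes
  (identity < 0.8, or no exact 12-mer) are invisible.
* Enrichment takes annotations as given — no ontology-graph propagation.
* With N = 3 stages, correlation p-values are hardly ever significant
  individually; they are reported for completeness and sign/aggregate
  analysis, matching the method's use.
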