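# Methods

This note documents the models, conventions and numerical choices behind
`wgpmap`, what its synthetic data does and does not emulate, and where the
design was genuinely open.

## Sequence-tag fingerprinting model

A WGP tag is the read taken inward from an *Eco*RI cut (G^AATTC) on a
fragment of an *Eco*RI/*Mse*I double digest. Tags include the 5-nt AATTC
remnant: sequencing starts at the restriction site, and keeping the remnant
makes every tag directly alignable to genomic sequence. The default tag
length is 30 nt (a 36-nt read minus a 6-nt pool barcode); fragments shorter
than 26 nt yield no tag, fragments of 26–29 nt yield truncated tags, which
reproduces the 26–31 nt tag-length range of the technology.

Cut coordinates are modeled per strand: a rightward read starts at the top
strand cut (site + 1), a leftward read at the bottom-strand cut (site + 5),
and *Mse*I (T^TAA) blocks reads at its top cut (site + 1) rightward and its
bottom cut (site + 3) leftward. These conventions make digestion exactly
strand-symmetric: digesting the reverse complement returns the identical tag
strings with left/right sides swapped (a left tag *is* the bottom-strand
read). Two deliberate simplifications: sequence ends count as fragment
boundaries (a terminal fragment with one internal cut can still emit a tag),
and rare *Eco*RI–*Eco*RI fragments without an intervening *Mse*I site emit
tags from both ends. Both affect only a handful of tags per megabase and no
downstream statistic visibly.

## Synthetic genomes and libraries

`simulate_genome` builds a genome as TE copies interleaved with unique
spacers. Copies are drawn from `n_families` master sequences and mutated at
2% per base (the realized divergence; substitutions always change the base),
so identical tags genuinely recur at distinct loci — the repeat confounding
that drives deconvolution loss and chimera formation. Spacer lengths are
exponential with mean chosen so the requested TE fraction is met in
expectation; the realized fraction is reported and stays within ±0.05 for
genomes of a megabase or more. Master lengths default to 0.8–6 kb.

`simulate_bac_library` draws uniform clone starts and normal insert sizes
(default 138 ± 13.8 kb, truncated below at max(1 kb, mean/5)), filling
384-well plates in order. Insert sequences are materialized lazily from the
genome, so a 42-plate library of 138-kb clones costs kilobytes, not
gigabytes. A configurable fraction of chimeric clones (two concatenated
intervals) exists purely as a QC fixture.

Pooling follows the 3-D design: per plate, 8 row pools (2 plate rows = 48
BACs), 8 column pools (3 columns = 48 BACs) and 6 split-box pools (the k-th
well of every 2×3 box, 64 BACs) — 22 pools per full plate, three pools per
clone, one per dimension. Reads are `barcode + tag` with uniform
substitution errors; position-specific error profiles and adaptor
read-through on truncated tags are out of scope.

What the simulator does **not** emulate: cloning bias, empty or
small-insert wells, cross-well contamination, PCR duplicates, pool-specific
depth variation, and real TE family structure (nested insertions, indel
divergence). Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical model, not performance on any
particular real library.

## Deconvolution and filtering

A tag is assigned to a well of a plate iff, within that plate, it occurs in
exactly one row, one column and one split-box pool; those three pools
intersect in a unique well. Any other pattern (missing dimensions, multiple
pools in a dimension) discards the tag for that plate, and plates are
independent, so multi-plate tags become multi-BAC assignments. On noiseless
input this is sound by construction — two distinct wells always differ in at
least one pool coordinate — which the acceptance suite verifies. The
`min_reads` pool-level threshold (default 1) exists to suppress
sequencing-error ghosts; no depth threshold is part of the published chain.

Filters run in a fixed order — contaminant (exact substring of the screen
set, either strand), homopolymer ≥ 5 nt, single-BAC, more than `max_bacs`
(12) BACs — because the single-BAC rule depends on prior removals. The
BAC-level filter removes fingerprints below 30% or above 2.5× the mean tag
count, the mean being computed after tag filtering; absolute thresholds
(≤ 4 / ≥ 40) are supported for compatibility with published processing.
Filtering is idempotent and each report's stage counts sum exactly to
input − output.

## Sulston score

The score is the upper tail of Binomial(n_hi, q) with
q = 1 − (1 − (2t+1)/G)^n_lo, computed by explicit log-space summation
(`lgamma` binomial coefficients + `logsumexp`), so cut-offs of 1e−75 and
far smaller compare exactly; a scipy binomial-survival cross-check runs in
the unit tests. Defaults are the WGP parameterization: G = 110,000, t = 0,
FromEnd = 8. The acceptance suite validates the closed form against a
10⁶-trial Monte-Carlo simulation of the coincidence null — band positions
i.i.d. uniform on a circular band space — at ten random parameterizations
(G ∈ [80, 200], n ≤ 8, t = 0). Two caveats belong in the open: with
t > 0 and small G the binomial independence assumption deviates from the
simulated null by more than Monte-Carlo precision (a known property of the
classic formula, not of this implementation), and drawing band *sets*
without replacement instead of i.i.d. positions shifts the null enough to be
distinguishable at 10⁶ trials.

## Contig assembly and CB maps

`build_contigs_incremental` takes the transitive closure of
score ≤ cutoff (single linkage, with at least `match` = 1 shared band);
`stepwise_assembly` then runs singleton-to-end joins, end-to-end merges and
DQing at each subsequent cut-off of the schedule (default 1e−75 rising by
10⁵ per step to 1e−05, 15 steps). An end clone is one whose placement starts
within `from_end` (8) CB slots of a contig end. Ties among candidate joins
go to the lowest score, then the smallest contig id — deterministic given
input order. The DQer dissolves contigs with > 10% questionable clones and
re-assembles their clones `dq_step` = 3 stringency steps (×10⁻¹⁵) below the
current cut-off, an interpretation of the established "Step: 3" parameter;
both knobs are configurable. On repeat-rich simulations the questionable-
clone count inflates at the loosest cut-offs and the DQer splits contigs,
raising the contig count again — the qualitative signature that motivates
stopping at 1e−11.

The CB map orders each contig's clones by spectral seriation: the Fiedler
vector of the Laplacian of the overlap-similarity graph (shared bands over
the smaller fingerprint). Seriation by greedy seed-and-insert was tried
first and scrambled large contigs badly (|rank correlation| ≈ 0.46 against
truth on 300-clone contigs, with dozens of spurious Q flags); the spectral
embedding recovers the true order essentially perfectly on the same inputs
and is deterministic (ties broken by clone id, eigenvector sign
canonicalized). Clone offsets accumulate along the order as
`bands(prev) − shared(prev, next)`; consensus slots are the band union
ordered by mean clone offset; `length_cb` is the slot count, so a perfect
tiling path has length_cb equal to its distinct tag count.

A clone is flagged questionable (Q) when fewer than half (`q_threshold`)
of its bands are *corroborated* — shared with at least one contig-mate —
and fall inside a single window of 1.5 × (its band count) consensus slots.
This operationalizes "inconsistent with a single placement interval" for
unordered tag sets; chimeric clones fail it because their foreign tags are
either uncorroborated or far from the main placement window.

## Evaluation against a reference

Tags map to reference sequences by exact full-length matching on both
strands (the search seeds on 5-nt tag prefixes, keeping it linear in the
reference). A BAC is *matched* when strictly more than 50% of its tags map.
A contig is *chimerical* when its matched-BAC placements span two reference
sequences or leave an intra-reference gap larger than `slack` (default
276 kb = 2 nominal BAC lengths). The published rule-of-thumb phrased the
allowance as contig span + slack, but a fusion inflates the contig's own
span and thereby hides exactly the gap it creates, so the span term is
dropped here; with either convention the planted-fusion fixtures in the
tests are unambiguous. The mis-assembled fraction is the percentage of
contig-placed BACs with under 50% of tags mapped; it is computed over all
contig BACs rather than only the matched regions of chimeric contigs — a
simplification that is exact when chimeras are absent or removed first.

CB-unit calibration divides each contig's spanned reference kb by its CB
length and reports mean ± sd (population sd, so identical contigs give 0).
Inter-tag distances are measured between *Eco*RI-site coordinates implied by
the placements, so the two tags flanking one site are 0 bp apart — about a
third of all distances in practice, matching the two-tags-per-site geometry.
The tag landscape uses windows anchored at 0 (default 50 kb sliding by
10 kb, partial tail dropped) and Pearson correlation with a zero-variance
guard that warns and returns r = 0. N90/L90 are computed against a fixed
reference total, not the assembly total, and return a "not reached"
sentinel (None, None) when the pieces cannot cover 90%. K-mer uniqueness
counts canonical (strand-collapsed) k-mers and reports the fraction of
distinct k-mers occurring exactly once; under that definition a homopolymer
scores 0, the degenerate case worth knowing about.

## Scaffolding

A sequence contig is linked to a physical-map unit (contig or singleton
clone) only on evidence of at least two distinct tags from two distinct
restriction sites — flanking tags of one site share a site id and count
once. Sequence contigs on one WGP contig are ordered by the mean
consensus-slot position of their supporting tags; exact intra-BAC tag
positions do not exist in this data, which is precisely why some orders are
unresolvable — those contigs share an unordered bin, and bins are scored as
such (an adjacency into or out of a bin uses the bin's extreme true
positions; within-bin order is never penalized). Sequence contigs eligible
to several WGP contigs vote on the relative order of those contigs with
weight equal to their supporting tag count; contradictions drop the weaker
link (ties drop both) and are reported as conflicts, never raised as
errors. Element orientation is the majority strand of its placements.
Inter-element gaps are unsized — emitted as AGP type-U components and
fixed 100-N spacers in FASTA — because gap sizes are unknowable de novo.
Superscaffold order error is orientation-invariant (minimum over the two
global orientations).

## Problem sizes and determinism

Every stochastic function takes an explicit integer seed; there is no
hidden global RNG state, and identical config + seed gives byte-identical
outputs. The test and acceptance simulations use desk-scale versions of the
study conditions: a repeat-free 5-Mb genome at 9× clone coverage (326
clones of 138 kb) for layout recovery, a 384-clone plate set on 4 Mb for
deconvolution soundness, 4 × 384 clones at ~46% per-plate coverage for the
pipeline demonstration, and 10⁶ Monte-Carlo trials per Sulston
parameterization. At these sizes the full test suite runs in about a
minute and the acceptance script in about half a minute on one CPU.

## Known limitations

- The CB map is a simplified consensus (spectral seriation + weighted mean
  slots), not a full consensus-band optimization with simulated annealing;
  it is validated by CB-unit and layout recovery, not band-exactness.
- Banded (sized-fingerprint) mode implements greedy one-to-one matching and
  shares the assembly machinery, but consensus slots treat band values as
  identities; it stands in for gel fingerprinting only at the resolution the
  tests exercise.
- The C1²/C2 chimera score is computed and comparable between contigs, but
  no default verdict threshold is set — the discriminating value is
  genome-dependent and must be established per dataset.
- Deconvolution is combinatorial, not probabilistic: ambiguous observations
  are discarded, never apportioned by an EM-style model.
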