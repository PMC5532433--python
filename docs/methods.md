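# Methods

This note documents the models, parameter choices, and numerical decisions
behind `halocrust`, and what the synthetic test bed does and does not show
about real data.

## Genome de-replication

Two bins belong to one species-level cluster when their scaffolds align at
≥98% nucleotide identity over more than 70% of a genome. The grouping is
single linkage: the pairwise rule "shared over 70% → same group" is applied
transitively, which is the only reading under which a set of mutually
overlapping bins forms one cluster.

**Shared-fraction basis.** The denominator of the shared fraction is the
smaller genome by default (`basis="smaller"`), because true replicate bins
routinely differ in completeness: a fragment of a genome shares ~100% of
*its* nucleotides with the complete bin and should be collapsed, not kept.
`basis="larger"` is available for the stricter reading.

**Alignment engine.** Desk-scale substitute for nucmer-class aligners:
exact 15-mer anchors are grouped by gapless diagonal and the full overlap
window on each diagonal is scored in ~500 bp blocks; a block counts as shared
when its identity meets the 98% threshold. The engine is substitution-only
(no indels), matching the read simulator and the Hamming-placement mapper;
on real data with indel divergence it would under-report shared fractions
near the threshold. Candidate bin pairs are pre-filtered by sampled k-mer
sketches so unrelated genomes are never aligned.

**Scoring.** Completeness = percent of the domain's SCG set present at least
once (51 bacterial, 38 archaeal); multi-copy SCGs do not reduce completeness
but penalize the representative score `presence − 2 × multi`. Ties are broken
by total length, then lexicographic bin id (logged), which makes
de-replication invariant to input order.

## rpS3 and nitrogenase profiling

Profiles are linear match-state chains built from seed alignments: columns
with <50% gaps become match states; emissions are Laplace-smoothed
(pseudocount 1) column frequencies as log-odds against a uniform 1/20
background. Scoring is local Viterbi with affine gaps (open 4 bits, extend
1 bit) and free entry/exit at any match state — hmmsearch-like domain
semantics without Plan7 loop states or E-values. The exact rpS3 seed
alignments of the original survey are not published, so the bundled
alignments are synthetic (eight sequences per domain, ~10% divergence from
an independent random ancestor per domain); they preserve the quantities
that matter to the pipeline's logic — per-domain score separation and the
absolute cutoffs (bacteria 111, archaea 172, eukaryotes 175 bits) — but not
real rpS3 sequence content.

ORFs come from a maximal stop-to-stop scanner on all six frames (standard
code), not a trained gene caller; the generator plants markers bounded by
in-frame stops so the scanner recovers genes exactly. Marker clustering is
greedy length-sorted centroid clustering (cluster_fast style) on protein
sequences at a default 0.99 identity — the survey's clustering threshold and
sequence level are unstated; 0.99 on protein gives species-level resolution
consistent with "unique" marker sequences, and the threshold is exposed.

The nitrogenase screen applies 14 synthetic nif profiles (nifH/D/K/E/N/B/Q/
V/W/Z/T/X/U/S), each with a 40-bit noise cutoff. 40 bits was chosen so that
a chance local alignment of an unrelated protein (observed ~14–21 bits for
random 300-mers) has essentially no mass near the cutoff, while a planted
consensus cassette scores ~350 bits.

## Read mapping and abundance

A read is accepted iff its best end-to-end placement on either strand has at
most ⌊0.03·L⌋ mismatches — exactly 3 for the survey's 100 bp reads —
generalized by read length so the 97%-identity contract holds for any L.
Seeding is pigeonhole-exact: the read is split into (max_mm + 1) chunks, one
of which must match exactly for any acceptable placement, so acceptance is
identical to a brute-force Hamming scan (verified against one in the test
suite). There are no indels in the mapper by design. Reads with equal-best
placements on several references are counted 1/k to each (configurable to
discard); the original analysis does not state its policy.

Relative abundance = mean per-nucleotide depth × (deepest sample's read
count / own read count). This per-sample scaling interpretation of
"sum normalized ... using the total number of reads" preserves within-sample
ratios and cancels sequencing effort; a matrix-wide alternative would mix
samples' depths. Presence requires normalized coverage ≥ 1.0 fold — the
survey never states its presence criterion, so the threshold is prominent in
the config and logged.

## CRISPR typing

Arrays are runs of ≥3 near-identical repeats (23–55 bp, ≤2 mismatches to the
consensus) separated by 25–60 bp spacers that must be mutually distinct (≥2
edits) — identical "spacers" mean a tandem repeat, which is rejected. These
windows follow CRISPRfinder conventions, the tool the survey delegated
detection to. Orientation is canonicalized to the lexicographically smaller
of repeat/reverse-complement; spacer lists are leader-first. The leader end
is the acquisition end: variants carrying extra spacers differ at index 0.

Locus types are connected components of the graph linking arrays with equal
repeat consensus that are identical, leader-end (terminal) variants, or
share ≥2 spacers; sharing a single spacer leaves loci distinct, mirroring
the observed gap between grouped loci and loci that "share only one spacer".
Variants within a type are exact spacer-list classes lettered a, b, c… by
decreasing spacer count. In the bundled 26-sample fixture this lettering
makes the identical cross-site pair variant 1b: the group's longest array
(1a) carries four extra leader spacers, and 1c lacks a further three — the
only arrangement consistent with both described group-1 relations at once.

## Ecology battery

All tests are implemented here (scikit-bio and scipy serve as independent
cross-checks in the tests, not as the implementation):

* **Bray–Curtis**: Σ|x−y| / Σ(x+y) per sample pair; an all-zero sample pair
  is undefined and raises.
* **NMDS**: SMACOF-style majorization of Kruskal stress-1 with isotonic
  regression of configuration distances on dissimilarity ranks; first start
  initialized from classical scaling, remaining starts random (default 50);
  convergence declared when the two best starts agree under Procrustes
  (disparity < 1e-4); k = 2 by default.
* **MRPP**: δ = Σ (n_g/N)·(mean within-group d); A = 1 − δ_obs/E[δ] with
  E[δ] the mean over permuted label assignments; plain d (not d²), group
  weights n_g/N — standard choices the survey does not specify.
* **PERMANOVA**: Anderson's distance-based sums of squares
  (SS_T = Σd²/N), single factor only.
* **BioENV**: exhaustive subsets of ≤12 z-scored variables, Euclidean env
  distances, Spearman rank correlation with the community matrix. Variables
  were z-scored (the survey does not say); constants are dropped.
* **Mantel**: Pearson by default (Spearman by flag), simultaneous
  row/column permutation, one-sided.

Permutation p-values use the add-one convention
p = (#{extreme} + 1)/(n_perm + 1), so p is never 0 and the observed
statistic is part of its own null; 999 permutations by default. All tests
take explicit seeds and are exactly reproducible.

## Synthetic community

Genomes are i.i.d. uniform nucleotides with embedded cassettes — a
composition-neutral test bed. Defaults encode the survey's design: the
genome panel holds 115 species (65 Halobacteriales, 31 Bacteroidetes, 4
Parcubacteria, 2 Actinobacteria, 5 Nanohaloarchaea, 3 Cyanobacteria, 1
Thermoplasmatales, 1 Proteobacteria, 3 Saccharibacteria) and the marker
panel 198; 26 samples in three sites (9/8/9) at 25.5/44.1/54.2 km from the
coast with 3113/1560/891 wetness hours; 100 bp paired reads from 600–1000 bp
fragments.

Key rates: within-species mutation 0.005 (safely inside the 2% species
boundary), between-species divergence 0.25 from a per-taxon ancestor
(pairwise identity ~0.6, far below any grouping threshold), read error
0.005 substitutions/base, species-level SCG dropout 0.05, redundant-bin
scaffold dropout up to 0.30 with multiplicity uniform on {1,2,3}, rpS3
protein divergence 0.08 between species. Genomes default to 20–50 kb over
3–8 scaffolds — deliberately desk-scale while exercising multi-scaffold
logic; tests and the acceptance script use 8–18 kb genomes where a stage is
quadratic in pool size (marker recovery, the end-to-end pipeline run), a
package choice to keep the suite fast at unchanged logic.

Cassettes (SCGs, rpS3, CRISPR arrays) are protected from within-species
mutation so that exact-match cassette scanning and marker recovery are
noise-free; real data would add detection noise at every one of these steps.
Occupancy structure is reconstructed from the reference panel's integer
percentages by round-half-up per taxon, so realized sample-/site-specific
fractions match the panel within rounding; present cells draw
1 + lognormal(0.5, 0.8) fold coverage times exp(affinity · z), where z is
the site's standardized log wetness and affinity ~ N(0.8, 0.4) per organism
— the moisture-driven composition signal that MRPP/Mantel/BioENV detect.
Because all four bundled environmental covariates are monotone along the
transect, their rank-based BioENV correlations tie; the wetness variable
attains the maximum but is not its unique witness.

What passing tests do **not** show about real data: robustness to indels,
chimeric bins, strain microdiversity below 2%, assembly fragmentation,
GC/composition bias, or gene-calling errors — the generator models none of
these.

## Known limitations

* The mapper and aligner ignore indels entirely; both would need banded
  edit-distance extension for real reads.
* Profile scores are uncalibrated bits (no E-values); cutoffs are absolute.
* PERMANOVA is single-factor; MRPP uses one weighting scheme.
* The survey's own dataset-level statistics (e.g. its MRPP A and Mantel r)
  derive from ~150 Gbp of raw reads and are not reproducible at desk scale;
  the package reproduces the method contracts and the in-paper arithmetic,
  not those dataset values.
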