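# Methods

`edscape` implements a desk-scale, fully testable pipeline for studying the
cis-regulatory architecture of A-to-I RNA editing: quantify per-site editing
levels across a panel of inbred strains, map editing QTLs (edQTLs) with
permutation-calibrated linear models, predict the editing complementary
sequence (ECS) that forms each edited dsRNA duplex, and interpret edQTLs
through their effect on that duplex. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Editing-level quantification

The editing level at a site is the fraction of reads carrying G at a
sense-strand A (inosine is read as guanosine). Levels are reported only at
coverage >= 50 reads. Replicates whose levels differ by more than 0.20
(strictly greater; a difference of exactly 0.20 is retained) are dropped for
that strain and site; concordant replicates are combined by a
coverage-weighted mean, which is the maximum-likelihood estimate under
binomial read sampling. Sites measured in fewer than 35 strains are removed.
The replicate-discordance exclusion is applied per strain and site, not
site-globally.

Per-site variability is reported two ways: the plain sample variance across
strains, and the sample variance divided by `p(1-p)` at the site's mean
level `p` (undefined at p of 0 or 1). The binomial-scaled form discounts
the mean-variance coupling of proportions; both columns are emitted because
either is a defensible ranking metric and the choice does not affect any
downstream stage.

The intronic-site discovery cascade operates on annotated pileups: a
candidate A-to-G site is accepted only with >= 2 supporting reads after
discarding observations with base or mapping quality < 20 or with the
mismatch in the first six read bases, variant frequency >= 3%, no
homopolymer or simple-repeat context, distance to the nearest splice
junction above a configurable threshold (default 4 nt), no bidirectional
transcription, and zero altered reads in an ADAR-null pileup when one is
supplied. Every rejection carries a reason code so one-factor-at-a-time
audits are possible.

## edQTL mapping

Per site, levels across strains are centred/scaled implicitly by a
rank-based inverse-normal transform: values are ranked (ties share the
average rank) and mapped to `Phi^-1((rank - 0.5)/n)`. Genotypes of inbred
lines are haploid-coded 0/1; heterozygous or missing VCF calls become
missing, and a strain with a missing call is dropped for that variant only.

The scan fits simple linear regressions (no covariates) of normalized level
on genotype for every variant in the site's gene, requiring >= 8 complete
observations and the minor allele in >= 4 strains with a measurement. The
minimum nominal p over the site's variants is calibrated by permuting the
strain labels of the phenotype against the genotypes — 10,000 permutations
by default — over the same fixed variant set, giving

    p_empirical = (1 + #{null min-p <= observed min-p}) / (1 + n_perm)

(the add-one estimator never returns zero; ties count toward the null,
which is conservative). Permutation streams are seeded per site from the
global seed and the site id, so runs are reproducible and independent of
site order. FDR control uses Storey q-values with pi0 estimated at a single
lambda = 0.5, floored at 1/m; forcing pi0 = 1 reproduces
Benjamini–Hochberg exactly, and the test suite asserts this.

For each site with a primary edQTL (q below the chosen FDR), the normalized
levels are residualized on the primary genotype (residuals are exactly
orthogonal to it), the primary variant and its perfect proxies (r² = 1) are
excluded, and the scan and permutations are rerun to call secondary edQTLs.

Effect sizes are computed on the raw (non-normalized) levels as half the
absolute difference between the two homozygote class means, so a planted
additive effect is recovered exactly in the noise-free limit. Distances
from variant to site are signed in transcription orientation (downstream
positive). Genome-wide scans flag p < 1e-8 (Bonferroni-style threshold).

## RNA folding engine

ADAR requires a double-stranded substrate, so structural interpretation
rests on a secondary-structure folder. The engine is a pluggable contract:
every downstream operation accepts an externally computed structure (e.g.
parsed from dot-bracket), and the built-in default is a deterministic
minimum-free-energy folder for nested structures:

- Watson–Crick and G·U pairs; N never pairs; hairpin loops >= 3 nt;
  no pseudoknots; an optional mask forbids positions from pairing.
- Helices score the sum of nearest-neighbour stacking energies
  (Xia–Turner Watson–Crick values; stacks with one wobble pair are −1.3,
  with two −0.5 kcal/mol — a deliberate simplification).
- Hairpin closure costs +3.0 regardless of loop size; a bulge/internal loop
  of total unpaired size `s` (1 <= s <= 30, both strands summed) costs
  `1.5 + 0.5 s`; multibranch loops cost `3.0 + 0.4 (branches + 1)` with
  multiloop nucleotides free. The span cap of 30 nt per internal loop is
  part of the model definition.
- The empty structure scores 0, so the MFE is never positive. The dynamic
  program is exact for this model; the test suite verifies it against a
  top-down memoized recursion, full structure enumeration at tiny lengths,
  and an independent loop-decomposition scorer.

This model is intentionally simpler than a full Turner-2004 implementation
(no dangles, no special hairpin tables, no coaxial stacking, no partition
function). What the analyses need — stable recovery of long planted
helices, energy penalties for disrupted pairs, deterministic output — is
insensitive to those refinements; absolute energies are model-relative and
only within-model comparisons (allelic differences) are interpreted.

A *stem* is a run of consecutive base pairs in which every interruption —
the unpaired run on either strand between consecutive pairs — is at most
the max-bulge parameter (8 nt at the standard cutoffs); positions inside an
interruption must be genuinely unpaired, so a helix branching into a
multiloop terminates the stem. The bulge size of an asymmetric internal
loop is the larger strand's run. Stem extraction walks outward and inward
from the pair at (or innermost pair enclosing) the anchor; the result is
invariant to which stem-interior position anchors it.

Two-segment duplexes (edit side + ECS) are folded joined by a
100-adenosine linker whose positions are masked from pairing, so the linker
contributes no energy and cannot compete with the intermolecular helix.

## ECS prediction

**Approach 1 (proximal).** Fold the sense-strand window within 200 nt of
the editing site, extract the stem containing the site, and accept the
prediction when the stem has >= 20 pairs with max bulge <= 8 nt. The ECS
bounds are the first and last paired bases of the complementary strand.
Minus-strand sites are folded on the reverse complement and intervals are
mirrored back; predictions are strand-consistent by construction and by
test.

**Approach 2 (distal, intronic).** Smooth a per-base conservation track
with a centered 51-nt window (truncated at track ends), take maximal runs
with smoothed score >= 0.90, length >= 20, within 2,500 nt of the site
(optionally intron-restricted), and fold `[site ± 60] + 100 A linker +
[candidate ± 30]` with the linker masked. Only stems whose partner strand
lies in the candidate segment are accepted, under the same 20/8 cutoffs.
When several candidates yield accepted ECSs all are reported, longest stem
first. A candidate overlapping the site flank triggers a warned fallback to
the proximal approach.

**Enrichment score.** Because the ECS is itself one strand of an edited
duplex, true ECSs are enriched for editing sites. The score is the density
of known sites inside merged accepted ECS intervals divided by the density
in two adjacent flanks of the ECS's own length (a density ratio, so flank
truncation at contig ends renormalizes cleanly; with intact flanks it
equals sites-in-ECS over half the flank total). The anchoring site of each
prediction is excluded from the tallies by default — counting it would
inflate every score regardless of prediction quality — and the flag is
recorded in the output.

Substrate property profiles report site-to-partner distances, stem lengths,
edit-side max bulges, and the fraction of substrates paired at each
position within ±10 nt of the site.

## Structural interpretation of edQTLs

A variant is *within the duplex* when it falls in the predicted stem's
edit-side or ECS interval, *distal* otherwise; sites without an accepted
prediction are *unresolved* and excluded from structural analyses. For
within-duplex variants both alleles' duplex constructs are folded;
`delta_g = G(high) − G(low)` where the higher-editing allele is the
homozygote class with the higher mean raw level (ties break toward the
reference allele, with a warning). A negative delta-G means the
higher-editing allele forms the more stable duplex. Base-pairing status of
the variant is read from the higher-editing allele's structure. A
headline comparison set applies an effect-size gate of 0.025 (a 5%
homozygote difference); the ungated set is retained with a flag. Only SNVs
are compared (substitutions preserve coordinates in the construct).

Signed positions along the stem put the editing site at 0, edit-side
positions transcriptionally downstream positive, and give an ECS position
the sign of its paired edit-side base; bulge positions take the nearest
stem pair. Distances are counted in stem base pairs, not primary-sequence
nucleotides.

Control variants are non-edQTLs with r² <= 0.05 (inclusive, as printed)
against every edQTL; the duplex mode requires them inside predicted
duplexes, the distal-matched mode samples them (seeded) from the genes of
distal edQTLs outside the primary duplex. Group comparisons use a
two-sided Fisher exact test (hypergeometric enumeration) for base-pairing
and a one-sided Mann–Whitney U test (exact permutation enumeration up to
n = 10 per group, normal approximation with tie and continuity correction
beyond) for delta-G; both agree with independent enumeration oracles in the
test suite.

Secondary cis-elements: for distal edQTLs the ±200 nt neighbourhood of the
variant is folded and all maximal stems containing the variant that meet
the 20/8 cutoffs and do not overlap the primary duplex are reported with
their distance to the editing site.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the statistical structure of a targeted editing
survey of inbred fly strains: 131 strains in two replicates by default,
biallelic cis variants with haploid-coded genotypes, editing levels in
[0, 1] with planted additive effects (`level = clamp(baseline + 2·effect·g
+ N(0, sd))`, so the homozygote means differ by twice the effect and the
half-difference estimator is unbiased away from the clamp), Poisson total
counts around a mean coverage of 100 with binomial G counts per replicate,
and one locus per gene carrying a planted hairpin duplex. Genotypes draw
the minor-allele count uniformly from the integers compatible with the
configured MAF range and assign carriers by permutation, so the realized
frequency always honours the range. Baseline editing levels are uniform on
a configurable range (default 0.2–0.8); the real banding of editing levels
(most sites weakly edited) is not reproduced, and nothing downstream
depends on it.

Planted loci are built so the planted stem *is* the MFE structure and the
truth is unambiguous: arms are exact complements with specified bulges,
bulge nucleotides are chosen unable to pair with their opposite-strand
neighbours, bulges are placed so both helix segments keep >= 6 pairs (a
4–5-pair segment across a large bulge is not reliably a single helix under
any energy model, which would make the planted truth ill-defined), flanks
are rejection-sampled against any off-target 12-nt reverse-complement
match, and short non-pairing spacers (all-C tracts outside the arms, an
A/C-only loop) prevent chance flank pairs from accreting onto the stem
across a <= 8 nt bulge. Within-duplex variants are planted >= 2 pairs from
the stem ends because the terminal pair's fold boundary can shift by a
base. Distal loci place the ECS beyond the proximal window and paint a
conservation track at 1.0 over the ECS plus a 25 nt margin so the region
survives 51-nt smoothing at the 0.90 threshold.

Not simulated: sequencing error, PCR duplicates, alignment artifacts,
trans-acting effects, relatedness among strains, linkage between planted
variants, and realistic conservation-score noise structure. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under its stated model, not robustness to the artifacts of real
sequencing data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical assertions are
well-powered: null calibration at 200 sites × 100 strains × 1,000
permutations, power at 100 replicate simulations of 100-strain panels, 100
proximal and 50 distal recovery loci, 500 enrichment loci, 100 allelic
comparisons. The folding engine handles the 401-nt proximal window in
about 0.1 s (numba-compiled dynamic program; a pure-Python fallback keeps
the package functional without numba).

Coordinates are 0-based half-open internally and in BED; all other emitted
tables are 1-based. Every output table carries one header line with the
stage name, a hash of the analysis parameters (paths excluded) and the
seed; reruns with the same inputs, parameters and seed are byte-identical,
and the pipeline aborts with the failing stage's name on any error.
Degenerate inputs are skipped with warnings (zero-variance sites, empty
genotype classes) rather than silently imputed.
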