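# Methods

This note documents the models implemented in `rootqtl`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the design was
genuinely open.

## Coordinate conventions

All image-derived quantities use a frame with **rows/y increasing
downward**, so the downward vertical — the assumed gravity vector — is
`(0, +1)` for `(x, y)` traces and `(+1, 0)` for `(row, col)` skeletons.
Tip angles after rotation use 0° = horizontal to the right and positive
clockwise, so a tip bending down moves toward +90°; the deviation from the
vertical is `90° − angle`.  Plates are rotated blindly with respect to each
root's established angle, so post-rotation starting angles straddle 0°: a
root starting above 0° has been carried *through* the gravity vector, one
below 0° rotated *away*; an exact 0 is assigned to "through" (tie-break,
documented here and in the code).

## Root phenotypes

* **avgAbsAng** is the absolute angle between the junction→tip vector of a
  traced polyline and the downward vertical, in [0°, 180°].  It is
  invariant to uniform scaling and translation of the trace (property
  tested).  The signed variant is positive for rightward deviation; the
  handedness check is a two-sided exact binomial sign test on the signs of
  the nonzero angles.
* **Swing rate** is the first difference of the 34-point tip-angle series
  divided by the 3.75-min sampling interval (°/min, labels T1–T33).  Its
  time integral telescopes to the net angle change, which is how the
  worked tip-angle arithmetic (−4°→+32° ⇒ Δ36°, 58° from vertical;
  +10°→+22° ⇒ Δ12°, 68° from vertical) is computed.
* **Direction index** assigns each pixel-to-pixel step a weight (down 0,
  diagonal down 1, horizontal 2, diagonal up 3, up 4) and averages over
  the steps.  Dividing by steps (pixels − 1) rather than pixels sidesteps
  the undefined direction of the terminal pixel; the two conventions
  coincide on homogeneous paths, which cover the analytic anchors (0 and
  4).  Reversing a path without horizontal steps maps the index to
  4 − index (property tested).

## Angle QTL: the mixed model

`trait ~ genotype + collide + (1|germAge) + (1|plateDate)`, fit by REML
(statsmodels `MixedLM` with the two factors as crossed variance
components).  Genotype is treatment-coded against the recurrent parent, so
each coefficient is an IL's modeled shift in degrees.  The `collide` flag
(root touched another root) is a fixed nuisance; the `along` flag is
carried in the data but not modeled.  germAge and plateDate are treated as
crossed, i.i.d. normal intercepts per level — nothing in the design makes
one nested in the other.

p-values use a t reference with residual degrees of freedom
(n − fixed-effect rank), a containment-style approximation chosen for
stability and freedom from extra dependencies; simulation shows 95 % Wald
CIs cover a planted effect at close to nominal rate (the calibration suite
requires 90–99 % over 100 fits).  A random factor observed at a single
level is dropped with a warning; if the REML fit fails or returns
non-finite standard errors, the model falls back to OLS with the random
factors as fixed blocks (also warned) — with crossed, near-balanced
factors this changes the genotype contrasts very little.  BH adjustment
runs across the genotype contrasts; q ≤ 0.01 calls an angle QTL.

## Gravitropism QTL: per-timepoint tests and runs

At each timepoint the one-way fixed-effect model `trait ~ genotype` is
fit (implemented as the pooled-variance contrast of each genotype against
the reference, identical to the OLS treatment-coded coefficient; with two
genotypes it reduces to the two-sample t-test, F = t²).  BH adjustment is
applied over the whole genotype × timepoint family by default — the
conservative reading of a family that is ambiguous — and per-timepoint
families are available.  An IL is a gravitropism QTL when q ≤ 0.05 at ≥3
consecutive timepoints; runs are labelled by their midpoint against the
early (T0–T6), middle (T7–T19), late (T20–T33) windows and signed
faster/slower by the mean effect in the run.

## Read QC

Pipeline order (the source rules are listed without an order; the order
below fixes adapter search first, polyN on the raw read, masking before
splitting):

1. discard on any exact substring of length ≥ `adapter_min_match`
   (default 12) of an adapter or its reverse complement — the
   interpretation of "significant fragments";
2. discard on any N-run ≥ 15 (raw read, pre-masking; configurable);
3. mask Phred ≤ 20 to N; 4. trim terminal Ns;
5. cluster internal Ns whose neighbours are < 20 non-N bases apart, excise
   each cluster's span inclusive of both flanking Ns, split, keep the
   longest piece (5′ on ties);
6. discard below 30 bases or without 10 contiguous non-N bases at either
   end.

Filtering kept output is idempotent (property tested).  Demultiplexing
assigns a read whose barcode prefix matches exactly one library code under
the ≤1-substitution rule (N counts as a substitution); zero or multiple
matches go to `undetermined`, and assigned + undetermined counts conserve
the input.

## Genotyping

Chimeras are built per whole gene: a gene belongs to the donor segment
when its interval **midpoint** lies inside (genes straddling a boundary
are emitted from the midpoint side and flagged, since their counts are
suspect).  Read alignment is replaced by exact-substring unique
assignment — a read counts for a parent when it occurs in exactly one gene
of exactly one parent; both parents or several genes ⇒ ambiguous.  At gene
resolution on error-free synthetic reads this is equivalent to unique
mapping, and real per-gene allele counts can be supplied in the same
table schema.  A gene with ≥ `min_reads` (default 10) informative reads is
called donor at donor fraction ≥ 0.9 (the fraction cutoff is this
package's choice); consecutive donor calls merge, bridging single-gene
low-coverage gaps.  With ≥50 informative reads per gene, inferred
boundaries land within ±1 gene of truth in ≥95 % of simulated panels
(acceptance suite).

## Differential expression

* **TMM**: per-sample factor = precision-weighted mean of gene-wise
  M-values against a reference sample (the one whose 75th-percentile count
  fraction is closest to the mean), after rank-based two-sided trimming of
  30 % on M and 5 % on A; genes with a zero in either sample are excluded;
  factors are rescaled to geometric mean 1.  Factors are invariant to gene
  order, to global count scaling, and to pure depth changes (tested, plus
  a brute-force reimplementation of the trimmed weighted mean).
* **Pseudo-counts**: counts linearly rescaled to the geometric-mean
  effective library size.  This is a deliberate simplification of
  quantile-based depth equalization; all exactness claims are against this
  package's own formulas, verified by enumeration oracles, not by
  bit-compatibility with any other implementation.
* **Dispersions** under NB(μ, φ), var = μ + φμ²: the common φ maximizes
  the conditional log-likelihood of the replicate splits given per-gene
  group totals, summed over genes (continuous-count extension via log-Γ).
  Tagwise values squeeze each gene's own conditional-ML estimate toward
  the common value with weights df_res : prior_df (default prior 10);
  prior_df → ∞ recovers the common value exactly.  The squeeze matters:
  with 2–3 replicates the per-gene likelihood is noisy, and letting
  sharply underestimated dispersions through makes the exact test
  anti-conservative (the null-calibration suite holds empirical FDR at
  q ≤ 0.01 under 0.05).
* **Exact test**: conditional on the rounded total of the depth-equalized
  pseudo-counts, p sums the probabilities of all splits as or less likely
  than the observed one (probability-mass ordering; doubled-smaller-tail
  behind a flag).  Dispersion 0 reduces to the exact binomial split.
  log2FC uses group means offset by 0.125 per sample.  Enumeration
  agreement to 1e-10 for totals ≤ 30 and group-swap antisymmetry are
  tested.
* **cis/trans**: a q ≤ 0.01 gene is *cis* iff its midpoint lies inside the
  contrasted IL's donor intervals, *trans* otherwise.

## Bins, fine-mapping, and the consistency test

Bins are maximal constant-signature segments of the introgression union
(breakpoint scan + merge; verified against per-base scans).  A bin is a
trait candidate when covered by ≥1 significant IL and by no
non-significant IL.  "Significant ILs of a gene's bin" is read as the
trait-significant members of the bin's coverage signature — for maximal
bins the signature *is* the covering set.  A candidate gene must be DE
(q ≤ 0.01) in ≥2 of those ILs, with one sign of log2FC across all of
them, and mean normalized count ≥5; its direction is positive when
expression and trait move the same way vs the reference, and candidates
are ranked by signed squared Pearson correlation of per-genotype summed
normalized expression with per-genotype trait effects.

## The synthetic study and its defaults

The generators emulate the statistical structure the analysis assumes,
with every planted quantity recorded in a `SimTruth` ledger (recoverable
without re-simulation; all generators are bit-reproducible per seed).

| quantity | default | rationale |
|---|---|---|
| residual angle SD | 6° | within-genotype spread of traced 3–4-day seedling roots |
| germAge / plateDate SD | 2° each | modest batch structure relative to residual noise |
| collide shift | 4° | root contact perturbs but does not dominate the angle |
| seedlings per genotype | 35 (parents 70) | ~9 traceable roots × 4 replicate cycles; parents occupy twice the plates |
| NB dispersion | lognormal(ln 0.01, 0.3) | biological CV ≈ 10 %: homozygous inbred lines, each library pooling 7–14 root tips |
| baseline gene mean | lognormal(ln 60, 0.8) counts | per-gene coverage of a multiplexed 50 bp single-end library |
| planted causal cis effect | log2FC 1.5, +8° trait shift | a strong single-locus contribution to a multigenic trait |
| tip-angle response | a0 + A·(1 − e^(−r·max(0,t−lag))) | the simplest saturating form consistent with the sampled kinetics; no functional form is prescribed by the assay |
| reads | 50 bp single-end, Phred+33, barcode prefix | the study's sequencing format |

The default end-to-end scenario places 27 tiling introgressions (25 %
pairwise overlap) plus 3 nested left-anchored sub-ILs on two chromosomes
of 1000 genes each, and puts the causal gene in the overlap of the sub-IL
family's parent and its right-hand neighbour, beyond the sub-ILs' reach —
so both overlapping parents are true angle QTL while the sub-ILs are
non-significant excluders, reproducing the nested fine-mapping geometry.
The causal gene's baseline mean is pinned at 100 counts: a gene this
pipeline can *by construction* nominate must clear the mean-count floor
of the consistency test, so the planted target is a solidly expressed
transcript.  Background cis effects (±1 log2FC on 5 % of covered genes)
and two 20-gene trans hotspots keep the DE landscape non-trivial.

What the generators do **not** emulate: genomic sequence realism (no
splicing, no position- or sequence-dependent error models beyond the
planted contamination classes), GC or length biases in counts,
trait–expression correlation beyond the planted causal link, or
segregating heterozygosity.  Passing tests therefore demonstrate that the
inference chain recovers the structure it assumes, at the noise levels
above — not robustness to artefacts absent from the generator.

## Problem sizes used by the validation suites

Oracle-equivalence suites use exhaustive enumeration at small totals
(≤30), per-base scans on panels with coordinates ≤300, and 1000 random
p-vectors.  Calibration uses 40 independent two-genotype null rotation
panels (independence makes the binomial reference for the type-I rate
valid — contrasts within a shared-reference panel are correlated), 20
all-null DE families of 500 genes, and 100 mixed-model fits of 5 ILs ×
12 seedlings.  End-to-end recovery runs the full default scenario (30
ILs × 2000 genes × 3 replicates) over 50 seeds, with DE computed for the
trait-significant ILs — the only DE tables the consistency test consumes;
boundary recovery runs 100 panels of 60 genes at ~100 informative reads
per gene.

## Known limitations

* The mixed-model p-values are approximate (t with residual df); with few
  random-effect levels the variance components are weakly identified,
  though the genotype contrasts are robust to this in balanced designs.
* The exact test conditions on a rounded continuous total; for very low
  counts the rounding can shift p by one enumeration step.
* Exact-substring genotyping ignores sequencing errors by design; real
  data should enter as externally produced per-gene allele counts.
* Bins are gene-resolution objects here; real introgression boundaries
  are uncertain at sub-gene scale, which the boundary-gene flags only
  partially capture.
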