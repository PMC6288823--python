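# rootqtl

QTL and eQTL mapping of **root growth angle** and **root gravitropism** in
an introgression-line (IL) population, built for studies that contrast a
cultivated recurrent parent (e.g. tomato cv. M82) with a wild donor
(e.g. *Solanum pennellii*) through a panel of lines each carrying a single
donor chromosomal segment.

A root's final angle is the long-term outcome of many growth decisions; its
response to a 90° reorientation is a short-term reflex.  `rootqtl`
implements the full inference chain needed to ask whether the two are
controlled by the same loci, and to walk from a trait QTL to a candidate
gene:

* **Phenotypes** (`root_traits`) — average absolute angle (avgAbsAng): the
  absolute angle between the junction→tip vector of a traced root and the
  downward vertical; signed handedness variant with an exact sign test;
  tip-angle time series after a 90° rotation (34 frames, 3.75 min apart),
  swing rates (first differences, °/min), through/away rotation classes;
  BRAT-style direction index of a pixel skeleton (down = 0 … up = 4) and
  root angle vs the vertical.
* **Angle QTL** (`trait_qtl`) — mixed model
  `trait ~ genotype + collide + (1|germAge) + (1|plateDate)` fit by REML;
  per-IL contrasts vs the recurrent parent with Benjamini–Hochberg FDR
  (q ≤ 0.01).  Gravitropism QTL: `trait ~ genotype` at every timepoint, BH
  over the genotype × timepoint family (q ≤ 0.05), and an IL is called when
  it differs at ≥3 consecutive timepoints (runs labelled early T0–T6,
  middle T7–T19, late T20–T33).  Trait-overlap partition and per-timepoint
  expression–trait R².
* **Read QC** (`read_qc`) — the study's custom FASTQ rules: adapter-fragment
  discard, polyN ≥ 15 discard, masking of Phred ≤ 20 bases to N, end
  trimming, excision/splitting of N pairs closer than 20 bases (longest
  piece kept), discard below 30 bases or without 10 clean bases at either
  end; demultiplexing by exact or single-change (including to-N) barcode
  match.
* **Genotyping** (`genotyping`) — per-gene chimeric references (donor
  sequence inside the introgression, recurrent elsewhere, boundary genes
  flagged), allele assignment of reads by unique exact match, introgression
  inference from per-gene donor fractions, concordance with expected
  intervals.
* **eQTL / DE** (`eqtl_de`) — TMM normalization (30 % M-trim, 5 % A-trim,
  precision-weighted), conditional-likelihood common and tagwise NB
  dispersions, the exact conditional NB test (probability-mass two-sided
  rule; dispersion 0 reduces to the exact binomial split), BH at q ≤ 0.01,
  and cis/trans classification: a significant gene whose midpoint lies in
  the IL's introgression is a *cis*-eQTL, elsewhere a *trans*-eQTL.
* **Bin fine-mapping** (`bin_mapping`) — bins: maximal segments with a
  constant signature of covering ILs; candidate bins are covered by ≥1
  trait-significant IL and no non-significant IL (nested sub-ILs thereby
  narrow an interval); the trait-consistency test keeps genes DE in ≥2
  significant covering ILs with one direction of change and mean
  normalized count ≥5, ranked by expression–trait R².
* **Synthetic data** (`synthetic_data`) — generators for every input above
  with a recorded truth ledger: two-parent transcriptomes with planted
  SNPs, tiling IL panels with nested sub-ILs, NB counts with planted
  cis/trans effects, seedling angle records with crossed random effects,
  saturating tip-angle responses, contaminated barcoded FASTQ whose
  filtering fate is known at construction, and the randomized 7-holder ×
  12-pair-slot plate layout.

## Worked example

`examples/06_eqtl_fine_mapping.py` runs the whole chain on the default
synthetic study — 30 ILs (27 tiling + 3 nested sub-ILs), 2000 genes, 3
RNA-seq replicates, one causal cis gene (log2FC = 1.5) driving a +8°
avgAbsAng shift:

```
trait-significant ILs (q ≤ 0.01): ['IL1-8', 'IL1-9']
bins: 55 total, 3 candidate after exclusion

candidate genes from the consistency test (DE in ≥2 significant covering ILs, consistent direction, mean ≥5):
  g010569 in bin d-1S: 2 ILs, positive association, expression–trait R² = 0.97 ← planted causal gene
  g010574 in bin d-1S: 2 ILs, positive association, expression–trait R² = 0.99

causal bin called candidate: True
causal gene recovered:        True
```

The two ILs whose introgressions contain the planted causal gene are the
only angle QTL; exclusion by the non-significant ILs (including the nested
sub-ILs) narrows 55 bins to 3 candidates; and the consistency test reduces
2000 genes to two candidates in the causal bin — the planted gene plus one
linked background cis effect — each strongly correlated with the trait
across genotypes.  The other examples demonstrate single capabilities
(phenotypes, rotation kinetics, the angle mixed model, read QC,
genotyping) in the same build–run–print style.

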