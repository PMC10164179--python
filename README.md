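# methylhic

Integration of a bacterial N6-methyladenine (6mA) methylome with genome
annotation, expression data and chromosome conformation, exercised end to
end on synthetic data with known ground truth.

Lactic-acid bacteria such as *Lacticaseibacillus paracasei* carry
strain-specific 6mA methyltransferases whose target motifs are short
degenerate sequences (e.g. the dyad `GCCAT/ATGGC`). Whether and where those
motifs are methylated correlates with coding-sequence usage, the expression
of carbohydrate-metabolism genes, and the spatial organisation of the
chromosome. This package implements the statistical machinery needed to ask
those questions of a methylome:

- **Degenerate motif scanning** over IUPAC alphabets, reporting every
  overlapping occurrence on both strands, with dyad motifs counted once.
- **Markov usage bias.** For a motif *m* and region class *c* (CDS or
  intergenic), the expected count E<sub>c</sub>(m) under an order-*k* Markov
  model of class composition is computed exactly by a positional dynamic
  program (never by expanding the motif). The bias score is
  `b = log2(O_ig/E_ig) − log2(O_cds/E_cds)`; `b < 0` means skew toward CDS.
- **CDS/intergenic site classification and densities** (sites per kb), per
  gene and per functional category (COG letter / KO id), with groups ranked
  by median per-gene density.
- **Differential filters and enrichment.** FDR ≤ 0.05 with 2-fold change
  for transcripts, raw p < 0.05 with 1.2-fold change for proteins; per-
  category two-sided Fisher exact tests with Benjamini–Hochberg correction;
  2^−ΔΔCT and Pearson r for qPCR-style validation.
- **TFBS scanning.** PWMs built from binding-site sets; 50–300 bp upstream
  regions; log2-odds scores with *exact* p-values from a quantized
  score-distribution DP; q ≤ 0.05 filtering; methylation-overlap labelling.
- **Comparative Hi-C** on a circular chromosome: ICE balancing,
  distance-stratified binomial interaction calling (kept iff p < 0.01,
  q < 0.01 and count > 2), insulation-score profiles, chromosomal
  interaction domain (CID) detection at insulation minima, and the
  differential procedures — unique interactions, unique CIDs (reciprocal
  overlap ≥ 0.8), unique insulation regions (sliding windows merged when
  the between-condition Pearson r exceeds 0.6), genes per region class.

Because the original sequencing data are not needed to test any of this
logic, the package ships a first-class synthetic generator
(`methylhic.synthgen`) producing a 200 kb circular chromosome with planted
motif occurrences methylated at class-specific rates, DE tables with one
category at elevated odds, and Poisson contact-map pairs with power-law
decay, planted domains and planted differential contacts — all recorded in
a truth table.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on one
simulated data set (`python analysis/01_simulate.py` … `05_hic.py`).
Representative output:

```
529 genome-wide motif occurrences (planted + background), 195 methylated (36.86%)
densities: 1.011 per kb in CDS vs 0.874 per kb intergenic
planted motif usage bias b = -0.1413 (skew toward CDS); unplanted motifs stay near b = 0

140 differentially expressed genes (112 up, 28 down) of 2000
most enriched category: [G] k/K = 52/213, odds ratio 6.236, p = 2.58e-18, q = 4.39e-17
fold-change cross-validation on 11 genes: Pearson R = 0.992

16 hits kept at q <= 0.05 across 68880 scanned offsets; planted sites recovered in 8/8 genes
16/16 kept hits are associated with non-methylated sites

ref: 0 significant interactions, 4 CIDs (boundaries at [0, 100, 200, 300])
test: 8 significant interactions, 5 CIDs (boundaries at [0, 100, 110, 200, 300])
unique to test: 8 interactions (8/8 planted recovered), 1 CIDs, 1 insulation regions
planted test-only boundary at bin 110 covered by unique insulation regions: True
```

Reading: the generator planted `GCCAT/ATGGC` at 0.96/0.77 occurrences per
kb (CDS/intergenic, 99% called methylated), and the measured densities and
negative bias recover that skew; the COG category planted at 8× odds among
DE genes is the top enrichment hit; every planted TFBS consensus and every
planted 20× differential contact is recovered; and the extra insulation
boundary planted only in the test condition appears as a fifth CID and is
covered by the unique insulation regions.

There is also a CLI (`methylhic simulate|map-features|motif-bias|enrich|
tfbs-scan|hic-compare`) wrapping the same library calls for file-based use.

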