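# Methods

This note records the models and procedures the package implements, the
default parameters and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that matter when
reproducing its output.

## Coordinates and formats

All coordinates are 0-based half-open internally. GFF3 and the simplified
PacBio-style `modifications.gff` dialect (1-based inclusive) are converted
at the file boundary only; writing and re-reading restores the original
values. Parsing is strict — a malformed line raises rather than being
skipped — because every input in this project is generated and silent loss
would mask generator bugs. The `motifs.csv` dialect is a five-column subset
(`motifString,centerPos,fraction,nDetected,nGenome`) of the PacBio motif
summary; extra columns are ignored.

## Motif model

A methylation motif is a degenerate IUPAC word, optionally with its
reverse partner written `forward/reverse` (the partner must equal the
IUPAC reverse complement). The scanner reports every overlapping match of
the forward word (strand `+`) and of its reverse complement (strand `−`);
a motif equal to its own reverse complement is scanned once so that each
dyad contributes one occurrence, matching the one-count-per-motif
convention of methylome summary tables. The percent-methylated summary is
plain arithmetic, `100·n_methylated/n_total`, reported to two decimals.

## Markov usage bias

Class-specific Markov models (default order 2, configurable 0–5,
pseudocount 1) are trained on the concatenated CDS fragments and the
concatenated intergenic fragments respectively; each class is evaluated
under its own model, so the expectation controls for class composition.
Order 2 captures codon-adjacent structure while remaining well estimated
on tens of kilobases; the order is exposed because no single value is
canonical. The expected count of a motif in a set of fragments is
`Σ_f (L_f − k + 1) · P_model(motif)`, with `P_model` computed by a dynamic
program over m-mer states — cost O(k·4^m), independent of the motif's
expansion size, so runs of N are free. Observed counts use the same
fragment decomposition (matches cannot span fragment boundaries), keeping
O and E commensurable. The bias is
`b = log2(O_ig/E_ig) − log2(O_cds/E_cds)`, the simplest monotone statistic
separating the two classes; it differs from the perpendicular distance to
the observed-vs-expected diagonal by a factor of 1/√2, which matters only
when comparing absolute values across studies. A zero observed count is
replaced by 0.5 and flagged.

## Enrichment statistics

Differential tables are filtered by the transcript rule (padj ≤ 0.05 and
|log2FC| ≥ log2(2)) or the protein rule (raw p < 0.05 and 1.2-fold);
both conventions are kept because they are standard for the two assay
types. Category enrichment uses the two-sided Fisher exact test
(probability-mass rule) per category on the 2×2 table
(k, n−k, K−k, N−K−n+k), Benjamini–Hochberg correction across the
categories of one analysis, and reports both raw p (significance flag at
p < 0.05) and q. The odds ratio reported is the sample cross-product
ratio. 2^−ΔΔCT and the sample Pearson correlation are provided for
qPCR-style validation.

## TFBS scanning

PWMs are built from equal-length site sets with
`(count + pseudocount·background) / (n + pseudocount)` per column. Scores
are log2 odds against an order-0 background (default: estimated from the
scanned regions; uniform in tests). P-values are exact under the
background: per-column scores are quantized to 1/1000 bit and the null
score distribution is obtained by convolution over columns, so every
offset's p-value is a tail of that distribution; hits carry the tail at
their quantized window score, which keeps the reported p exactly on the
distribution's support. Q-values are Benjamini–Hochberg across all scanned
offsets of an analysis (an approximation of FIMO-style q-values), filtered
at q ≤ 0.05. Upstream regions are the up-to-300 bp gap 5′ of each gene,
truncated at the nearest annotated feature and dropped below 50 bp; minus-
strand regions are reverse-complemented. A hit is "methylated" iff a call
position lies inside its half-open interval; the strictest reading of
site/methylation association, with proximity windows left to the caller.

## Comparative Hi-C

Matrices are dense symmetric arrays on a circular chromosome (400 bins by
default). ICE balancing divides rows/columns by their coverage until the
coefficient of variation of row sums is < 1e−5 (≤ 200 iterations);
all-zero bins are masked and carry NaN bias. Interaction calling is a
simplified Fit-Hi-C: the expected probability of a pair is the mean
balanced contact at its circular distance, normalized over tested pairs,
and the p-value is the upper binomial tail of the observed raw count out
of the total tested count; q is BH over all tested pairs; calls require
p < 0.01, q < 0.01 and raw count > 2. Pairs closer than 20 bins
(`min_distance`) are not tested: in that regime contact frequency is
dominated by domain-scale structure rather than discrete looping, the
flat per-distance expectation is misspecified there, and standard callers
likewise exclude or spline-refine short-range contacts.

The insulation score of bin *i* is the mean balanced contact in the w×w
square linking the w bins 5′ of *i* to the w bins starting at *i*
(default w = 10; at 500 bp–1 kb bins this probes the tens-of-kb CID
scale); profiles are normalized as `n(i) = log2(s(i)/mean s)`. CID
boundaries are local minima of n whose strength — the left and right
`delta_span`-bin means above the minimum, summed (defaults 10 bins,
0.3) — clears the threshold; CIDs are the arcs between consecutive
boundaries and always tile the circle. Unique CIDs use reciprocal arc
overlap ≥ 0.8, a standard domain-matching rule the source procedure does
not specify. Unique insulation regions slide a `window_bins` window
(default 40, step 1, circular) over both normalized profiles, mark
windows with Pearson r > 0.6 concordant (a numerically flat window pair
is concordant iff both are flat), remove every bin covered by a
concordant window, and return maximal runs of the remainder. The window
default of 40 bins reflects a statistical constraint measured during
design: insulation noise is autocorrelated over ~w bins, so short windows
have too few effective degrees of freedom for the correlation test to be
stable. Genes are assigned to regions by ≥ 1 bp overlap and deduplicated
per region class.

## The synthetic generator

`SynthConfig` defaults are the desk-scale study conditions and are not
tuned per run:

- **Genome**: one circular 200 kb chromosome, order-0 composition at 46%
  GC (typical for the organism); order 1–5 Markov composition available.
- **Annotation**: 120 non-overlapping CDS of 600–1400 bp with alternating
  strands and multinomial-random gaps (~60% coding), each tagged with a
  COG letter from a 17-letter palette (optionally weighted) and a
  synthetic KO id.
- **Methylation**: the dyad motif `GCCAT/ATGGC` (the most abundant motif
  of the source methylome table) planted at 0.96/0.77 occurrences per kb
  in CDS/intergenic, each occurrence concretized, written on a random
  strand and called methylated with probability 0.99 — so the methylated-
  site densities land near 0.95 vs 0.76 per kb, the headline CDS/
  intergenic contrast. Placement is Poisson with re-draw on collision
  (hard-core bias negligible at these densities).
- **Hi-C**: 400-bin Poisson pair with μ(i,j) = C·d^−α (C = 100, α = 1,
  circular distance, d capped at 1 on the diagonal); four tiling CID
  blocks at 2× self-association (bacterial CID contrasts are modest);
  eight differential contacts at 20× in the test matrix; one test-only
  boundary at bin 110 — the flank of the shared junction at 100 —
  implemented as 0.3× depletion of contacts straddling the boundary
  within 15 bins. A depletion (rather than a boosted block) perturbs
  insulation without generating spurious significant interactions, and
  placing it beside shared structure is what makes the window-correlation
  comparison statistically stable; it also mirrors how domain splits
  appear at existing boundary flanks. Unchanged pairs share the reference
  draw, so conditions differ only where differences are planted. An
  optional shared short-range "texture" field (off by default) adds
  locus-specific compaction for experiments needing structure along the
  whole circle.
- **Differential expression**: each gene flagged DE with baseline
  probability 0.05, odds multiplied by 8 in category G; p/padj/log2FC are
  back-filled so that |log2FC| ≥ 1 and padj ≤ 0.05 iff flagged. Count-model
  internals (dispersion estimation etc.) are out of scope; only threshold
  filtering and enrichment are tested. DE-scale runs use a 3 Mb/2000-gene
  annotation with category G at a 10% share (size ~200).

What the generator does **not** emulate: sequencing noise and kinetics
(calls are exact positions with a global miss rate), background motif
occurrences are unmethylated (so whole-genome percent-methylated is far
below the per-planted-instance 99%), contact maps lack coverage bias,
loops and replication gradients, and DE p-values are not derived from a
count model. Passing tests therefore demonstrate the correctness and
statistical calibration of the analysis machinery under known truth, not
robustness to every artefact of real data.

## Benchmark sizes and determinism

The recovery benchmarks run 100 seeds (400 for the type-I calibration) at
200 kb / 400 bins; all randomness derives from one base seed through
`numpy.random.SeedSequence`, and generator streams are keyed by stable
CRC-32 names, so results are identical across processes and platforms.
Measured with the defaults (base seed 1): CDS/intergenic densities
0.967/0.741 per kb, bias sign recovered in 100/100 seeds at 2:1 planted
rates, CID boundaries exact in all seeds, 100% of differential contacts
recovered with 0.17 stray unique pairs per seed, planted-boundary
coverage 100/100, enrichment power 100/100 at odds 8 and type-I rate
0.0525 at odds 1 — all recomputed by `scripts/acceptance.py`.

## Known limitations

- The bias statistic's absolute scale depends on the Markov order and on
  the fragment decomposition; comparisons across annotation versions need
  identical settings.
- BH across scan offsets is cruder than FIMO's density-based q-values;
  with few scanned regions it is conservative.
- The interaction caller has no spline refinement; with strong domain
  structure inside the tested distance range, within-domain pairs can
  reach significance in both conditions (they cancel in the differential
  sets but inflate per-condition call counts).
- The window-correlation insulation comparison is unreliable where both
  profiles are featureless; this is inherent to the procedure, not to the
  implementation (see the window-length discussion above).
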