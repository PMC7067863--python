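# Methods

## Model and procedure

The caller treats a MeRIP experiment as paired count/coverage tracks: an IP
library enriched for fragments carrying m⁶A and an Input library measuring
the underlying transcript abundance. Enrichment is local — a methylated
site raises IP coverage over a ~100–200-bp footprint while Input coverage
follows expression — so detection is windowed: 100-bp windows stepping by
50 bp across each protein-coding gene's genomic span (a gene shorter than
100 bp gets a single window covering it; the grid is anchored at the
gene's 5′-most genomic coordinate and no partial terminal window is
emitted). Counting is unstranded with union/nonunique-all semantics: a
read contributes to every window it overlaps. When inputs are per-base
coverage (bedGraph) rather than alignments, the window count is
reconstructed as total depth over the window divided by the read length
(default 65 bp, single-end).

Four detectors run per IP/Input pair on the windows exceeding 10 IP reads
(strict inequality), each with the thresholds listed in
`meripseq.defaults.DEFAULTS`:

* **Fisher**: one-sided hypergeometric tail of the window-vs-rest-of-library
  2×2 table. The table construction (window against the remainder of each
  library, one-sided enrichment) is the standard RIP-seq choice; a
  two-sided variant is not exposed because the decision rule is one-sided
  by design. BH correction runs over all tested windows of the sample
  (family = post-coverage-filter windows).
* **RPMF**: RPM(IP) − RPM(Input), a *difference* of reads-per-million.
  Though often called a fold, the statistic is defined by subtraction; a
  ratio mode is available (`rpmf_mode="ratio"`). Being an absolute RPM
  difference, its operating point depends on library size: at the tens of
  millions of mapped reads of a real experiment the >10 cut-off is
  many standard errors from the null, while on a desk-scale simulated
  transcriptome (libraries of ~10⁵ reads) RPM units inflate ~100-fold and
  the technique becomes permissive. The consensus rule (≥3 of 4
  techniques) absorbs this: a noisy technique can only upgrade regions
  that two calibrated techniques already support.
* **POM/POI**: medians of *non-zero* per-base depth (null positions
  removed before any median). Windows on genes with no non-zero exonic IP
  coverage are unevaluable and skipped with a warning. A zero/undefined
  Input POM yields POI = +∞: the window passes but is flagged
  `input_empty` so downstream users can audit it.
* **Local Poisson**: λ is the larger of the genome-wide expected IP rate
  for the window (IP library × window length / grid footprint) and the
  Input count rescaled to the IP library — the core of MACS2's
  local-lambda idea, with BH-adjusted upper-tail p-values. This stage is
  a self-contained windowed formulation, and an adapter maps externally
  computed MACS2 narrowPeak files onto the grid for users who want the
  original tool's output (any overlapping window passes).

Consensus: per technique, windows passing in ≥3 distinct IP samples are
kept (occurrence is evaluated on original window identities, before
merging), merged with bedtools-merge semantics (overlapping or book-ended
intervals coalesce — this also makes the merge exactly equivalent to a
per-base union), and re-centred to the 150-bp interval around the
*leftmost* maximum of the per-base median coverage across all IP samples
(leftmost on ties keeps results deterministic; all-zero regions fall back
to the region centre with a warning). Genomic positions covered by ≥3
techniques' sites are merged and the maximum of the median coverage is
searched again on the combined region (rather than reusing per-technique
maxima — recomputing is the only choice that makes the final peak a
function of the combined evidence). Peaks may extend past gene bounds
after re-centring and are clipped only at chromosome edges (then flagged
`clipped`).

Annotation: host gene = largest overlap; region label by precedence
5′UTR > 3′UTR > CDS > intron over overlapped bases; motif score = weighted
count (overlaps allowed) of GAACA/GGACA/GAACT/GGACT on the sense strand
(the four variants share the shape G[AG]AC[AT]; a boolean presence flag
for that degenerate pattern is emitted alongside the integer score);
metagene coordinate maps the peak midpoint onto the spliced transcript and
scales piecewise 5′UTR→[0,1), CDS→[1,2), 3′UTR→[2,3), strand-aware, with
intronic midpoints snapped to the nearest exonic base and CDS-less genes
excluded.

## Differential analysis

Counts (peak × IP samples; gene × Input samples) pass two inclusion
filters: ≥5 CPM in ≥3 samples, and — for peaks — ≥5 CPM in ≥2 samples of
each role within every (condition, IP procedure) cell. TMM normalization
follows the standard construction: reference library by upper quartile
closest to the mean upper quartile, 30%/5% double trim on M/A values,
precision-weighted mean of M, factors rescaled to geometric mean 1. The
log₂-CPM transform uses the 0.5/1.0 offsets, an unweighted first-pass fit,
a lowess trend (span 0.5) of √sd against average log-count, and weights
sd⁻⁴ at each fitted log-count; below 16 features the trend is not
estimable and unit weights are used with a warning. Feature-wise weighted
least squares on `~ condition + batch factors` (treatment coding,
reference level CONV when present; single-level factors are dropped; a
rank-deficient design raises an error naming the aliased columns) is
followed by empirical-Bayes moderation with the method-of-moments fit on
log residual variances (prior df via a Newton trigamma inverse;
`prior_df=0` recovers classical t-tests exactly, `prior_df=inf` pools all
variances). Significance: BH-adjusted p < 0.05 **and** |log₂FC| > 1, both
strict, exactly as printed. Batch-corrected log-CPM (fitted batch-term
contributions subtracted, condition effects retained) is provided for
ordination/heat maps only, never for inference.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes:

* genes with 5′UTR/CDS/3′UTR structure and 1–3 exons laid on one random
  chromosome, alternating strands;
* gene expression log-normal (σ = 0.7 on the log₂ scale) with
  negative-binomial sampling noise (dispersion 0.05 at the coverage level,
  0.1 in the count-level simulator — values typical of biological
  replicates);
* Input reads uniform over a gene's spliced exons; IP reads add an extra
  read stratum confined to each spiked site with weight (γ−1)·site/exonic
  length, so mean in-site IP:Input depth ratio ≈ γ (default fold γ = 8,
  site width 150 bp, sites fully inside single exons);
* two conditions × three IP/Input pairs (six pairs) at ~30× mean exonic
  coverage from 65-bp single-end reads, 100 genes, 50 spiked sites, 10
  differentially methylated (log₂ enrichment difference 2) and 10
  differentially expressed genes (log₂FC 2);
* sequencing batch, library batch and IP procedure as gene-specific
  multiplicative (log-additive) effects with σ = 0.25 log₂ units,
  assigned cyclically so the design stays full rank. With three pairs per
  condition a two-level IP-procedure factor cannot satisfy the
  per-procedure CPM rule (which needs ≥2 samples per cell) nor remain
  estimable, so the coverage-level default uses one procedure; the factor
  is exercised in the count-level simulator, which uses six samples per
  condition. GGACT motifs (3 per site) are implanted inside spiked sites;
  at density 0 chance motif occurrences inside sites are scrubbed so the
  zero-signal contract holds exactly.

Two count-level simulators support calibration and power studies: null
window counts drawn from one multinomial for IP and Input at realistic
library sizes (2×10⁷), and a negative-binomial peak-count matrix
(2000 features, 20 true effects at |log₂FC| = 2 with alternating sign,
n = 6 per condition, batch effects matching the model).

All randomness flows from `numpy.random.default_rng(seed)`; integer
streams only, so outputs are bit-for-bit reproducible.

### What passing tests do and do not show

The generator produces step-function enrichment on clean exon geometry,
no sequencing errors, no fragment-length structure, no multimapping, no
isoform complexity, and conditions differing only where configured. The
caller's perfect sensitivity/precision here demonstrates correctness of
the mechanics (grid, tests, thresholds, merge/recentre, consensus) under
the model's own assumptions — not expected performance on real tissue
data, where antibody efficiency, coverage ruggedness and transcript
structure will lower both. A triangular enrichment shape option exists to
exercise re-centring with off-centre maxima. Peak counts of the original
study (tens of thousands from deposited sequencing runs) are not
reproducible at these problem sizes and are not targeted.

## Numerical choices

* Medians via `numpy.median` (mid-mean on even length); thresholds applied
  with the printed strictness (>10 reads, adjusted p < 0.001, POM < 4
  removed, POI > 2, RPMF > 10, p_adj < 0.05, |logFC| > 1).
* Ties in max-coverage search: leftmost position.
* BH families: all windows tested in a sample (detectors); all features of
  a contrast (differential stage). NaN p-values are excluded from the
  family and propagated.
* Fisher p-values via the hypergeometric survival function (validated to
  10⁻¹⁰ against exact rational enumeration); Poisson tails via the
  survival function (validated against direct series summation).
* Trigamma inverse by Newton iteration (50 iterations max, 10⁻⁸ relative
  step tolerance).
* Problem sizes in tests and the acceptance script (100 genes, 2.5k null
  windows, 2000-feature count matrices, 20 replicates) were chosen as the
  smallest sizes at which the binomial/NB sampling bands in the checks are
  meaningful.

## Known limitations

* No isoform-resolved counting; windows tile the genomic span and only
  the POM gene median is exon-restricted.
* The narrowPeak adapter maps regions to windows by overlap; it does not
  reproduce MACS2 summit refinement or duplicate handling.
* The per-procedure CPM rule constrains only roles present in the matrix
  (peak matrices carry IP columns; Input support is checked when Input
  columns are provided).
* `remove_batch_effects` output is for visualization; re-fitting on
  corrected values would double-count the batch terms.
* BAM coverage reading loads whole-chromosome depth arrays; fine for
  targeted/simulated genomes, memory-hungry for full mammalian ones.
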