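# Methods

drnakit analyses read-level poly(A)-tail measurements and isoform-level
count matrices from Nanopore direct RNA sequencing of whole blood, in a
two-condition design (six patients with bacterial and six with viral
sepsis, each sample its own library batch by default). This note records
the statistical models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer should know about.

## Read-level data model

A read record carries its sample, batch, condition, gene assignment, read
length and poly(A)-tail estimate in nucleotides. Tail estimates come from
the basecaller as an integer auxiliary BAM tag (default name `pt`) or
from the three-column extraction table (read id, read length, tail).
Estimates below 1 nt are stored as missing: the downstream response is a
log tail length, and a sub-1-nt value means "not estimated" rather than a
measurable tail. Only primary alignments contribute. Gene assignment is
either the alignment reference name (transcriptome alignment) or a
caller-supplied reference-to-gene map; both are exposed because read-level
tail summaries are insensitive to which of the two a study used.

Annotation is parsed from GTF/GFF3 (1-based inclusive coordinates,
converted internally to 0-based half-open). A gene's length is the length
of the union of its exon intervals; GC content, when a genome FASTA is
given, is counted over the same union. Strand is ignored — exon unions and
base composition are strand-symmetric for these purposes. Mitochondrial
genes are recognised by chromosome name (`MT`, `chrM`, `chrMT`,
case-insensitive).

## Poly(A) profiles

Per gene we report the median tail (the ranking score), per-condition
medians, and the mean log2 tail. The median rather than the mean is used
for ranking because tail distributions are right-skewed and the median is
what a ranked enrichment analysis of "long-tail vs short-tail genes"
should order by. Compartment summaries (mitochondrial vs nuclear) report
n, median, the fractions of tails above 70 and 350 nt, and a mode
estimated from a 1-nt histogram smoothed with a +/-2 nt moving average —
deterministic and cheap, and at the read depths involved (10^5-10^6 reads)
at least as stable as a kernel density estimate. Ties in the smoothed
histogram resolve to the smallest bin; ranking ties resolve by gene id, so
all orderings are reproducible.

## Differential polyadenylation

Per gene, every usable read contributes one observation to

    log2(tail) = b0 + b1 * 1[viral] + u_batch + e,
    u_batch ~ N(0, sigma_b^2),  e ~ N(0, sigma^2).

The base-2 log makes `b1` directly the log2 fold change that the calling
cutoff (|log2FC| >= 0.5, BH-adjusted p < 0.05) refers to; positive `b1`
means longer tails under viral infection. The model is fitted by REML,
profiled over the variance ratio lambda = sigma_b^2/sigma^2: for a single
random intercept the profiled criterion needs only per-batch sufficient
statistics, so each evaluation is O(#batches) and a bounded scalar search
on log lambda converges in a few dozen evaluations. The reported p-value
is a two-sided t test of `b1` with Satterthwaite denominator degrees of
freedom, computed as 2 f^2 / (g' C g) where f is the sampling variance of
`b1`, g its gradient in (sigma^2, sigma_b^2) (central differences) and C
the inverse observed REML information (numerical Hessian). On shared
datasets the fit agrees with R's `lmerTest` to about six significant
digits in the estimate and standard error and three in the degrees of
freedom, and one test keeps that cross-check alive.

With a single batch, or when the lambda estimate hits the zero boundary,
the fit is ordinary least squares, which for a binary design is exactly
the pooled two-sample t-test (asserted to 1e-10 against an independent
implementation). A likelihood-ratio variant was considered and dropped:
the Satterthwaite t is what the reference mixed-model tooling reports and
the two differ only in finite-sample corrections the t handles better
here.

Eligibility requires at least `min_reads = 10` usable reads per condition
(no such rule is inherent to the model; 10 keeps the within-gene variance
estimable without discarding most genes at blood-typical depth). BH
adjustment runs across all fitted genes.

### Bootstrap robustness

Each called gene is refitted `n_boot = 100` times on reads resampled with
replacement. Resampling is stratified within each (gene, sample) stratum
by default, preserving the 6+6 design and per-sample depths; a pooled
mode is available. Within every replicate the candidate set is re-adjusted
by BH and a success is an adjusted p below alpha; `robust_fraction` is
the success rate and `is_robust` applies a 0.95 threshold (exposed as a
flag — the procedure itself only defines the comparison per replicate).
Replicates in which resampling empties a condition count as failures
rather than being dropped, which makes the fraction conservative for
small strata.

## Pre-ranked enrichment

Genes are ranked by median tail, longest first, and scored against gene
sets with the weighted Kolmogorov-Smirnov running sum (weight exponent 1;
exponent 0 gives the unweighted statistic). Hits increment by
|score|^w / sum of hit weights, misses decrement by 1/(N - N_hits); the
enrichment score is the signed maximal deviation, with an exact tie
between extremes resolved to the positive one. The null is gene-label
permutation — equivalent to placing the set at random positions — which is
the correct null for a per-gene scalar ranking. Permutation scores are
computed from sorted hit positions only (the running sum is piecewise
linear, so its extremes sit immediately after or before hits), which makes
thousands of permutations per set a vectorised O(B x k) operation; a unit
test pins this fast path to the plain running-sum evaluation.

The nominal p-value is computed against the same-signed portion of the
null with add-one smoothing, `(1 + #same-sign >= |es|) / (n_same + 1)`;
normalising by the full permutation count instead empirically doubles the
null rejection rate. NES divides the score by the mean |null score| of
matching sign, and q-values follow the pooled same-sign NES ratio
procedure, capped at 1. Set members absent from the ranking are dropped
and the used size is reported; sets outside [min_size, max_size] =
[10, 500] are skipped.

## Cross-platform concordance

TPM scaling is explicit about length normalisation: `length_normalized`
records whether counts were divided by feature length before scaling to
1e6, because long-read quantifier "TPM" is frequently a CPM in disguise
and the two behave differently against gene-length bias. Per-sample and
per-feature Pearson correlations default to log2(x+1) (the raw option
exists for literal reproduction); features missing from one matrix are
dropped, not zero-imputed, since zero-imputation inflates agreement.
Jensen-Shannon divergence is computed per sample between the two
platforms' gene-probability vectors (abundances renormalised to 1),
base 2, via the squared `scipy` JS distance; the choice of distribution is
a convention, recorded here because nothing in the outputs pins it down.
Fisher's z test compares two per-sample correlations with the standard
1/(n-3) variance. Bias diagnostics regress per-gene mean log2(TPM+1) on
log10 length or GC fraction by OLS; a constant response returns slope 0,
r 0, p 1 (no bias) rather than an error, so exact no-bias constructions
are representable.

## Differential transcript usage

Counts are filtered in the DRIMSeq style with the study defaults
12/4/10/10 (samples with expressed gene / samples with expressed
transcript / gene total / transcript count), then genes keep at least two
transcripts. Fractional quantifier outputs are rounded with a warning —
the likelihood is a count model.

Per gene, transcript counts per sample are Dirichlet-multinomial with a
precision (concentration) parameter and a proportion vector; the null
shares one proportion vector across samples, the alternative has one per
condition, and the likelihood-ratio statistic is referred to chi-squared
with K-1 degrees of freedom. The precision is the critical nuisance. Three
policies were evaluated on 500-2,000-gene null simulations (12 samples,
totals ~300, true precision 50):

- re-estimating precision freely in both models is anti-conservative
  (7.7% at nominal 5%);
- fixing it at its null-model estimate restores calibration (5.5%) but
  saturates the statistic under strong single-gene effects (p floor near
  1e-3), so one extreme gene among hundreds can never survive BH — a
  method defect for exactly the sparse-signal use case this tool targets;
- estimating one common precision across genes by maximising the summed
  Cox-Reid-adjusted profile likelihood of the full model, then testing
  every gene with it fixed, is both calibrated (4-5%, KS-uniform) and
  powerful (an extreme proportion swap reaches p ~1e-150).

The pipeline uses the third policy (`estimate_common_precision`,
subsampling at most 200 genes for the joint scalar optimisation; the CR
adjustment subtracts half the log-determinant of the observed information
of the proportion logits, removing the incidental-parameter bias that
many per-gene proportion estimates induce). A standalone `dm_gene_test`
call without cross-gene information falls back to a per-gene CR-adjusted
estimate, which is mildly liberal (~7% empirically) — prefer passing the
study-wide precision. Real data in which precision varies strongly across
genes violates the common-precision approximation; the per-gene fallback
is then the honest alternative, at some cost in calibration.

Transcript-level tests collapse each transcript against the sum of the
others (K = 2, df = 1) at the same fixed precision.

### Stage-wise adjustment

Stage 1 screens genes by BH at alpha = 0.05. Stage 2 confirms transcripts
only within screened genes using Holm with Shaffer's improvement (the
gene-level rejection licenses dropping the first Holm multiplier from K to
K-1, so a two-transcript gene needs no within-gene correction), and the
confirmation p is scaled by m/R (genes tested / genes screened), capped
at 1. Transcripts of unscreened genes receive no confirmation p. The
global-null simulation keeps the fraction of genes with any confirmed
transcript below nominal.

## Synthetic data generator

The generator realises exactly the models the tests assume, which is its
purpose and its main limitation.

- **Tails.** Nuclear gene baselines mu_g (log2 median) are normal; each
  read adds a per-(gene, batch) normal effect and per-read normal noise,
  so every per-gene dataset follows the DP mixed model by construction.
  Batch effects are drawn independently per gene so that per-gene tests
  are independent across genes, as the calibration tests require.
  Mitochondrial tails are truncated-normal (centre 45 nt, sd 9, floor
  10 nt), matching the narrow symmetric mitochondrial regime, with no
  condition or batch effect.
- **Default calibration.** The defaults (gene-baseline sd 0.22 log2, read
  noise 0.22 log2, batch sd 0.2 log2, mu chosen so the mean per-gene
  median is ~84 nt) jointly place the mean of per-gene medians near 83 nt
  and the pooled nuclear density peak near 78-80 nt. Under a lognormal
  family the pooled mode is exp(mu - sigma_pooled^2) — below the median —
  so wider, more realistic spreads (which would also reproduce a 26-147 nt
  median range and ~0.2% of tails above 350 nt) drag the pooled peak far
  below 80 nt. The defaults favour the mode and mean anchors; heavier
  tails are available by configuration (the exceedance test uses gene sd
  0.45 / read noise 0.5, whose lognormal tail probability is the
  closed-form oracle). Passing tests therefore demonstrate correct
  behaviour under this family, not under the messier empirical tail
  distributions of real basecallers.
- **Counts.** Paired platform log-means are bivariate normal per gene at
  the target correlation; platform A optionally adds length and GC shifts;
  per-sample counts are Poisson around depth-scaled means. With the
  default abundance scale (log-mean 6, sd 1.5 natural log) Poisson noise
  attenuates per-sample correlations by well under 0.01, so the configured
  correlation is a usable oracle. No over-dispersion beyond Poisson, no
  zero inflation.
- **Isoforms.** Per gene and sample, a proportion vector is drawn
  Dirichlet(precision x pi_condition) and counts are multinomial around
  it, with negative-binomial totals; non-DTU genes draw one pi per gene
  from Dirichlet(5,...,5). This is exactly the DM model the test assumes —
  real data deviate through per-gene precision heterogeneity and
  positional/coverage artefacts that are not modelled.
- **Determinism.** All draws come from `numpy.random.default_rng` seeded
  with integer lists (seed, stream); identical configs and seeds give
  identical outputs on any platform.

Reads per gene per sample default to negative binomial with mean 50 and
dispersion 0.1 — a deliberately modest, blood-typical depth at which the
whole pipeline (2,000 genes, ~1.2 M reads) fits and tests in seconds.

## Pipeline

`run_all` executes simulate -> profile -> dp -> gsea -> concordance ->
dtu from a YAML config. Every stage records a parameter hash, its input
checksums and SHA-256 checksums of its outputs in `manifest.json`; a stage
re-runs only when its parameters, inputs or outputs changed, so editing a
downstream threshold leaves upstream outputs untouched (and the manifest
proves it). All result tables are TSV with 12-significant-digit floats;
identical config and seed reproduce them byte-for-byte. Figures (tail
histograms, a volcano plot) are best-effort diagnostics and deliberately
outside the determinism contract.

## Known limitations

- Two conditions only; no covariates beyond the batch random intercept.
- The DM common-precision approximation trades per-gene precision
  heterogeneity for calibration; no moderated shrinkage between the two
  extremes is implemented.
- GSEA q-values follow the pooled-NES heuristic of the canonical
  procedure; they are not a formal FDR.
- The generator produces no nucleotide sequence, no basecalling error
  model and no alignment artefacts; gene assignment in simulated data is
  always correct.
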