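# drnakit

Read-level poly(A)-tail and transcript-usage analysis for Nanopore direct
RNA sequencing, built for two-condition clinical designs (e.g. blood from
patients with bacterial vs viral sepsis). Short-read RNA-seq measures how
much of each gene is present; native RNA sequencing additionally measures
*how* each molecule is processed — the length of its poly(A) tail and
which isoform it is. drnakit turns those read-level measurements into
candidate disease biomarkers:

- **Poly(A) profiles** — per-gene median tail lengths, mitochondrial vs
  nuclear tail distributions (modes, medians, long-tail fractions), and a
  longest-to-shortest gene ranking.
- **Differential polyadenylation (DP)** — per gene, a linear mixed model
  `log2(tail) ~ condition + (1 | batch)` fitted by REML with
  Satterthwaite degrees of freedom; BH adjustment; DPG calls at
  adjusted p < 0.05 and |log2FC| >= 0.5; and a stratified bootstrap
  (reads resampled with replacement within each sample, 100x) measuring
  how robustly each call survives resampling.
- **Pre-ranked GSEA** — weighted Kolmogorov-Smirnov enrichment score on
  the tail-length ranking, gene-label permutation null, NES, and pooled
  same-sign FDR q-values.
- **Platform concordance** — TPM/CPM scaling (explicit about gene-length
  normalisation), per-sample and per-feature Pearson correlation,
  Fisher-z comparison of correlations, per-sample Jensen-Shannon
  divergence, expression-filter sweeps, and length/GC bias regressions.
- **Differential transcript usage (DTU)** — DRIMSeq-style count filtering
  (12/4/10/10), a per-gene Dirichlet-multinomial likelihood-ratio test
  with a common precision estimated across genes by Cox-Reid adjusted
  profile likelihood, per-transcript one-vs-rest tests, and stage-wise
  (screen genes, confirm transcripts) adjustment controlling the overall
  FDR.
- **Synthetic data** — truth-known generators for read-level tails
  (mitochondrial regime centred at 45 nt, nuclear regime peaking near
  80 nt, injected DP genes, batch structure), paired two-platform count
  matrices with tunable correlation and length/GC bias, and
  Dirichlet-multinomial isoform counts with injected DTU genes. Every
  statistical stage is validated against these generators.

The models and defaults are documented in [docs/methods.md](docs/methods.md).

## Worked example

A full synthetic study — 300 genes (13 mitochondrial), 12 samples, two
injected DP genes (log2 shifts +1.2 and -0.8) and one DTU gene whose
first and third isoforms swap proportions between conditions:

```yaml
# demo.yaml
seed: 17
outdir: demo_run
simulate:
  n_genes: 300
  n_mito_genes: 13
  reads_per_gene_mean: 40.0
  isoform_total_mean: 800.0
  dp_genes: {G00012: 1.2, G00040: -0.8}
  dtu_genes:
    G00020: [[0.85, 0.1, 0.05], [0.05, 0.1, 0.85]]
dp: {n_boot: 50, min_reads: 10}
gsea: {n_perm: 500, n_sets: 15, min_size: 5}
```

```bash
drnakit run --config demo.yaml
```

The run writes TSVs (plus a manifest with per-stage checksums) into
`demo_run/`. The compartment table recovers the two tail regimes:

```
compartment      n  mode  median  fraction_gt_70
       mito   6531    45  45.073        0.002603
    nuclear 138237    78  82.420        0.737422
```

— mitochondrial tails centred at 45 nt with ~0.3% above 70 nt, nuclear
tails peaking at 78 nt. The DP stage calls exactly the two injected genes,
with the right signs and bootstrap-stable significance:

```
gene_id    log2fc        p_adj  robust_fraction is_robust
 G00012  1.285735 7.581432e-07              1.0      True
 G00040 -0.834658 4.665617e-04              1.0      True
```

and the DTU stage screens the injected gene and confirms the two swapped
isoforms while leaving the stable middle isoform unconfirmed:

```
gene_id transcript_id          p_tx  stagewise_adj_p  screened
 G00020     G00020.T1 6.595154e-120    3.957092e-117      True
 G00020     G00020.T2  4.283652e-01     1.000000e+00      True
 G00020     G00020.T3 6.938748e-133    4.163249e-130      True
```

The concordance stage reports a mean per-sample Pearson r of 0.865
between the two simulated platforms (target correlation 0.9, attenuated
at this small gene count). Re-running the same config and seed reproduces
every TSV byte-for-byte; changing one threshold re-runs only the stages
downstream of it.

The same stages are available as subcommands on real inputs
(`drnakit polya-profile`, `dp-test`, `gsea`, `concordance`, `dtu`,
`simulate`), consuming tagged BAMs or tail tables, GTF/GFF3, abundance
TSVs, GMT gene sets, and a sample metadata sidecar
(`sample_id  batch  condition`).

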