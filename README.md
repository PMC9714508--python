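# spliceome

Transcript-level splicing characterization for a gene family, built for
cohort-scale RNA-seq TPM matrices (GTEx-style GCT or TSV). Instead of
summing transcripts to the gene level, the pipeline quantifies which
isoforms a gene actually uses, how that usage shifts with tissue, sex,
condition, library preparation and genotype, and provides a synthetic
cohort generator with complete ground truth so every statistic is
testable without any downloads.

## What it computes

* **Isoform usage** — for transcript *i* of gene *g* in sample *s*,
  `u_{i,s} = TPM_{i,s} / Σ_{j∈g} TPM_{j,s}` (undefined where the gene
  total is at or below an expression floor). From these: **dominance**
  (number of isoforms with usage > θ, default 0.5, in any sample or in
  any group mean) and **recurrence** (isoforms with usage > θ_r in ≥ m
  samples at a mean-TPM floor).
* **Biotype composition** — the percent of each gene's expression
  carried by protein-coding, nonsense-mediated-decay (NMD),
  retained-intron and other transcript classes, and a Kruskal–Wallis
  test of library-prep (polyA vs total RNA) effects on those shares.
* **Splice genotype** — when a biallelic variant controls a splice
  choice, the fraction using form 1 is trimodal across individuals:
  homozygotes at the extremes, heterozygotes between. Modeled as a
  3-component Gaussian mixture on logit usage selected against a
  1-component fit by BIC (`ΔBIC = BIC₁ − BIC₃ > 0` flags genotype-like
  structure), with MAP genotype calls, a Hardy–Weinberg χ² check
  (`p̂ = (2n_hom2 + n_het)/2n`, expected `n·(q², 2pq, p²)`), and OLS of
  usage on allele dosage (0/1/2) as an explicit sQTL test.
* **Group contrasts** — Welch t on log2(TPM+1) with Benjamini–Hochberg
  q-values, optional stratification (e.g. by age bracket), and a
  cross-platform consensus set: reference-significant transcripts whose
  fold-change sign agrees on every other platform.
* **Synthetic cohorts** — multi-isoform genes, Dirichlet tissue usage,
  library-prep capture bias applied *before* TPM closure (so prep
  changes apparent shares, as in real data), HWE genotype-driven splice
  usage, planted group effects, log-normal noise; all parameters
  recorded as ground truth.

## Worked example

```python
import spliceome as sp

cfg = sp.SimulationConfig(seed=3, n_subjects=200, tissues=("blood", "brain"),
                          n_genes=20, sqtl_genes=(sp.SqtlGeneSpec(gene="G001"),))
cohort = sp.simulate_cohort(cfg)
usage = sp.compute_usage(cohort.expression, cohort.annotation)
screen = sp.bimodality_screen(usage, samples=cohort.samples)
print(screen.head(2)[["gene_id", "delta_bic", "trimodal"]])
```

```
  gene_id   delta_bic  trimodal
0    G001   92.870563      True
1    G004   43.915882      True
```

The planted sQTL gene G001 tops the screen. Calling genotypes from the
mixture fit and checking Hardy–Weinberg:

```python
focal = cohort.truth.gene_transcripts["G001"][0]
rest = set(cohort.truth.gene_transcripts["G001"][1:])
u = sp.splice_form_usage(usage, "G001", {focal}, rest, samples=cohort.samples)
fit = sp.fit_usage_mixture(sp.genotype.aggregate_per_subject(u))
calls, hwe = sp.call_genotypes(fit, u)
print(round(hwe.allele_frequency_hat, 3), round(hwe.p_value, 2))
res = sp.sqtl_regression(u, cohort.genotypes, "var_G001")
print(round(res.beta, 2))
```

```
0.333 0.72
0.44
```

The estimated alt-allele frequency (0.333) matches the configured 0.3,
the called genotype counts are consistent with Hardy–Weinberg
(p = 0.72), and each alt allele shifts the two-form usage by +0.44 —
close to the configured generative effect, in which the genotype moves
the focal form's logit-mean from −3 through 0 to +3 (about +0.45 per
allele on the usage scale).

The same stages run from the shell:

```sh
spliceome simulate --out cohort/ --seed 11
spliceome profile --expression cohort/expression.gct \
    --annotation cohort/annotation.tsv --samples cohort/samples.tsv --out reports/
spliceome genotype-screen --expression cohort/expression.gct \
    --annotation cohort/annotation.tsv --samples cohort/samples.tsv \
    --genotypes cohort/genotypes.tsv --out screen/
spliceome contrast --expression cohort/expression.gct --samples cohort/samples.tsv \
    --group-key sex --level1 female --level2 male --out contrast/
```

Each run writes plain TSV reports plus a `manifest.json` with input
digests and the seed; identical inputs and seed give byte-identical
reports.

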