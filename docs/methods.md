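# Methods

## Data model

All tables are plain pandas objects. Expression is a transcripts ×
samples matrix of non-negative finite TPM; values are consumed as
provided (no renormalization on read — TPM is already a within-sample
closure). Annotation maps each transcript to exactly one gene with a
biotype from a fixed set (protein_coding, nonsense_mediated_decay,
retained_intron, processed_transcript, lncRNA, processed_pseudogene,
other); unrecognized biotype strings bucket into `other` so composition
always closes to 100%. Protein length is kept only for classes that can
be translated (protein-coding, NMD). Sample metadata uses an `"unknown"`
sentinel for missing factors rather than dropping samples. Transcript id
version suffixes (the part after the final `.`) are stripped by default
when harmonizing, since expression providers and annotation releases
frequently disagree on versions; the behaviour is a flag. Duplicate
annotation rows resolve first-wins with a logged warning. Zero overlap
after harmonization is a hard error — it almost always means an
identifier-scheme mismatch, not an empty study.

## Usage, dominance, recurrence

Usage of transcript *i* in sample *s* is its share of the gene total,
undefined where the total is at or below the expression floor (default
0). All "greater than X%" rules use strict `>`; sample-count minima use
`≥`. The dominance summary counts, per gene, isoforms exceeding the
usage threshold θ (default 0.5) in at least one sample, and separately
in at least one group mean (e.g. tissue). The "expressed isoform" count
supports two rules — mean TPM above the floor, or any single sample
above the floor — because both conventions are in circulation;
`mean_tpm` is the default. The usage denominator defaults to all
annotated transcripts of the gene; a flag restricts both the numerator
and denominator to a biotype subset. Ties at exactly θ are excluded by
strictness; ties for the top isoform break lexicographically by
transcript id for determinism. Recurrence additionally requires a
minimum number of qualifying samples and a mean-TPM floor; undefined
usage never qualifies. Common presets are (θ_r = 0.20, large m) for
isoforms common across a cohort and (θ_r = 0.75, smaller m) for isoforms
that dominate within some individuals; both thresholds are plain
parameters.

Pairwise transcript association is OLS of one transcript on another
(optionally after log2(x+1)), reporting the squared Pearson correlation;
zero variance on either axis is reported as degenerate with r² = 0
rather than an error. Gene–gene correlation operates on summed gene TPM
or on each gene's top isoform, Spearman by default.

## Biotype composition and library-prep effect

Per gene and sample, the percentage of gene expression per biotype
class; defined entries sum to 100 ± 1e-6. For the prep-effect test a
per-sample scalar is needed; the unweighted mean across genes with
defined composition is used (weighting by gene expression would let a
few high-expression genes dominate the very statistic whose biases are
under study). Groups are the library-prep levels; the test is
Kruskal–Wallis (rank-based, appropriate for bounded skewed percentages;
scipy implementation with tie correction), requiring ≥ 2 levels with ≥ 3
defined values each. Identical values across all groups report H = 0,
p = 1.

## Splice-genotype mixture

Two disjoint transcript sets define splice forms 1 and 2; the statistic
is `u = Σ form1 usage / (Σ form1 + Σ form2 usage)`, undefined where the
two-form denominator does not exceed the floor. `u` is clamped to
[δ, 1−δ] (δ = 0.005 — 0% and 100% usage are common) and
logit-transformed. A single Gaussian and a 3-component Gaussian mixture
are fit; the 3-component count is fixed by the biology (two homozygote
classes and heterozygotes), so k = 2 is deliberately not offered.
`ΔBIC = BIC₁ − BIC₃` with BIC = p·ln n − 2·logL (p = 2 and 8); ΔBIC > 0
on a converged fit flags trimodal structure.

The EM is deterministic: three fixed starts — means at the
10th/50th/90th percentiles, at the 1st/50th/99th percentiles, and at
(min, midrange, max) — each with equal weights and the pooled SD; the
best final likelihood wins. A single central-percentile start is not
sufficient: when one allele is rare (frequency ~0.1) the minor
homozygote class occupies ~1% of the sample, beyond the 90th percentile,
and EM from a central start splits the major cluster instead. The
range-anchored start reaches any cluster that contains the extremes.
Component SDs are floored at 1e-3 to prevent singular collapse;
convergence is a log-likelihood improvement below `tol` (1e-8) within
`max_iter` (500); non-convergence is reported via a flag, never an
exception; the log-likelihood is asserted non-decreasing every
iteration. Components are reported in ascending-mean order and named
HOM_1 / HET / HOM_2; the estimated allele frequency is that of the
allele carried twice by HOM_2. A component weight below
`min_component_weight` (default 0.05) trips an advisory flag: a genotype
class comprising under 5% of subjects — e.g. the minor homozygote at
allele frequency 0.02 — cannot be confidently resolved at desk-scale
cohort sizes.

Genotype calls are MAP posteriors. When a subject contributes samples
from several tissues, calling is per subject on the mean clamped-logit
usage (flag to disable): splice genotype is a property of the
individual, and the cross-tissue mean suppresses tissue-level usage
variation. Hardy–Weinberg consistency is the standard 1-df χ² of the
called counts against n·(q², 2pq, p²). The sQTL test is OLS of `u` on
alt-allele dosage with a two-sided t (n−2 df); zero residual variance
(perfectly linear input) sets a degenerate flag with SE 0 and p reported
as 0.

The cohort-wide screen reduces each gene to its two highest-mean-usage
isoforms, collapses usage per subject, fits the mixture, and ranks genes
by ΔBIC. Two screen-specific guards: (a) genes whose minor form carries
under 5% of the two-form usage on average are skipped — with one form
essentially unused there is no splice choice to genotype, and clamping
would compress the one-sided tail into a boundary point mass that mimics
an extra mixture component; (b) per-subject collapsing is the default
because tissue-specific usage otherwise masquerades as multimodality.
Single-isoform genes and genes with too few defined values are skipped
with a log entry.

## Contrasts and consensus

Welch's unequal-variance t on log2(TPM+1); the fold change is the
difference of group means on that scale (pseudocount 1; at TPM ≫ 1 the
log-ratio is recovered to within ~0.01 for a 4-fold change). Transcripts
below the pooled mean-TPM floor (default 1) are excluded before testing.
BH q-values are computed within each stratum (statsmodels
implementation, verified against the textbook step-up in tests).
Identical zero-variance groups yield t = 0, p = 1 — no evidence either
way. Swapping the group levels negates fold changes and t and leaves
p/q unchanged. The consensus set takes reference-significant transcripts
(q < α, default α = 0.05) whose fold-change sign is identical and
nonzero across the reference and every other platform table; zero fold
change counts as inconsistent, for determinism. No empirical-Bayes
variance moderation is applied — the fully specified Welch statistic is
preferred here over a moderated fit so that every number is reproducible
from the definitions above.

## Synthetic cohorts

Generative order: (1) per-gene abundance ~ log-normal (default
μ = 3, σ = 1 on the natural-log scale, i.e. typical gene TPM ≈ 20) and
per-tissue usage ~ Dirichlet(c·base + 0.05) around a gene-level base
profile (c = 8 by default: tissues related but distinct); (2) sQTL
subject genotypes ~ Binomial(2, p), focal-isoform usage =
inv-logit Normal(logit-mean of the genotype, sd), drawn once per subject
and constant across that subject's tissues, remaining isoforms rescaled
to the complement; (3) contrast effects multiply selected transcripts by
2^effect in the targeted group; (4) capture coefficients per
(library prep, biotype) multiply transcript abundance; (5) multiplicative
log-normal noise (σ = 0.25); (6) each sample column renormalized to 1e6.
Closure after capture bias is deliberate: it reproduces the
compositional artifact by which a prep that under-captures one class
inflates the apparent share of every other class.

Defaults are the study conditions: isoform counts 1–8 with roughly half
the genes single-isoform and a long right tail; the first isoform of a
gene always protein-coding, later isoforms drawn from
{protein_coding 0.45, NMD 0.15, retained_intron 0.20,
processed_transcript 0.10, lncRNA 0.10}; polyA capture 0.2 for retained
introns and 0.3 for NMD relative to total RNA (unlisted pairs 1.0);
subjects contribute one sample per tissue, emulating multi-tissue
designs and exercising per-subject genotype aggregation. Each logical
step draws from its own child of the master seed, so adding genes or
subjects does not perturb unrelated draws; identical (config, seed) is
bit-reproducible.

What the generator does **not** emulate: read-level error, positional
and GC coverage bias, exon-coordinate structure (the unit is the whole
transcript), correlated subject covariates, batch effects beyond library
prep, and isoform-count mis-annotation. Passing recovery tests therefore
demonstrates correctness of the statistics under the generative
assumptions, not robustness to every artifact of real RNA-seq.

`truth_expected_summaries` computes dominance expectations analytically
from the stored true fractions; it refuses noisy or capture-biased
configurations, where expected values would only be approximate.

## Problem sizes and numerical choices

Recovery studies use 20 cohorts of n = 550 for the mixture
(allele frequencies 0.1/0.3/0.5, logit component means (−3, 0, 3),
sd 0.5 — 6-sd separation), a 100-sample single-tissue cohort for
capture-bias recovery, 200 replicates of 10-gene cohorts for prep-test
null calibration, and 50 replicates of ~200-transcript null cohorts for
FDR calibration; these sizes give stable estimates while keeping the
full suite quick to run end to end. The capture ratio is recovered as
the exponentiated difference of group-mean log-odds of the
retained-intron share — when only one class's capture changes, its
within-gene share odds scale exactly by the coefficient, so the
log-odds difference is an unbiased estimator of the log capture ratio.
Floating-point invariants: usage sums to 1 ± 1e-9 where defined,
composition to 100 ± 1e-6; oracle equivalence is asserted at 1e-9.

## Known limitations

* The 3-component mixture detects any strong non-normality of logit
  usage, not genotype structure specifically; ΔBIC ranks candidates but
  the HWE check and (when available) dosage regression are the
  confirmatory steps.
* Nominal sQTL p-values only; no permutation-based multi-variant
  correction and no LD or population-frequency reasoning.
* The prep-effect scalar (unweighted gene mean) treats genes equally;
  genes with systematically undefined composition (unexpressed) drop
  out of the mean sample by sample.
* GTF reading consumes transcript feature lines only; full genomic
  feature parsing is out of scope.
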