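"""Synthetic multi-tissue cohort generator with complete ground truth.

The generator emulates the statistical structure the analysis assumes:
genes carrying 1-8 isoforms, tissue-specific usage profiles drawn from
Dirichlet distributions, transcript biotypes with library-prep-dependent
capture efficiency, sQTL genes whose splice-form usage is set per subject
by a Hardy-Weinberg biallelic genotype, group (sex/condition) fold
changes, multiplicative log-normal measurement noise, and per-sample TPM
closure (columns renormalized to 1e6 *after* capture bias, so prep
changes apparent shares, not just absolute abundance — the compositional
artifact real library preps produce).

Generative order: (1) gene abundances and per-tissue usage; (2) sQTL
subject genotypes ~ Binomial(2, p) with focal-isoform usage
inv-logit-normal around the genotype's logit mean, constant across a
subject's tissues; (3) contrast effects on the log2 scale; (4) capture
coefficients per (library prep, biotype); (5) log-normal noise;
(6) column renormalization to 1e6.

Each logical step draws from its own child of the master seed, so adding
genes or tissues does not perturb unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoisyTruthError, ValidationError
from .io import BIOTYPES
from .usage import DominanceCriteria

#: genes with 1..8 isoforms — anchored to the observed family structure
#: (roughly half the genes single-isoform, a long right tail to 7-8).
DEFAULT_ISOFORM_COUNT_PROBS = (0.46, 0.25, 0.14, 0.09, 0.03, 0.02, 0.007, 0.003)

#: biotype distribution of non-primary isoforms (the first isoform of a
#: gene is always protein-coding).
DEFAULT_SECONDARY_BIOTYPE_PROBS = {
    "protein_coding": 0.45,
    "nonsense_mediated_decay": 0.15,
    "retained_intron": 0.20,
    "processed_transcript": 0.10,
    "lncRNA": 0.10,
}

#: polyA selection depletes unspliced (retained-intron) and NMD-destined
#: species relative to ribo-depleted total RNA; unlisted pairs are 1.0.
DEFAULT_CAPTURE_COEFFICIENTS = {
    ("polyA", "retained_intron"): 0.2,
    ("polyA", "nonsense_mediated_decay"): 0.3,
}

AGE_BRACKETS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")


@dataclass
class SqtlGeneSpec:
    """A gene whose splice-form-1 usage is controlled by a biallelic variant."""

    gene: str
    allele_frequency: float = 0.3
    usage_logit_means: tuple = (-3.0, 0.0, 3.0)
    usage_logit_sd: float = 0.5


@dataclass
class ContrastEffect:
    """Multiplicative log2 fold change applied to selected transcripts."""

    transcripts: tuple
    group_key: str = "sex"
    level: str = "female"
    log2_effect: float = 1.0


@dataclass
class SimulationConfig:
    n_genes: int = 30
    isoform_count_probs: tuple = DEFAULT_ISOFORM_COUNT_PROBS
    n_subjects: int = 60
    tissues: tuple = ("blood", "brain", "artery")
    gene_abundance_log_mu: float = 3.0
    gene_abundance_log_sigma: float = 1.0
    usage_concentration: float = 8.0
    secondary_biotype_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_SECONDARY_BIOTYPE_PROBS)
    )
    library_prep_probs: dict = field(default_factory=lambda: {"polyA": 0.5, "total": 0.5})
    capture_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE_COEFFICIENTS)
    )
    sqtl_genes: tuple = ()
    contrast_effects: tuple = ()
    condition_probs: dict = field(default_factory=lambda: {"control": 0.5, "case": 0.5})
    noise_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        def _check_probs(name, probs):
            p = np.asarray(list(probs), dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValidationError(f"{name} must be a probability vector summing to 1")

        if self.n_genes < 1 or self.n_subjects < 1:
            raise ValidationError("n_genes and n_subjects must be positive")
        if len(self.isoform_count_probs) != 8:
            raise ValidationError("isoform_count_probs must cover isoform counts 1..8")
        _check_probs("isoform_count_probs", self.isoform_count_probs)
        _check_probs("secondary_biotype_probs", self.secondary_biotype_probs.values())
        _check_probs("library_prep_probs", self.library_prep_probs.values())
        _check_probs("condition_probs", self.condition_probs.values())
        for (prep, bt), coef in self.capture_coefficients.items():
            if coef <= 0:
                raise ValidationError(f"capture coefficient ({prep}, {bt}) must be > 0")
            if bt not in BIOTYPES:
                raise ValidationError(f"unknown biotype {bt!r} in capture_coefficients")
        for spec in self.sqtl_genes:
            if not 0.0 < spec.allele_frequency < 1.0:
                raise ValidationError("sQTL allele frequency must lie in (0, 1)")
            if len(spec.usage_logit_means) != 3:
                raise ValidationError("usage_logit_means needs 3 values (per genotype)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not self.tissues:
            raise ValidationError("at least one tissue required")


@dataclass
class SyntheticTruth:
    """Complete generative state for recovery testing."""

    config: SimulationConfig
    gene_transcripts: dict  # gene_id -> list of transcript ids
    biotypes: pd.Series  # per transcript
    gene_abundance: pd.Series  # per gene, TPM-scale before closure
    tissue_usage: dict  # gene_id -> DataFrame (tissue x transcript)
    sqtl_genotypes: dict  # gene_id -> Series dosage per subject
    sqtl_focal_usage: dict  # gene_id -> Series u per subject
    sample_prep: pd.Series  # per sample
    capture_multipliers: pd.DataFrame  # transcript x sample
    true_fractions: pd.DataFrame  # transcript x sample, pre-capture/noise
    true_tpm: pd.DataFrame  # transcript x sample, post-capture pre-noise, closed


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    genotypes: pd.DataFrame
    truth: SyntheticTruth


def _closure(matrix: pd.DataFrame, total: float = 1e6) -> pd.DataFrame:
    colsum = matrix.sum(axis=0)
    return matrix * (total / colsum)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort; bit-reproducible from (config, config.seed)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        s_structure,
        s_abundance,
        s_usage,
        s_genotypes,
        s_assign,
        s_noise,
    ) = ss.spawn(6)
    rng_structure = np.random.default_rng(s_structure)
    rng_abundance = np.random.default_rng(s_abundance)
    rng_usage = np.random.default_rng(s_usage)
    rng_genotypes = np.random.default_rng(s_genotypes)
    rng_assign = np.random.default_rng(s_assign)
    rng_noise = np.random.default_rng(s_noise)

    # --- gene/transcript structure ---------------------------------------
    genes = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    symbols = {g: f"GENE{i + 1}" for i, g in enumerate(genes)}
    n_iso = rng_structure.choice(
        np.arange(1, 9), size=config.n_genes, p=np.asarray(config.isoform_count_probs)
    )
    sec_classes = list(config.secondary_biotype_probs)
    sec_p = np.asarray([config.secondary_biotype_probs[c] for c in sec_classes])
    gene_transcripts: dict[str, list[str]] = {}
    biotype_map: dict[str, str] = {}
    for g, k in zip(genes, n_iso):
        txs = [f"{g}T{j + 1}" for j in range(k)]
        gene_transcripts[g] = txs
        biotype_map[txs[0]] = "protein_coding"
        for tx in txs[1:]:
            biotype_map[tx] = rng_structure.choice(sec_classes, p=sec_p)
    transcripts = [tx for g in genes for tx in gene_transcripts[g]]
    biotypes = pd.Series({tx: biotype_map[tx] for tx in transcripts}, name="biotype")
    protein_len = {
        tx: (
            int(rng_structure.integers(50, 300))
            if biotype_map[tx] in ("protein_coding", "nonsense_mediated_decay")
            else np.nan
        )
        for tx in transcripts
    }
    annotation = pd.DataFrame(
        {
            "gene_id": [g for g in genes for _ in gene_transcripts[g]],
            "gene_symbol": [symbols[g] for g in genes for _ in gene_transcripts[g]],
            "biotype": biotypes.to_numpy(),
            "protein_length_aa": [protein_len[tx] for tx in transcripts],
        },
        index=pd.Index(transcripts, name="transcript_id"),
    )

    # --- abundances and per-tissue usage ----------------------------------
    gene_abundance = pd.Series(
        np.exp(
            rng_abundance.normal(
                config.gene_abundance_log_mu,
                config.gene_abundance_log_sigma,
                size=config.n_genes,
            )
        ),
        index=genes,
        name="tpm",
    )
    tissue_usage: dict[str, pd.DataFrame] = {}
    for g in genes:
        k = len(gene_transcripts[g])
        base = rng_usage.dirichlet(np.ones(k))
        profiles = np.vstack(
            [
                rng_usage.dirichlet(config.usage_concentration * base + 0.05)
                for _ in config.tissues
            ]
        )
        tissue_usage[g] = pd.DataFrame(
            profiles, index=list(config.tissues), columns=gene_transcripts[g]
        )

    # --- subjects, samples, metadata ---------------------------------------
    subjects = [f"SUBJ{i + 1:03d}" for i in range(config.n_subjects)]
    sample_rows = []
    prep_levels = list(config.library_prep_probs)
    prep_p = np.asarray([config.library_prep_probs[l] for l in prep_levels])
    cond_levels = list(config.condition_probs)
    cond_p = np.asarray([config.condition_probs[l] for l in cond_levels])
    subj_sex = rng_assign.choice(["female", "male"], size=config.n_subjects)
    subj_age = rng_assign.choice(AGE_BRACKETS, size=config.n_subjects)
    subj_cond = rng_assign.choice(cond_levels, size=config.n_subjects, p=cond_p)
    for i, subj in enumerate(subjects):
        for tissue in config.tissues:
            sample_rows.append(
                {
                    "sample_id": f"{subj}-{tissue}",
                    "subject_id": subj,
                    "tissue": tissue,
                    "sex": subj_sex[i],
                    "age_bracket": subj_age[i],
                    "library_prep": rng_assign.choice(prep_levels, p=prep_p),
                    "project_id": "SIM",
                    "condition": subj_cond[i],
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    sample_ids = list(samples.index)

    # --- sQTL genotypes and per-subject focal usage ------------------------
    sqtl_genotypes: dict[str, pd.Series] = {}
    sqtl_focal_usage: dict[str, pd.Series] = {}
    geno_rows = []
    for spec in config.sqtl_genes:
        if spec.gene not in gene_transcripts:
            raise ValidationError(f"sQTL gene {spec.gene!r} not among simulated genes")
        if len(gene_transcripts[spec.gene]) < 2:
            raise ValidationError(f"sQTL gene {spec.gene!r} needs >= 2 isoforms")
        dosage = rng_genotypes.binomial(2, spec.allele_frequency, size=config.n_subjects)
        means = np.asarray(spec.usage_logit_means, dtype=float)
        x = rng_genotypes.normal(means[dosage], spec.usage_logit_sd)
        u1 = 1.0 / (1.0 + np.exp(-x))
        sqtl_genotypes[spec.gene] = pd.Series(dosage, index=subjects)
        sqtl_focal_usage[spec.gene] = pd.Series(u1, index=subjects)
        for subj, d in zip(subjects, dosage):
            geno_rows.append(
                {"subject_id": subj, "variant_id": f"var_{spec.gene}", "dosage": d}
            )
    genotypes = pd.DataFrame(geno_rows, columns=["subject_id", "variant_id", "dosage"])
    if not genotypes.empty:
        genotypes["dosage"] = genotypes["dosage"].astype("Int64")

    # --- assemble true fractions and abundances ----------------------------
    frac = np.zeros((len(transcripts), len(sample_ids)))
    tx_pos = {tx: i for i, tx in enumerate(transcripts)}
    subj_of = samples["subject_id"]
    tissue_of = samples["tissue"]
    for g in genes:
        txs = gene_transcripts[g]
        rows = [tx_pos[t] for t in txs]
        prof = tissue_usage[g].loc[tissue_of.to_numpy()].to_numpy()  # samples x k
        if g in sqtl_focal_usage:
            u1 = sqtl_focal_usage[g].loc[subj_of.to_numpy()].to_numpy()
            rest = prof[:, 1:]
            rest_sum = rest.sum(axis=1, keepdims=True)
            rest_scaled = np.where(
                rest_sum > 0, rest / rest_sum, 1.0 / max(len(txs) - 1, 1)
            ) * (1.0 - u1)[:, None]
            prof = np.column_stack([u1, rest_scaled])
        frac[rows, :] = prof.T
    fractions = pd.DataFrame(frac, index=transcripts, columns=sample_ids)
    abundance_per_tx = fractions.mul(
        gene_abundance.loc[annotation["gene_id"]].to_numpy(), axis=0
    )

    # --- contrast effects (log2 scale) --------------------------------------
    for eff in config.contrast_effects:
        missing = [t for t in eff.transcripts if t not in tx_pos]
        if missing:
            raise ValidationError(f"contrast effect transcripts not simulated: {missing}")
        mask = samples[eff.group_key] == eff.level
        cols = samples.index[mask]
        abundance_per_tx.loc[list(eff.transcripts), cols] *= 2.0**eff.log2_effect

    # --- capture bias --------------------------------------------------------
    prep_of = samples["library_prep"]
    capture = np.ones((len(transcripts), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        prep = prep_of.loc[sid]
        for i, tx in enumerate(transcripts):
            coef = config.capture_coefficients.get((prep, biotype_map[tx]), 1.0)
            capture[i, j] = coef
    capture_mult = pd.DataFrame(capture, index=transcripts, columns=sample_ids)
    biased = abundance_per_tx * capture_mult
    true_tpm = _closure(biased)

    # --- measurement noise and closure ---------------------------------------
    if config.noise_sigma > 0:
        noise = np.exp(
            rng_noise.normal(0.0, config.noise_sigma, size=biased.shape)
        )
    else:
        noise = np.ones(biased.shape)
    expression = _closure(biased * noise)

    truth = SyntheticTruth(
        config=config,
        gene_transcripts=gene_transcripts,
        biotypes=biotypes,
        gene_abundance=gene_abundance,
        tissue_usage=tissue_usage,
        sqtl_genotypes=sqtl_genotypes,
        sqtl_focal_usage=sqtl_focal_usage,
        sample_prep=prep_of,
        capture_multipliers=capture_mult,
        true_fractions=fractions,
        true_tpm=true_tpm,
    )
    return SimulatedCohort(
        expression=expression,
        annotation=annotation,
        samples=samples,
        genotypes=genotypes,
        truth=truth,
    )


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (YAML-loaded) mapping.

    ``capture_coefficients`` may be given nested as
    ``{prep: {biotype: coef}}``; ``sqtl_genes`` and ``contrast_effects``
    as lists of mappings.
    """
    data = dict(data)
    cap = data.get("capture_coefficients")
    if cap is not None and cap and isinstance(next(iter(cap.values())), dict):
        data["capture_coefficients"] = {
            (prep, bt): float(c) for prep, sub in cap.items() for bt, c in sub.items()
        }
    if "sqtl_genes" in data:
        data["sqtl_genes"] = tuple(
            s if isinstance(s, SqtlGeneSpec) else SqtlGeneSpec(
                gene=s["gene"],
                allele_frequency=float(s.get("allele_frequency", 0.3)),
                usage_logit_means=tuple(s.get("usage_logit_means", (-3.0, 0.0, 3.0))),
                usage_logit_sd=float(s.get("usage_logit_sd", 0.5)),
            )
            for s in data["sqtl_genes"]
        )
    if "contrast_effects" in data:
        data["contrast_effects"] = tuple(
            e if isinstance(e, ContrastEffect) else ContrastEffect(
                transcripts=tuple(e["transcripts"]),
                group_key=e.get("group_key", "sex"),
                level=e.get("level", "female"),
                log2_effect=float(e.get("log2_effect", 1.0)),
            )
            for e in data["contrast_effects"]
        )
    for key in ("isoform_count_probs", "tissues"):
        if key in data:
            data[key] = tuple(data[key])
    valid = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown simulation config field(s): {sorted(unknown)}")
    return SimulationConfig(**data)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def simulate_splice_usage(
    n: int,
    allele_frequency: float,
    usage_logit_means=(-3.0, 0.0, 3.0),
    usage_logit_sd: float = 0.5,
    seed: int = 0,
):
    """Draw (usage fractions, genotype dosages) for one sQTL-controlled form.

    A light-weight helper for mixture-model recovery studies: genotype
    ~ Binomial(2, p) under HWE, usage = inv-logit Normal around the
    genotype's logit mean.
    """
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, allele_frequency, size=n)
    means = np.asarray(usage_logit_means, dtype=float)
    x = rng.normal(means[dosage], usage_logit_sd)
    return 1.0 / (1.0 + np.exp(-x)), dosage


def truth_expected_summaries(
    truth: SyntheticTruth,
    criteria: DominanceCriteria,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Analytic dominance summaries from the generative truth.

    Only meaningful when the observed matrix equals the truth, i.e. a
    noiseless simulation with unit capture coefficients; otherwise refuses
    (expected values would be approximate). Computed with independent
    straightforward loops over the true per-sample fractions and closed
    TPM, serving as a cross-module oracle for the usage statistics.
    """
    cfg = truth.config
    if cfg.noise_sigma > 0:
        raise NoisyTruthError("expected summaries require a noiseless simulation")
    if any(c != 1.0 for c in cfg.capture_coefficients.values()):
        raise NoisyTruthError("expected summaries require unit capture coefficients")
    theta = criteria.fraction_threshold
    groups = None
    if criteria.group_key is not None:
        if samples is None or criteria.group_key not in samples.columns:
            raise ValidationError(
                "group-level expected summaries need the sample table"
            )
        groups = samples.loc[truth.true_fractions.columns, criteria.group_key]
    rows = []
    for g, txs in truth.gene_transcripts.items():
        frac = truth.true_fractions.loc[txs]
        tpm = truth.true_tpm.loc[txs]
        if criteria.expressed_rule == "mean_tpm":
            n_expr = int((tpm.mean(axis=1) > criteria.expressed_tpm_floor).sum())
        else:
            n_expr = int((tpm > criteria.expressed_tpm_floor).any(axis=1).sum())
        n_sample_dom = int((frac > theta).any(axis=1).sum())
        mean_frac = frac.mean(axis=1)
        order = mean_frac.loc[sorted(mean_frac.index)].sort_values(
            ascending=False, kind="stable"
        )
        if groups is not None:
            gm = frac.T.groupby(groups).mean().T
            n_group = int((gm > theta).any(axis=1).sum())
        else:
            n_group = np.nan
        rows.append(
            {
                "gene_id": g,
                "n_expressed_isoforms": n_expr,
                "top_isoform_id": order.index[0],
                "top_isoform_mean_fraction": float(order.iloc[0]),
                "n_sample_dominant": n_sample_dom,
                "n_group_dominant": n_group,
            }
        )
    return pd.DataFrame(rows)
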