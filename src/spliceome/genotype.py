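"""Genotype-like structure in splice-form usage and sQTL association.

When a biallelic variant controls the choice between two splice forms,
the per-sample fraction *u* of expression using form 1 clusters into
three groups — the two homozygote classes at the extremes and
heterozygotes in between. This module formalizes that reading as a
three-component Gaussian mixture on the logit of *u*, selected against a
one-component fit by BIC, followed by MAP genotype calls, a
Hardy-Weinberg consistency check on the called counts, and an explicit
per-allele-dosage linear regression when genotypes are available.

The two-component alternative is deliberately not fit: the biological
model has three genotype classes, and a nearly-absent class manifests as
a near-zero mixture weight (exposed via ``min_component_weight``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    InsufficientDataError,
    NotTrimodalError,
    UnknownIdError,
    ValidationError,
)
from .usage import GeneUsage

logger = logging.getLogger("spliceome")

GENOTYPE_CLASSES = ("HOM_1", "HET", "HOM_2")

_SD_FLOOR = 1e-3


def logit(u: np.ndarray) -> np.ndarray:
    return np.log(u) - np.log1p(-u)


def inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def splice_form_usage(
    usage: GeneUsage,
    gene: str,
    form1: set,
    form2: set,
    samples: pd.DataFrame | None = None,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Fraction of a gene's two-form expression carried by splice form 1.

    ``u = sum(form1 usage) / (sum(form1 usage) + sum(form2 usage))``,
    undefined (NaN) where the two-form denominator does not exceed the
    floor. Returns a DataFrame indexed by sample with columns ``u`` and
    ``subject_id`` (the sample id itself when no sample table is given).
    """
    form1, form2 = set(form1), set(form2)
    if not form1 or not form2:
        raise ValidationError("both form sets must be non-empty")
    if form1 & form2:
        raise ValidationError(f"form sets overlap: {sorted(form1 & form2)}")
    gene_tx = set(usage.annotation.index[usage.annotation["gene_id"] == gene])
    if not gene_tx:
        raise UnknownIdError(f"gene {gene!r} not in annotation")
    stray = (form1 | form2) - gene_tx
    if stray:
        raise UnknownIdError(f"transcripts {sorted(stray)} not members of gene {gene!r}")
    f1 = usage.fractions.loc[sorted(form1)].sum(axis=0, min_count=1)
    f2 = usage.fractions.loc[sorted(form2)].sum(axis=0, min_count=1)
    denom = f1 + f2
    with np.errstate(invalid="ignore", divide="ignore"):
        u = f1 / denom
    u[~(denom > floor)] = np.nan
    subjects = (
        samples.loc[u.index, "subject_id"]
        if samples is not None
        else pd.Series(u.index, index=u.index)
    )
    return pd.DataFrame({"u": u, "subject_id": subjects})


def aggregate_per_subject(u: pd.DataFrame, clamp: float = 0.005) -> pd.DataFrame:
    """Collapse per-sample usage to one value per subject (mean on logit scale).

    Splice genotype is a property of the individual, not the tissue: a
    subject sampled in several tissues contributes the inverse-logit of
    its mean clamped-logit usage. Returns the same (u, subject_id) layout
    with one row per subject.
    """
    values = u.dropna(subset=["u"])
    x = values.groupby("subject_id")["u"].apply(
        lambda v: float(np.mean(logit(np.clip(v.to_numpy(), clamp, 1 - clamp))))
    )
    return pd.DataFrame({"u": inv_logit(x.to_numpy()), "subject_id": x.index}, index=x.index)


def _normal_logpdf(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


class LogitUsageMixture(BaseEstimator):
    """Gaussian mixture on logit splice-form usage with 1-vs-3 BIC selection.

    Usage fractions are clamped to ``[clamp, 1 - clamp]`` (0% and 100%
    usage are common) and logit-transformed. A single Gaussian and a
    three-component mixture are both fit; ``delta_bic_ > 0`` (BIC of k=1
    minus BIC of k=3) flags genotype-like trimodal structure. The k=3 EM
    is initialized deterministically at the 10th/50th/90th percentiles
    with equal weights and the pooled standard deviation, so ``seed`` only
    exists for interface symmetry with the stochastic parts of the
    pipeline.

    Fitted attributes (components in ascending-mean order): ``means_``,
    ``sds_``, ``weights_``, ``loglik_k1_``, ``loglik_k3_``, ``bic_k1_``,
    ``bic_k3_``, ``delta_bic_``, ``converged_``, ``n_iter_``,
    ``trimodal_``, ``low_weight_component_``.
    """

    def __init__(
        self,
        clamp: float = 0.005,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: int = 0,
        min_component_weight: float = 0.05,
        min_n: int = 30,
    ):
        self.clamp = clamp
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.min_component_weight = min_component_weight
        self.min_n = min_n

    # -- internals ---------------------------------------------------------

    def _to_logit(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        u = u[np.isfinite(u)]
        return logit(np.clip(u, self.clamp, 1.0 - self.clamp))

    def fit(self, u, y=None):
        """Fit both models on an array/Series of usage fractions (NaN dropped)."""
        if not (0.0 < self.clamp < 0.5):
            raise ValidationError("clamp must lie in (0, 0.5)")
        x = self._to_logit(np.asarray(u, dtype=float))
        n = x.size
        if n < self.min_n:
            raise InsufficientDataError(f"mixture fit needs >= {self.min_n} values, got {n}")

        # k = 1: closed-form Gaussian MLE
        mu1 = float(x.mean())
        sd1 = float(max(x.std(), _SD_FLOOR))
        self.loglik_k1_ = float(_normal_logpdf(x, mu1, sd1).sum())
        self.bic_k1_ = 2 * np.log(n) - 2.0 * self.loglik_k1_
        self.mean_k1_, self.sd_k1_ = mu1, sd1

        # k = 3 EM. Several deterministic percentile starts (the central
        # 10/50/90 one plus wider ones that reach a rare homozygote class
        # when an allele is uncommon); the best-likelihood solution wins.
        starts = [
            np.percentile(x, [10.0, 50.0, 90.0]).astype(float),
            np.percentile(x, [1.0, 50.0, 99.0]).astype(float),
            # range-anchored start: reaches a rare homozygote cluster that
            # occupies < 10% of the sample and anchors the heterozygote
            # component between the extremes
            np.array([x.min(), 0.5 * (x.min() + x.max()), x.max()]),
        ]
        best = None
        for means0 in starts:
            result = self._em(x, means0)
            if best is None or result[3] > best[3]:
                best = result
        means, sds, weights, ll, converged, it = best
        order = np.argsort(means, kind="stable")
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.weights_ = weights[order]
        self.loglik_k3_ = ll
        self.bic_k3_ = 8 * np.log(n) - 2.0 * ll
        self.delta_bic_ = float(self.bic_k1_ - self.bic_k3_)
        self.converged_ = converged
        self.n_iter_ = it
        self.n_ = n
        self.trimodal_ = bool(self.converged_ and self.delta_bic_ > 0)
        self.low_weight_component_ = bool((self.weights_ < self.min_component_weight).any())
        return self

    def _em(self, x: np.ndarray, means0: np.ndarray):
        """One EM run from a given mean initialization; loglik is monotone."""
        n = x.size
        means = means0.copy()
        sds = np.full(3, max(x.std(), _SD_FLOOR))
        weights = np.full(3, 1.0 / 3.0)
        prev_ll = -np.inf
        converged = False
        ll = prev_ll
        for it in range(1, self.max_iter + 1):
            log_comp = _normal_logpdf(x[:, None], means[None, :], sds[None, :]) + np.log(
                weights
            )[None, :]
            log_norm = np.logaddexp.reduce(log_comp, axis=1)
            ll = float(log_norm.sum())
            # EM monotonicity invariant (tiny slack for round-off)
            assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), "EM loglik decreased"
            if ll - prev_ll < self.tol:
                converged = True
                break
            prev_ll = ll
            resp = np.exp(log_comp - log_norm[:, None])
            nk = np.maximum(resp.sum(axis=0), 1e-12)
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), _SD_FLOOR)
            weights = nk / n
        return means, sds, weights, ll, converged, it

    def predict_proba(self, u) -> np.ndarray:
        """Posterior responsibilities of the three components for each value."""
        x = logit(np.clip(np.asarray(u, dtype=float), self.clamp, 1.0 - self.clamp))
        log_comp = _normal_logpdf(x[:, None], self.means_[None, :], self.sds_[None, :]) + np.log(
            np.maximum(self.weights_, 1e-300)
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        return np.exp(log_comp - log_norm[:, None])

    def predict(self, u) -> np.ndarray:
        """MAP genotype class (HOM_1 / HET / HOM_2) per value."""
        proba = self.predict_proba(u)
        return np.array(GENOTYPE_CLASSES, dtype=object)[proba.argmax(axis=1)]


def fit_usage_mixture(
    u: pd.DataFrame | pd.Series | np.ndarray,
    clamp: float = 0.005,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> LogitUsageMixture:
    """Functional wrapper over :class:`LogitUsageMixture`.

    ``u`` may be the frame returned by :func:`splice_form_usage` (its ``u``
    column is used) or a bare array of fractions. Non-convergence is
    reported via ``converged_=False``, never as an exception.
    """
    values = u["u"] if isinstance(u, pd.DataFrame) else u
    return LogitUsageMixture(clamp=clamp, tol=tol, max_iter=max_iter, seed=seed).fit(values)


# ---------------------------------------------------------------------------
# genotype calls + Hardy-Weinberg
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    allele_frequency_hat: float
    observed: tuple
    expected: tuple
    chi_square: float
    p_value: float


def hardy_weinberg_test(n_hom1: int, n_het: int, n_hom2: int) -> HweResult:
    """Chi-square (1 df) consistency of genotype counts with HWE.

    The estimated allele frequency is that of the allele carried twice by
    HOM_2: ``p_hat = (2 n_hom2 + n_het) / (2 n)``; expected counts are
    ``n * (q^2, 2pq, p^2)``.
    """
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise InsufficientDataError("no genotype calls")
    p = (2 * n_hom2 + n_het) / (2 * n)
    q = 1.0 - p
    expected = (n * q * q, n * 2 * p * q, n * p * p)
    observed = (n_hom1, n_het, n_hom2)
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            chi2 += (o - e) ** 2 / e
    return HweResult(
        allele_frequency_hat=float(p),
        observed=observed,
        expected=expected,
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


def call_genotypes(
    fit: LogitUsageMixture, u: pd.DataFrame, per_subject: bool = True
) -> tuple[pd.DataFrame, HweResult]:
    """MAP genotype calls plus an HWE consistency check.

    Refuses (``NotTrimodalError``) unless the fit converged with positive
    BIC support for three components. With ``per_subject`` (default), a
    subject with samples in several tissues is called once, on the mean of
    its clamped logit usage — splice genotype is a property of the
    individual, not the tissue.
    """
    if not (getattr(fit, "converged_", False) and fit.delta_bic_ > 0):
        raise NotTrimodalError(
            "genotype calling requires a converged fit with delta_bic > 0"
        )
    values = u.dropna(subset=["u"])
    if per_subject:
        agg = aggregate_per_subject(values, clamp=fit.clamp)
        uu = agg["u"].to_numpy()
        ids = agg["subject_id"]
    else:
        uu = values["u"].to_numpy()
        ids = values.index
    proba = fit.predict_proba(uu)
    classes = np.array(GENOTYPE_CLASSES, dtype=object)[proba.argmax(axis=1)]
    calls = pd.DataFrame(
        {
            "subject_id": ids if per_subject else values["subject_id"].to_numpy(),
            "genotype": classes,
            "p_hom1": proba[:, 0],
            "p_het": proba[:, 1],
            "p_hom2": proba[:, 2],
        }
    ).reset_index(drop=True)
    counts = [int((classes == c).sum()) for c in GENOTYPE_CLASSES]
    hwe = hardy_weinberg_test(*counts)
    return calls, hwe


# ---------------------------------------------------------------------------
# sQTL regression
# ---------------------------------------------------------------------------


@dataclass
class SqtlResult:
    variant_id: str
    beta: float
    intercept: float
    standard_error: float
    t_statistic: float
    p_nominal: float
    n: int
    n_per_dosage: dict
    degenerate: bool


def sqtl_regression(
    u: pd.DataFrame, genotypes: pd.DataFrame, variant_id: str
) -> SqtlResult:
    """OLS of splice-form usage on alt-allele dosage (0/1/2).

    Two-sided p from the t distribution with n - 2 df. Perfectly linear
    (zero residual variance) data sets the degenerate flag, reporting
    p = 0 and standard error 0.
    """
    geno = genotypes[genotypes["variant_id"] == variant_id]
    if geno.empty:
        raise UnknownIdError(f"variant {variant_id!r} not in genotype table")
    dosage_by_subject = geno.dropna(subset=["dosage"]).set_index("subject_id")["dosage"]
    values = u.dropna(subset=["u"]).copy()
    values["dosage"] = values["subject_id"].map(dosage_by_subject)
    values = values.dropna(subset=["dosage"])
    n = len(values)
    if n < 10:
        raise InsufficientDataError(f"sQTL regression needs >= 10 samples, got {n}")
    d = values["dosage"].astype(float).to_numpy()
    y = values["u"].astype(float).to_numpy()
    levels, level_counts = np.unique(d, return_counts=True)
    if levels.size < 2:
        raise InsufficientDataError("all genotype dosages identical")
    # normal equations
    dc = d - d.mean()
    beta = float(np.dot(dc, y) / np.dot(dc, dc))
    intercept = float(y.mean() - beta * d.mean())
    resid = y - intercept - beta * d
    rss = float(np.dot(resid, resid))
    tss = float(np.dot(y - y.mean(), y - y.mean()))
    degenerate = rss <= 1e-12 * max(tss, 1.0)
    n_per = {int(k): int(v) for k, v in zip(levels, level_counts)}
    if degenerate:
        return SqtlResult(variant_id, beta, intercept, 0.0, np.inf, 0.0, n, n_per, True)
    se = float(np.sqrt(rss / (n - 2) / np.dot(dc, dc)))
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SqtlResult(variant_id, beta, intercept, se, float(t), p, n, n_per, False)


# ---------------------------------------------------------------------------
# cohort-wide screen
# ---------------------------------------------------------------------------


def bimodality_screen(
    usage: GeneUsage,
    genes: list | None = None,
    samples: pd.DataFrame | None = None,
    floor: float = 0.0,
    clamp: float = 0.005,
    tol: float = 1e-8,
    max_iter: int = 500,
    per_subject: bool = True,
    min_minor_usage: float = 0.05,
) -> pd.DataFrame:
    """Screen genes for genotype-like splice-form structure.

    Each gene is reduced to its two highest-mean-usage isoforms as
    form 1 / form 2; the logit-usage mixture is fit and genes are ranked
    by ``delta_bic`` descending. With ``per_subject`` (default) and a
    sample table linking samples to subjects, usage is collapsed to one
    value per subject before fitting — tissue-specific usage differences
    would otherwise masquerade as multimodality. Genes where the minor
    form carries less than ``min_minor_usage`` of the two-form total on
    average are skipped: with one form essentially unused there is no
    splice choice to genotype, and the clamp would compress the one-sided
    tail into a boundary point mass that mimics an extra component.
    Genes failing any precondition are skipped with a log entry.
    """
    if genes is None:
        genes = list(usage.annotation["gene_id"].unique())
    rows = []
    for gene in genes:
        ann_g = usage.annotation[usage.annotation["gene_id"] == gene]
        if len(ann_g) < 2:
            logger.info("bimodality screen: %s has < 2 isoforms, skipped", gene)
            continue
        mean_use = usage.fractions.loc[ann_g.index].mean(axis=1)
        top2 = mean_use.loc[sorted(mean_use.index)].sort_values(ascending=False, kind="stable").index[:2]
        form1, form2 = {top2[0]}, {top2[1]}
        u = splice_form_usage(usage, gene, form1, form2, samples=samples, floor=floor)
        mean_u = u["u"].mean()
        if not (min_minor_usage <= mean_u <= 1 - min_minor_usage):
            logger.info(
                "bimodality screen: %s minor form below %.3f of two-form usage, skipped",
                gene,
                min_minor_usage,
            )
            continue
        if per_subject and samples is not None:
            u = aggregate_per_subject(u, clamp=clamp)
        try:
            fit = fit_usage_mixture(u, clamp=clamp, tol=tol, max_iter=max_iter)
        except InsufficientDataError as exc:
            logger.info("bimodality screen: %s skipped (%s)", gene, exc)
            continue
        rows.append(
            {
                "gene_id": gene,
                "form1": top2[0],
                "form2": top2[1],
                "delta_bic": fit.delta_bic_,
                "converged": fit.converged_,
                "trimodal": fit.trimodal_,
                "low_weight_component": fit.low_weight_component_,
                "mean_low": inv_logit(fit.means_[0]),
                "mean_mid": inv_logit(fit.means_[1]),
                "mean_high": inv_logit(fit.means_[2]),
                "n": fit.n_,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "form1",
            "form2",
            "delta_bic",
            "converged",
            "trimodal",
            "low_weight_component",
            "mean_low",
            "mean_mid",
            "mean_high",
            "n",
        ],
    )
    return out.sort_values(["delta_bic", "gene_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
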