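"""Per-gene isoform-usage fractions, dominance and recurrence statistics.

Usage of transcript *i* of gene *g* in sample *s* is its share of the
gene's total expression, ``tpm[i,s] / sum_{j in g} tpm[j,s]``, undefined
where the gene total does not exceed the expression floor. Dominance
("which isoforms ever carry more than θ of the gene") and recurrence
("which isoforms carry more than θ_r of the gene in at least m samples at
a TPM floor") are thresholded with strict ``>`` on fractions and ``>=``
on sample-count minima throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UnknownIdError

logger = logging.getLogger("spliceome")


@dataclass
class GeneUsage:
    """Isoform usage fractions plus the supporting gene totals.

    Attributes
    ----------
    fractions : DataFrame
        transcripts × samples, values in [0, 1], NaN where the gene total
        is at or below the floor.
    gene_totals : DataFrame
        genes × samples summed TPM.
    annotation : DataFrame
        the (harmonized) annotation the tensor was built against, indexed
        by transcript_id.
    floor : float
        expression floor used for definedness.
    """

    fractions: pd.DataFrame
    gene_totals: pd.DataFrame
    annotation: pd.DataFrame
    floor: float

    @property
    def tx2gene(self) -> pd.Series:
        return self.annotation["gene_id"]

    def gene_fractions(self, gene_id: str) -> pd.DataFrame:
        tx = self.annotation.index[self.annotation["gene_id"] == gene_id]
        if len(tx) == 0:
            raise UnknownIdError(f"gene {gene_id!r} not in annotation")
        return self.fractions.loc[tx]


@dataclass
class DominanceCriteria:
    fraction_threshold: float = 0.5
    expressed_tpm_floor: float = 1.0
    expressed_rule: str = "mean_tpm"  # or "any_sample_tpm"
    biotype_filter: frozenset | None = None
    group_key: str | None = None
    filter_denominator: bool = False


@dataclass
class RecurrenceCriteria:
    fraction_threshold: float = 0.2
    min_samples: int = 1
    mean_tpm_floor: float = 1.0


@dataclass
class PairAssociation:
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool


def compute_usage(
    matrix: pd.DataFrame, annotation: pd.DataFrame, expression_floor: float = 0.0
) -> GeneUsage:
    """Build the per-gene usage tensor from a harmonized TPM matrix."""
    ann = annotation.loc[annotation.index.intersection(matrix.index)]
    dropped = annotation.index.difference(matrix.index)
    if len(dropped):
        logger.warning("%d annotated transcripts absent from matrix, skipped", len(dropped))
    mat = matrix.loc[ann.index]
    totals = mat.groupby(ann["gene_id"], sort=False).sum()
    denom = totals.loc[ann["gene_id"]].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = mat.to_numpy() / denom
    frac[denom <= expression_floor] = np.nan
    fractions = pd.DataFrame(frac, index=mat.index, columns=mat.columns)
    return GeneUsage(fractions=fractions, gene_totals=totals, annotation=ann, floor=expression_floor)


def _expressed_mask(tpm: pd.DataFrame, rule: str, floor: float) -> pd.Series:
    """Per-transcript 'expressed' indicator under the configured rule."""
    if rule == "mean_tpm":
        return tpm.mean(axis=1) > floor
    if rule == "any_sample_tpm":
        return (tpm > floor).any(axis=1)
    raise ValueError(f"unknown expressed_rule {rule!r}")


def summarize_dominance(
    usage: GeneUsage,
    matrix: pd.DataFrame,
    samples: pd.DataFrame | None,
    criteria: DominanceCriteria,
) -> pd.DataFrame:
    """Per-gene dominance summary table.

    Columns: gene_id, n_expressed_isoforms, top_isoform_id,
    top_isoform_mean_fraction, n_sample_dominant, n_group_dominant.
    ``n_group_dominant`` counts isoforms whose *within-group mean* usage
    exceeds the threshold in at least one group of ``criteria.group_key``
    (NaN when no grouping is requested).
    """
    theta = criteria.fraction_threshold
    groups = None
    if criteria.group_key is not None:
        if samples is None or criteria.group_key not in samples.columns:
            raise UnknownIdError(f"group key {criteria.group_key!r} not a sample column")
        groups = samples.loc[usage.fractions.columns, criteria.group_key]

    rows = []
    for gene, ann_g in usage.annotation.groupby("gene_id", sort=False):
        tx = ann_g.index
        frac = usage.fractions.loc[tx]
        tpm = matrix.loc[tx]
        if criteria.biotype_filter is not None:
            keep = ann_g["biotype"].isin(criteria.biotype_filter)
            if criteria.filter_denominator:
                sub = tpm.loc[keep[keep].index]
                denom = sub.sum(axis=0)
                frac = sub.div(denom, axis=1)
                frac.loc[:, denom <= usage.floor] = np.nan
                tpm = sub
            else:
                frac = frac.loc[keep[keep].index]
                tpm = tpm.loc[keep[keep].index]
            tx = frac.index
        if len(tx) == 0:
            continue

        expressed = _expressed_mask(tpm, criteria.expressed_rule, criteria.expressed_tpm_floor)
        sample_dominant = (frac > theta).any(axis=1)
        mean_frac = frac.mean(axis=1)
        # deterministic top isoform: highest mean fraction, lexicographic tie-break
        order = (
            mean_frac.fillna(-np.inf)
            .loc[sorted(mean_frac.index)]
            .sort_values(ascending=False, kind="stable")
        )
        top = order.index[0]
        if groups is not None:
            gm = frac.T.groupby(groups).mean().T  # tx × groups
            n_group = int((gm > theta).any(axis=1).sum())
        else:
            n_group = np.nan
        rows.append(
            {
                "gene_id": gene,
                "n_expressed_isoforms": int(expressed.sum()),
                "top_isoform_id": top,
                "top_isoform_mean_fraction": float(mean_frac.loc[top])
                if np.isfinite(mean_frac.loc[top])
                else np.nan,
                "n_sample_dominant": int(sample_dominant.sum()),
                "n_group_dominant": n_group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_expressed_isoforms",
            "top_isoform_id",
            "top_isoform_mean_fraction",
            "n_sample_dominant",
            "n_group_dominant",
        ],
    )


def recurrent_isoforms(
    usage: GeneUsage, matrix: pd.DataFrame, criteria: RecurrenceCriteria
) -> pd.DataFrame:
    """Transcripts recurrently carrying > θ_r of their gene across samples.

    A transcript qualifies iff the number of samples with usage strictly
    above ``fraction_threshold`` is at least ``min_samples`` and its mean
    TPM is at least ``mean_tpm_floor``. Undefined-usage samples never count.
    Returns a table (transcript_id, gene_id, n_qualifying_samples, mean_tpm)
    of qualifying transcripts.
    """
    frac = usage.fractions
    tpm = matrix.loc[frac.index]
    n_qual = (frac > criteria.fraction_threshold).sum(axis=1)
    mean_tpm = tpm.mean(axis=1)
    qualifies = (n_qual >= criteria.min_samples) & (mean_tpm >= criteria.mean_tpm_floor)
    out = pd.DataFrame(
        {
            "transcript_id": frac.index,
            "gene_id": usage.annotation["gene_id"].to_numpy(),
            "n_qualifying_samples": n_qual.to_numpy(),
            "mean_tpm": mean_tpm.to_numpy(),
        }
    )
    return out[qualifies.to_numpy()].reset_index(drop=True)


def pair_association(
    matrix: pd.DataFrame, tx_a: str, tx_b: str, transform: str = "identity"
) -> PairAssociation:
    """Best-fit line of transcript b on transcript a across samples.

    ``r_squared`` is the squared Pearson correlation; a zero-variance
    vector on either axis yields ``degenerate=True`` with r² reported as 0.
    """
    for tx in (tx_a, tx_b):
        if tx not in matrix.index:
            raise UnknownIdError(f"transcript {tx!r} not in matrix")
    a = matrix.loc[tx_a].to_numpy(dtype=float)
    b = matrix.loc[tx_b].to_numpy(dtype=float)
    if a.size < 3:
        raise InsufficientDataError(f"pair association needs >= 3 samples, got {a.size}")
    if transform == "log2p1":
        a, b = np.log2(a + 1.0), np.log2(b + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return PairAssociation(np.nan, np.nan, 0.0, a.size, True)
    res = stats.linregress(a, b)
    return PairAssociation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(a.size),
        degenerate=False,
    )


def gene_correlation(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "gene_sum",
    method: str = "spearman",
) -> pd.DataFrame:
    """Gene × gene expression correlation across samples.

    ``gene_sum`` sums member-transcript TPM per gene first; ``top_isoform``
    uses each gene's highest-mean-TPM transcript.
    """
    if matrix.shape[1] < 3:
        raise InsufficientDataError("gene correlation needs >= 3 samples")
    ann = annotation.loc[annotation.index.intersection(matrix.index)]
    if level == "gene_sum":
        profiles = matrix.loc[ann.index].groupby(ann["gene_id"], sort=False).sum()
    elif level == "top_isoform":
        top = (
            matrix.loc[ann.index]
            .mean(axis=1)
            .groupby(ann["gene_id"], sort=False)
            .idxmax()
        )
        profiles = matrix.loc[top]
        profiles.index = top.index
    else:
        raise ValueError(f"unknown level {level!r}")
    if profiles.shape[0] < 2:
        raise InsufficientDataError("gene correlation needs >= 2 genes")
    corr = profiles.T.corr(method=method)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr
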