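"""Two-group differential transcript analysis and cross-platform consensus.

The contrast statistic is a Welch unequal-variance t-test on
log2(TPM + 1); the fold change is the difference of group means on that
log scale (group1 minus group2). Multiple testing is controlled per
stratum with Benjamini-Hochberg. A consensus set across sequencing
platforms keeps the reference platform's significant transcripts whose
fold-change sign agrees (and is nonzero) on every other platform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UnknownIdError

logger = logging.getLogger("spliceome")

CONTRAST_COLUMNS = [
    "transcript_id",
    "stratum",
    "mean_log2_group1",
    "mean_log2_group2",
    "log2_fold_change",
    "t_statistic",
    "p_value",
    "q_value",
    "n_group1",
    "n_group2",
]


def _contrast_one(
    matrix: pd.DataFrame, cols1, cols2, min_mean_tpm: float, stratum: str
) -> pd.DataFrame:
    keep = matrix[list(cols1) + list(cols2)].mean(axis=1) >= min_mean_tpm
    sub = matrix.loc[keep]
    if sub.empty:
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    log1 = np.log2(sub[list(cols1)].to_numpy(dtype=float) + 1.0)
    log2_ = np.log2(sub[list(cols2)].to_numpy(dtype=float) + 1.0)
    m1, m2 = log1.mean(axis=1), log2_.mean(axis=1)
    t, p = stats.ttest_ind(log1, log2_, axis=1, equal_var=False)
    # identical zero-variance groups give nan; no evidence either way
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "transcript_id": sub.index,
            "stratum": stratum,
            "mean_log2_group1": m1,
            "mean_log2_group2": m2,
            "log2_fold_change": m1 - m2,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "n_group1": len(cols1),
            "n_group2": len(cols2),
        }
    ).reset_index(drop=True)


def differential_transcripts(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group_key: str,
    level1: str,
    level2: str,
    min_mean_tpm: float = 1.0,
    strata_key: str | None = None,
) -> pd.DataFrame:
    """Welch-t differential table of level1 vs level2 of ``group_key``.

    Transcripts whose overall mean TPM (both groups pooled, within the
    stratum) falls below ``min_mean_tpm`` are excluded before testing; BH
    q-values are computed across the tested transcripts within each
    stratum. Strata with fewer than 3 samples in either group are skipped
    with a log entry.
    """
    for key in filter(None, (group_key, strata_key)):
        if key not in samples.columns:
            raise UnknownIdError(f"{key!r} not a sample column")
    meta = samples.loc[samples.index.intersection(matrix.columns)]
    for level in (level1, level2):
        if not (meta[group_key] == level).any():
            raise UnknownIdError(f"level {level!r} absent from {group_key!r}")
    strata = [("all", meta)] if strata_key is None else list(meta.groupby(strata_key))
    pieces = []
    for name, sub in strata:
        cols1 = sub.index[sub[group_key] == level1]
        cols2 = sub.index[sub[group_key] == level2]
        if len(cols1) < 3 or len(cols2) < 3:
            if strata_key is None:
                raise InsufficientDataError(
                    f"each group needs >= 3 samples ({len(cols1)} vs {len(cols2)})"
                )
            logger.info("stratum %r skipped: %d vs %d samples", name, len(cols1), len(cols2))
            continue
        pieces.append(_contrast_one(matrix, cols1, cols2, min_mean_tpm, str(name)))
    if not pieces:
        raise InsufficientDataError("no stratum met the minimum group sizes")
    return pd.concat(pieces, ignore_index=True)


def sign_consistent_consensus(
    reference: pd.DataFrame, others: list[pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Reference-significant transcripts with platform-consistent fold-change sign.

    Membership: reference ``q_value < alpha`` AND ``log2_fold_change`` has
    the same nonzero sign in the reference and every other table.
    Transcripts missing from any table are excluded (inner join). Returns
    the member rows of the reference table plus one log2FC column per
    other platform.
    """
    ref = reference.set_index("transcript_id")
    other_fc = []
    common = ref.index
    for i, other in enumerate(others):
        o = other.set_index("transcript_id")["log2_fold_change"].rename(f"log2_fc_platform_{i + 1}")
        common = common.intersection(o.index)
        other_fc.append(o)
    if len(common) == 0:
        raise InsufficientDataError("no transcripts shared across all platforms")
    ref = ref.loc[common]
    signs = np.sign(ref["log2_fold_change"].to_numpy())
    member = (ref["q_value"].to_numpy() < alpha) & (signs != 0)
    for o in other_fc:
        member &= np.sign(o.loc[common].to_numpy()) == signs
    out = ref.loc[member].copy()
    for o in other_fc:
        out[o.name] = o.loc[out.index]
    return out.reset_index()
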