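"""Biotype composition of gene expression and library-prep effect testing.

For each gene and sample the share of the gene's TPM carried by each
transcript biotype class (protein-coding, NMD, retained intron, ...) is
expressed as a percentage closing to 100. PolyA selection depletes
unspliced and NMD-destined species relative to ribo-depleted total RNA, so
apparent composition shifts with library prep; the prep effect is tested
with a rank-based K-group (Kruskal-Wallis) test on per-sample mean shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UnknownIdError
from .io import BIOTYPES


def biotype_fractions(
    matrix: pd.DataFrame, annotation: pd.DataFrame, floor: float = 0.0
) -> pd.DataFrame:
    """Percent of each gene's expression per biotype class, per sample.

    Returns a DataFrame indexed by (gene_id, sample_id) with one column per
    biotype class; rows are NaN where the gene total is at or below the
    floor, and defined rows sum to 100.
    """
    ann = annotation.loc[annotation.index.intersection(matrix.index)]
    mat = matrix.loc[ann.index]
    gene_totals = mat.groupby(ann["gene_id"], sort=False).sum()
    key = [ann["gene_id"], ann["biotype"]]
    class_totals = mat.groupby(key, sort=False).sum()

    genes = gene_totals.index
    out = {}
    for bt in BIOTYPES:
        sub = class_totals.xs(bt, level=1, drop_level=True) if bt in class_totals.index.get_level_values(1) else None
        if sub is None:
            num = pd.DataFrame(0.0, index=genes, columns=mat.columns)
        else:
            num = sub.reindex(genes).fillna(0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * num.to_numpy() / gene_totals.to_numpy()
        pct[gene_totals.to_numpy() <= floor] = np.nan
        out[bt] = pd.DataFrame(pct, index=genes, columns=mat.columns).stack(future_stack=True)
    comp = pd.DataFrame(out)
    comp.index.names = ["gene_id", "sample_id"]
    return comp


def group_biotype_summary(
    comp: pd.DataFrame, samples: pd.DataFrame, group_key: str
) -> pd.DataFrame:
    """n / mean / median / quartiles of biotype percentages per group × gene × class.

    Undefined (NaN) composition entries are excluded; a cell with no
    defined entries reports n=0 with absent statistics.
    """
    if group_key not in samples.columns:
        raise UnknownIdError(f"group key {group_key!r} not a sample column")
    long = comp.stack(future_stack=True).rename("percent").reset_index()
    long.columns = ["gene_id", "sample_id", "biotype", "percent"]
    long["group"] = samples.loc[long["sample_id"], group_key].to_numpy()
    grouped = long.groupby(["group", "gene_id", "biotype"], sort=True)["percent"]
    summary = grouped.agg(
        n="count",
        mean="mean",
        median="median",
        q1=lambda v: v.quantile(0.25),
        q3=lambda v: v.quantile(0.75),
    ).reset_index()
    return summary


@dataclass
class PrepEffectResult:
    biotype: str
    group_means: dict
    statistic: float
    p_value: float
    n_per_group: dict


def prep_effect_test(
    comp: pd.DataFrame, samples: pd.DataFrame, biotype: str
) -> PrepEffectResult:
    """Kruskal-Wallis test of a biotype's per-sample mean share across library preps.

    The per-sample scalar is the unweighted mean across genes with defined
    composition of the biotype's percentage; groups are the distinct
    ``library_prep`` levels, each required to contribute >= 3 defined values.
    """
    if biotype not in comp.columns:
        raise UnknownIdError(f"unknown biotype class {biotype!r}")
    per_sample = comp[biotype].groupby(level="sample_id").mean()
    per_sample = per_sample.dropna()
    prep = samples.loc[per_sample.index, "library_prep"]
    groups = {lvl: per_sample[prep == lvl].to_numpy() for lvl in sorted(prep.unique())}
    groups = {lvl: v for lvl, v in groups.items() if v.size > 0}
    if len(groups) < 2 or any(v.size < 3 for v in groups.values()):
        raise InsufficientDataError(
            "prep effect test needs >= 2 library_prep levels with >= 3 values each"
        )
    values = list(groups.values())
    if np.ptp(np.concatenate(values)) == 0:
        h, p = 0.0, 1.0  # all observations identical: no rank separation
    else:
        h, p = stats.kruskal(*values)
    return PrepEffectResult(
        biotype=biotype,
        group_means={lvl: float(v.mean()) for lvl, v in groups.items()},
        statistic=float(h),
        p_value=float(p),
        n_per_group={lvl: int(v.size) for lvl, v in groups.items()},
    )
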