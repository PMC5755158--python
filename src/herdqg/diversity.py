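"""Alpha-diversity phenotypes: Shannon index, OTU richness, contemporary-group
pre-adjustment, and the enterotype diversity contrast.

The Shannon index is H = -sum_i p_i ln p_i (nats) over an individual sample's
OTU proportions; richness is the number of OTUs observed at the fixed rarefied
depth.  Before genetic analysis, post-weaning measurements are pre-adjusted
for contemporary group by removing group-mean deviations from the grand mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import OtuTable


class DiversityError(ValueError):
    pass


def shannon_index(counts: np.ndarray) -> float | np.ndarray:
    """Shannon entropy in nats of one count vector or a samples x OTUs matrix."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise DiversityError("negative counts")
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    else:
        squeeze = False
    totals = arr.sum(axis=1)
    if np.any(totals <= 0):
        raise DiversityError("sample with zero total count")
    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=1)
    return float(H[0]) if squeeze else H


def otu_richness(counts: np.ndarray) -> int | np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim == 1:
        return int(np.count_nonzero(arr))
    return (arr > 0).sum(axis=1)


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and OTU richness."""
    return pd.DataFrame(
        {
            "shannon": shannon_index(table.counts),
            "richness": otu_richness(table.counts),
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def pre_adjust_for_group(
    values: pd.Series, group: pd.Series
) -> pd.Series:
    """Remove group-mean deviations: value - group mean + grand mean.

    After adjustment every group mean equals the grand mean; the operation is
    idempotent and preserves the grand mean.  A singleton group's value maps
    exactly to the grand mean.
    """
    values = values.astype(float)
    if group.isna().any():
        raise DiversityError("missing group label")
    grand = values.mean()
    gm = values.groupby(group.to_numpy()).transform("mean")
    return values - gm + grand


def compare_enterotype_diversity(
    df: pd.DataFrame,
    value_col: str = "shannon",
    enterotype_col: str = "enterotype",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Welch two-sample t test of diversity between two enterotypes within sex.

    Returns one row per sex with group means/SDs, the t statistic, and p.
    Sexes where either enterotype has < 2 samples yield a missing result.
    """
    rows = []
    ets = sorted(df[enterotype_col].dropna().unique())
    if len(ets) != 2:
        raise DiversityError(f"expected exactly 2 enterotypes, got {ets}")
    for sex, sub in df.groupby(sex_col):
        a = sub.loc[sub[enterotype_col] == ets[0], value_col].dropna()
        b = sub.loc[sub[enterotype_col] == ets[1], value_col].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append((sex, len(a), len(b), np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            (sex, len(a), len(b), a.mean(), a.std(ddof=1), b.mean(),
             b.std(ddof=1), float(t), float(p))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sex", "n_1", "n_2", "mean_1", "sd_1", "mean_2", "sd_2", "t", "p",
        ],
    ).set_index("sex")
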