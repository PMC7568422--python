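"""Library-size normalization and per-condition mean expression.

Median-of-ratios size factors: each sample's factor is the median, over a
reference gene set, of the ratio of that sample's count to the gene's
geometric mean across samples.  The reference set is the rows with no
zero count (the geometric mean of a row containing a zero is zero and
its log undefined).  Normalized count = raw count / size factor;
condition means average normalized counts over the replicates of each
condition.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "median_ratio_size_factors",
    "normalized_counts",
    "condition_means",
]


def median_ratio_size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Per-sample median-of-ratios size factors.

    Parameters
    ----------
    counts
        Integer counts, genes in rows, samples in columns.
    allow_pseudo_reference
        When no gene has all-positive counts, fall back to using every
        row with a positive geometric mean of the positive entries.
        Off by default: the all-positive-row convention is the standard
        one and silently switching references changes the estimate.

    Returns
    -------
    pandas.Series of strictly positive factors indexed by sample.
    """
    x = counts.to_numpy(dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("counts must be a non-empty genes x samples matrix")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    reference = (x > 0).all(axis=1)
    if not reference.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene row has all-positive counts; re-run with "
                "allow_pseudo_reference=True to use positive entries only"
            )
        with np.errstate(divide="ignore"):
            logs = np.where(x > 0, np.log(x), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        reference = np.isfinite(log_geo)
        if not reference.any():
            raise ValueError("counts matrix is all zero")
        ratios = np.where(
            x[reference] > 0,
            x[reference] / np.exp(log_geo[reference])[:, None],
            np.nan,
        )
        factors = np.nanmedian(ratios, axis=0)
    else:
        log_geo = np.log(x[reference]).mean(axis=1)
        ratios = x[reference] / np.exp(log_geo)[:, None]
        factors = np.median(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("size factors are not all finite and positive")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return counts.div(factors.reindex(counts.columns), axis=1)


def condition_means(
    counts: pd.DataFrame,
    factors: pd.Series,
    condition_map: Mapping[str, str],
    condition_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene normalized mean count in each condition.

    mu_k(g) = mean over samples i of condition k of x_gi / l_i.

    Parameters
    ----------
    condition_map
        sample -> condition label for every column of ``counts``.
    condition_order
        Column order of the result; defaults to first-appearance order
        of conditions over the samples.
    """
    missing = [s for s in counts.columns if s not in condition_map]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    norm = normalized_counts(counts, factors)
    groups = norm.T.groupby([condition_map[s] for s in counts.columns])
    means = groups.mean().T
    if condition_order is None:
        seen: list[str] = []
        for s in counts.columns:
            if condition_map[s] not in seen:
                seen.append(condition_map[s])
        condition_order = seen
    empty = [c for c in condition_order if c not in means.columns]
    if empty:
        raise ValueError(f"conditions with zero samples: {empty}")
    return means[condition_order]
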