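"""Sucrose-gradient proteome fraction analysis.

A label-free quantification experiment yields a protein-by-fraction table of
non-normalized MS intensities (here a :class:`pandas.DataFrame` with protein
identifiers as index and ordered fraction labels as columns). Because the
protein composition of each gradient band is fundamentally different,
per-sample normalisation from the search engine is not applicable; instead
normalisation factors are derived from the summed raw intensity of each
fraction. A protein's distribution across the gradient then reads off where
it sediments, and strong enrichment in the PSI-LHC band (75-100% of the
total) marks it as a supercomplex component.

Missing values are treated as zero intensity (absence in the MS run).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["normalization_factors", "distribution", "enrichment_call"]


def _clean(table: pd.DataFrame) -> pd.DataFrame:
    if table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("need at least one protein and two fractions")
    table = table.fillna(0.0).astype(float)
    if (table.values < 0).any():
        raise ValueError("intensities must be non-negative")
    return table


def normalization_factors(table: pd.DataFrame) -> pd.Series:
    """Per-fraction factors equalising the summed raw intensities.

    factor_f = mean(all fraction totals) / total_f, so multiplying fraction
    *f* by its factor brings every fraction to the same total. The anchor
    (the mean) is a convention; it cancels in any per-protein distribution.
    """
    table = _clean(table)
    totals = table.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"fraction(s) with zero total intensity: {empty}")
    return totals.mean() / totals


def distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein share of normalized intensity in each fraction.

    Raw intensities are first rescaled by the per-fraction normalisation
    factors, then divided by each protein's row sum, so every row sums to 1.
    Proteins with all-zero intensities cannot be distributed; they are
    excluded and reported in ``result.attrs['excluded']``.
    """
    table = _clean(table)
    factors = normalization_factors(table)
    normalized = table * factors
    row_sums = normalized.sum(axis=1)
    excluded = list(row_sums.index[row_sums == 0])
    kept = normalized.loc[row_sums > 0]
    dist = kept.div(row_sums[row_sums > 0], axis=0)
    dist.attrs["excluded"] = excluded
    return dist


def enrichment_call(
    dist: pd.DataFrame, target_fraction: str, threshold: float = 0.75
) -> pd.Series:
    """Flag proteins strongly enriched in one gradient fraction.

    True where the protein carries at least ``threshold`` of its total
    (normalized) intensity in ``target_fraction``; the default 0.75 matches
    the 75-100% criterion used to call PSI-LHC supercomplex components.
    """
    if target_fraction not in dist.columns:
        raise KeyError(
            f"unknown fraction {target_fraction!r}; have {list(dist.columns)}"
        )
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if threshold == 0.0:
        return dist[target_fraction] > 0.0
    return dist[target_fraction] >= threshold
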