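"""HPLC pigment quantification and stoichiometry.

Integrated chromatogram peak areas are converted to molar amounts through
per-pigment response factors (area per mol) and expressed relative to the
chlorophyll a content as mol per 100 Chl.  Vaucheriaxanthin, for which no
pure standard is commonly available, borrows the violaxanthin response
factor with a 10% correction for its different absorption spectrum.  The
Chl:Car ratio is 100 divided by the summed carotenoid content per 100 Chl.

Contents reported only as upper bounds (e.g. "< 1 mol per 100 Chl") are
carried as :class:`~psitrap.types.Censored` values; a stoichiometry computed
from censored entries is returned as an interval rather than a point.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .types import Censored

__all__ = ["vaucheriaxanthin_rf", "quantify", "chl_car_ratio", "CHL_NAMES"]

CHL_NAMES = ("chlorophyll-a", "chlorophyll a", "chl a", "chl-a", "chla")


def vaucheriaxanthin_rf(viola_rf: float, correction: float = 0.10) -> float:
    """Vaucheriaxanthin response factor estimated from violaxanthin's.

    Applies a fractional correction for the different absorption spectrum:
    ``viola_rf * (1 + correction)``. The sign of ``correction`` is
    configurable; pass a negative value to lower the factor instead.
    """
    if viola_rf <= 0:
        raise ValueError(f"violaxanthin response factor must be positive, got {viola_rf}")
    return viola_rf * (1.0 + correction)


def _is_chl(name: str) -> bool:
    return name.strip().lower() in CHL_NAMES


def quantify(
    areas: Mapping[str, float] | pd.DataFrame,
    response_factors: Mapping[str, float] | None = None,
    chl_area: float | None = None,
    chl_rf: float | None = None,
) -> pd.DataFrame:
    """Convert peak areas to mol per 100 Chl a.

    ``areas`` is either a mapping pigment -> area together with
    ``response_factors``, ``chl_area`` and ``chl_rf``, or a table with
    columns (pigment, area, response_factor) containing a chlorophyll-a row
    that serves as the reference. Returns the table with a ``mol_per_100chl``
    column (the chlorophyll row reads 100 by construction).
    """
    if isinstance(areas, pd.DataFrame):
        table = areas.copy()
        required = {"pigment", "area", "response_factor"}
        if not required.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        chl_rows = table[table["pigment"].map(_is_chl)]
        if chl_rows.empty:
            raise ValueError("table contains no chlorophyll-a reference row")
        chl_area = float(chl_rows["area"].iloc[0])
        chl_rf = float(chl_rows["response_factor"].iloc[0])
    else:
        if response_factors is None or chl_area is None or chl_rf is None:
            raise ValueError(
                "mapping input requires response_factors, chl_area and chl_rf"
            )
        table = pd.DataFrame(
            {
                "pigment": list(areas.keys()),
                "area": list(areas.values()),
                "response_factor": [response_factors[p] for p in areas],
            }
        )
    if chl_area <= 0:
        raise ValueError("chlorophyll reference area must be positive")
    if chl_rf <= 0:
        raise ValueError("chlorophyll response factor must be positive")
    if (table["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    if (table["response_factor"] <= 0).any():
        raise ValueError("response factors must be positive")
    chl_mol = chl_area / chl_rf
    table = table.reset_index(drop=True)
    table["mol_per_100chl"] = (
        100.0 * (table["area"] / table["response_factor"]) / chl_mol
    )
    return table


def _carotenoid_contents(quant) -> list:
    if isinstance(quant, pd.DataFrame):
        rows = quant[~quant["pigment"].map(_is_chl)]
        return list(rows["mol_per_100chl"])
    return [v for name, v in quant.items() if not _is_chl(name)]


def chl_car_ratio(quant: pd.DataFrame | Mapping) -> float | tuple:
    """Chlorophyll-to-carotenoid molar ratio: 100 / sum of carotenoid contents.

    ``quant`` is a quantification table (or a mapping pigment ->
    mol per 100 Chl); chlorophyll rows are excluded from the sum. Entries
    that are :class:`Censored` upper bounds make the total uncertain, so the
    ratio is then returned as a ``(low, high)`` interval.
    """
    contents = _carotenoid_contents(quant)
    if not contents:
        raise ValueError("no carotenoid entries found")
    point = sum(c for c in contents if not isinstance(c, Censored))
    censored_upper = sum(c.upper for c in contents if isinstance(c, Censored))
    if any(not isinstance(c, Censored) and c < 0 for c in contents):
        raise ValueError("carotenoid contents must be non-negative")
    if censored_upper == 0:
        if point <= 0:
            raise ValueError("total carotenoid content is zero")
        return 100.0 / point
    if point <= 0:
        raise ValueError("all carotenoid contents are censored or zero")
    return (100.0 / (point + censored_upper), 100.0 / point)
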