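"""Steady-state spectral operations.

Covers the conventions used when comparing photosystem preparations:
normalisation (to the peak, to the Qy peak, or to the integrated red tail
beyond a threshold wavelength), difference spectra, band detection through
the smoothed second derivative (Savitzky-Golay), and sub-grid emission
maxima. Chlorophyll Qy sub-bands that overlap in the raw absorption show up
as resolved minima of the second derivative, which is why band positions are
read off d2A/d(lambda)2 rather than the spectrum itself.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from .types import BandList, SpectrumRecord

__all__ = [
    "normalize",
    "difference",
    "second_derivative_bands",
    "emission_maximum",
]

QY_RANGE = (620.0, 720.0)  # nm, lowest-energy Chl a absorption region


def normalize(
    spec: SpectrumRecord, mode: str = "max", threshold: float = 705.0
) -> SpectrumRecord:
    """Rescale a spectrum by one of the standard conventions.

    ``max``      : global maximum scaled to 1.
    ``qy_max``   : maximum within the Qy region (620-720 nm) scaled to 1.
    ``red_tail`` : integral from ``threshold`` nm to the end of the grid
                   scaled to 1 (used to compare spectra per red-form content).
    """
    wl, values = spec.wavelengths, spec.values
    if mode == "max":
        scale = np.max(values)
    elif mode == "qy_max":
        mask = (wl >= QY_RANGE[0]) & (wl <= QY_RANGE[1])
        if not mask.any():
            raise ValueError("grid does not cover the Qy region")
        scale = np.max(values[mask])
    elif mode == "red_tail":
        if threshold >= wl[-1]:
            raise ValueError(
                f"red-tail threshold {threshold} nm beyond grid end {wl[-1]} nm"
            )
        mask = wl >= threshold
        scale = np.trapezoid(values[mask], wl[mask])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if scale == 0:
        raise ValueError("cannot normalize a zero spectrum")
    return spec.copy_with(
        values=values / scale,
        metadata={**spec.metadata, "normalization": mode},
    )


def difference(a: SpectrumRecord, b: SpectrumRecord) -> SpectrumRecord:
    """Pointwise a - b on a's grid, with b linearly interpolated.

    Restricted to the overlap of the two wavelength ranges; disjoint ranges
    are an error.
    """
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectra have no overlapping wavelength range")
    mask = (a.wavelengths >= lo) & (a.wavelengths <= hi)
    wl = a.wavelengths[mask]
    b_interp = np.interp(wl, b.wavelengths, b.values)
    return SpectrumRecord(
        wavelengths=wl,
        values=a.values[mask] - b_interp,
        kind=a.kind,
        temperature=a.temperature,
        metadata={"operation": "difference"},
    )


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple:
    """Sub-grid extremum position/value from a parabola through 3 points."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + delta * step), float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)


def second_derivative_bands(
    spec: SpectrumRecord,
    window: int = 11,
    polyorder: int = 3,
    min_depth: float = 0.05,
) -> BandList:
    """Detect absorption bands as minima of the smoothed second derivative.

    The spectrum is smoothed and differentiated in one Savitzky-Golay pass;
    local minima of the second derivative that are negative and at least
    ``min_depth`` times as deep as the deepest minimum are reported, with
    parabolic sub-grid interpolation of their positions. Requires a uniform
    wavelength grid (non-uniform grids are resampled).
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window <= polyorder:
        raise ValueError("smoothing window must exceed the polynomial order")
    wl, values = spec.wavelengths, spec.values
    if wl.size <= window:
        raise ValueError("spectrum shorter than the smoothing window")
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        wl_u = np.linspace(wl[0], wl[-1], wl.size)
        values = np.interp(wl_u, wl, values)
        wl = wl_u
    delta = float(wl[1] - wl[0])
    d2 = savgol_filter(values, window, polyorder, deriv=2, delta=delta)

    interior = np.arange(1, wl.size - 1)
    is_min = (d2[interior] < d2[interior - 1]) & (d2[interior] <= d2[interior + 1])
    candidates = interior[is_min & (d2[interior] < 0)]
    if candidates.size == 0:
        return BandList(positions=np.array([]), depths=np.array([]))
    deepest = np.min(d2[candidates])
    positions, depths = [], []
    for i in candidates:
        if d2[i] <= min_depth * deepest:  # both negative: depth cutoff
            pos, val = _parabolic_refine(wl, d2, i)
            positions.append(pos)
            depths.append(-val)
    order = np.argsort(positions)
    return BandList(
        positions=np.asarray(positions)[order], depths=np.asarray(depths)[order]
    )


def emission_maximum(
    spec: SpectrumRecord, search_range: tuple = (640.0, 800.0)
) -> float:
    """Position (nm) of the emission maximum within a wavelength range.

    The argmax is refined by parabolic interpolation through the three grid
    points around the discrete maximum. A maximum on the boundary of the
    search range (monotone spectrum) is returned as-is with a warning.
    """
    lo, hi = search_range
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not mask.any():
        raise ValueError("search range does not overlap the wavelength grid")
    wl, values = spec.wavelengths[mask], spec.values[mask]
    i = int(np.argmax(values))
    if i == 0 or i == wl.size - 1:
        warnings.warn(
            "emission maximum lies on the boundary of the search range",
            stacklevel=2,
        )
        return float(wl[i])
    pos, _ = _parabolic_refine(wl, values, i)
    return pos
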