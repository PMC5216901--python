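"""Shared containers for time-resolved images, spectra and fit results."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: center ``mu`` (ps) and width ``sigma`` (ps).

    Streak-camera temporal responses are usually quoted as FWHM; use
    :meth:`from_fwhm` when constructing from such numbers.
    """

    center: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"IRF sigma must be >= 0, got {self.sigma}")

    @classmethod
    def from_fwhm(cls, center: float, fwhm: float) -> "IRFModel":
        return cls(center=center, sigma=fwhm * FWHM_TO_SIGMA)

    @property
    def fwhm(self) -> float:
        return self.sigma / FWHM_TO_SIGMA


@dataclass
class TimeResolvedImage:
    """Fluorescence intensity on a (time ps x wavelength nm) grid.

    ``times`` and ``wavelengths`` must be strictly increasing; ``intensity``
    has shape ``(len(times), len(wavelengths))``. ``irf`` describes the
    Gaussian temporal response of the time range the image was recorded in.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    intensity: np.ndarray
    irf: IRFModel = field(default_factory=IRFModel)
    time_range: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size == 0 or self.wavelengths.size == 0:
            raise ValueError("time and wavelength grids must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.intensity.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({self.times.size}, {self.wavelengths.size})"
            )


@dataclass
class SpectrumRecord:
    """A steady-state spectrum: wavelength grid (nm) plus values.

    ``kind`` is one of ``absorption``, ``emission`` or ``cd``;
    ``temperature`` is in kelvin.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorption"
    temperature: float = 295.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def copy_with(self, **changes) -> "SpectrumRecord":
        return dataclasses.replace(self, **changes)


@dataclass
class BandList:
    """Detected absorption bands: positions (nm, ascending) and second-derivative depths."""

    positions: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("band positions must be sorted ascending")

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class KineticFitResult:
    """Result of a global (shared-lifetime) fit of one or more streak images.

    ``lifetimes`` are sorted ascending; ``das[n]`` is the decay-associated
    spectrum of component *n* on ``wavelengths``; ``scales`` holds one factor
    per fitted image.
    """

    lifetimes: np.ndarray
    fixed: np.ndarray
    das: np.ndarray
    wavelengths: np.ndarray
    scales: np.ndarray
    rms: float
    n_images: int
    cost: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        self.das = np.asarray(self.das, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(np.diff(self.lifetimes) < 0):
            raise ValueError("lifetimes must be sorted ascending")
        if self.rms < 0:
            raise ValueError("rms must be >= 0")

    @property
    def n_components(self) -> int:
        return self.lifetimes.size

    def normalized_das(self) -> np.ndarray:
        """DAS rescaled so the total t=0 amplitude across components is 1.

        This mirrors the convention of normalising decay-associated spectra
        to the initial population of excited states.
        """
        total = float(np.trapezoid(self.das.sum(axis=0), self.wavelengths))
        if total == 0:
            raise ValueError("total initial amplitude is zero")
        return self.das / total


@dataclass
class ComponentClassification:
    """Per-component connected/disconnected labels with the rule that produced them."""

    labels: tuple
    lifetime_threshold: float

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in ("connected", "disconnected"):
                raise ValueError(f"unknown label {lab!r}")

    @property
    def connected_indices(self) -> tuple:
        return tuple(i for i, lab in enumerate(self.labels) if lab == "connected")


@dataclass(frozen=True)
class Censored:
    """A left-censored quantity known only to lie in (0, upper]."""

    upper: float

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError("censoring bound must be positive")


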