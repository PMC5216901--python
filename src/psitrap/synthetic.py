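"""Synthetic emulation of every input the analysis pipeline consumes.

Stands in for the instruments: a streak camera recording time-resolved
fluorescence of a photosystem I supercomplex (PSI-LHC), a UV-Vis
spectrophotometer (77 K absorption with four Qy sub-bands), a
spectrofluorimeter (77 K emission dominated by the 722 nm red-form band), a
sucrose-gradient proteomics experiment (protein-by-fraction intensity
tables) and an HPLC pigment quantification (peak areas with response
factors).

Defaults reproduce the measured PSI-LHC kinetics of *Nannochloropsis
gaditana*: four decay components with lifetimes 10.5 ps, 45.5 ps, 1.7 ns and
6 ns (the slowest being free chlorophyll a) carrying signed decay-associated
spectra whose areas split 33.1 / 48.9 / 11 / 7 percent of the initial
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import exp_conv_gauss
from .types import FWHM_TO_SIGMA, IRFModel, SpectrumRecord, TimeResolvedImage

__all__ = [
    "KineticGroundTruth",
    "FractionArchetype",
    "gen_streak",
    "gen_streak_set",
    "gen_absorption",
    "gen_emission",
    "gen_fraction_table",
    "gen_pigment_areas",
    "default_time_grid",
    "default_wavelength_grid",
    "default_archetypes",
    "QY_BANDS_77K",
    "ALPHA_DM_PIGMENTS",
]

# 77 K Qy absorption sub-bands: (center nm, sigma nm, amplitude).
# Band widths 6-9 nm FWHM (sigma = FWHM/2.355), typical of low-temperature
# chlorophyll a sub-bands.
QY_BANDS_77K: tuple = (
    (669.0, 6.0 * FWHM_TO_SIGMA, 0.60),
    (679.5, 7.0 * FWHM_TO_SIGMA, 1.00),
    (685.0, 7.0 * FWHM_TO_SIGMA, 0.80),
    (697.5, 9.0 * FWHM_TO_SIGMA, 0.35),
)

# Carotenoid content of the alpha-DM PSI-LHC preparation, mol per 100 Chl a.
ALPHA_DM_PIGMENTS: dict = {
    "violaxanthin": 14.5,
    "vaucheriaxanthin": 2.3,
    "anteraxanthin": 2.1,
    "zeaxanthin": 2.5,
    "beta-carotene": 10.2,
}

# Streak-camera time ranges: (tag, length ps, temporal response FWHM ps).
# The instrument numbers its ranges TR1/TR2/TR4.
TIME_RANGES: tuple = (("TR1", 155.0, 4.5), ("TR2", 400.0, 6.5), ("TR4", 1500.0, 20.0))


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass(frozen=True)
class KineticGroundTruth:
    """Ground truth for a multiexponential streak image.

    ``das_bands[n]`` is a band mixture ``(center nm, sigma nm, signed area)``
    defining the decay-associated spectrum of component *n*; each band
    contributes a Gaussian whose integral over wavelength equals its signed
    area, so the configured areas double as relative amplitudes.
    ``irf_fwhm`` holds one Gaussian FWHM (ps) per time range; set
    ``irf_width_is_sigma`` if the widths are standard deviations instead.
    """

    lifetimes: tuple = (10.5, 45.5, 1700.0, 6000.0)
    das_bands: tuple = (
        ((685.0, 13.0, 33.1),),
        ((688.0, 13.0, 48.9),),
        ((680.0, 11.0, 11.0),),
        ((675.0, 9.0, 7.0),),
    )
    irf_center: float = 10.0
    irf_fwhm: tuple = (4.5, 6.5, 20.0)
    irf_width_is_sigma: bool = False
    noise_scale: float = 0.005

    def __post_init__(self) -> None:
        taus = np.asarray(self.lifetimes, dtype=float)
        if taus.size == 0:
            raise ValueError("at least one kinetic component required")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be strictly positive")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("lifetimes must be strictly increasing")
        if len(self.das_bands) != taus.size:
            raise ValueError("one band mixture required per component")
        for bands in self.das_bands:
            for center, width, _amp in bands:
                if width <= 0:
                    raise ValueError(f"band width must be positive, got {width}")
        if any(w < 0 for w in self.irf_fwhm):
            raise ValueError("IRF widths must be non-negative")

    @classmethod
    def alpha_dm(cls) -> "KineticGroundTruth":
        """PSI-LHC purified with alpha-DM (the default)."""
        return cls()

    @classmethod
    def beta_dm(cls) -> "KineticGroundTruth":
        """PSI-LHC purified with beta-DM: same scheme, slightly slower tau1."""
        return cls(
            lifetimes=(13.0, 45.1, 1600.0, 6000.0),
            das_bands=(
                ((685.0, 13.0, 35.5),),
                ((688.0, 13.0, 52.0),),
                ((680.0, 11.0, 6.3),),
                ((675.0, 9.0, 6.2),),
            ),
        )

    def irf_sigma(self, time_range: int) -> float:
        width = self.irf_fwhm[time_range]
        return width if self.irf_width_is_sigma else width * FWHM_TO_SIGMA

    def das_matrix(self, wavelengths: np.ndarray) -> np.ndarray:
        """Evaluate the per-component DAS on a wavelength grid, shape (n, n_wl)."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        das = np.zeros((len(self.lifetimes), wavelengths.size))
        for n, bands in enumerate(self.das_bands):
            for center, sigma, area in bands:
                # unit-area Gaussian scaled to the signed band area
                das[n] += area / (sigma * np.sqrt(2 * np.pi)) * _gauss(
                    wavelengths, center, sigma
                )
        return das


def default_time_grid(time_range: int, n_points: int = 256) -> np.ndarray:
    """Time grid (ps) for one of the three streak time ranges."""
    _, length, _ = TIME_RANGES[time_range]
    return np.linspace(0.0, length, n_points)


def default_wavelength_grid(step: float = 5.0) -> np.ndarray:
    """Detection wavelength grid, 590-860 nm."""
    return np.arange(590.0, 860.0 + 0.5 * step, step)


def gen_streak(
    truth: KineticGroundTruth,
    time_grid: np.ndarray,
    wavelength_grid: np.ndarray,
    seed: int,
    time_range: int = 0,
) -> TimeResolvedImage:
    """Simulate one streak image.

    The noise-free signal is ``sum_n DAS_n(lambda) * (exp(-t/tau_n) (x) IRF)``;
    noise is Gaussian with variance proportional to the local signal plus a
    small floor, approximating photon statistics after camera gain. The same
    seed always yields the identical image.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    wavelength_grid = np.asarray(wavelength_grid, dtype=float)
    if time_grid.size == 0 or wavelength_grid.size == 0:
        raise ValueError("time and wavelength grids must be non-empty")
    if np.any(np.diff(time_grid) <= 0) or np.any(np.diff(wavelength_grid) <= 0):
        raise ValueError("grids must be strictly increasing")

    sigma = truth.irf_sigma(time_range)
    das = truth.das_matrix(wavelength_grid)
    basis = np.column_stack(
        [exp_conv_gauss(time_grid, tau, truth.irf_center, sigma) for tau in truth.lifetimes]
    )
    clean = basis @ das
    if truth.noise_scale > 0:
        rng = np.random.default_rng(seed)
        peak = float(np.max(np.abs(clean)))
        var = truth.noise_scale**2 * peak * (np.clip(clean, 0, None) + 1e-3 * peak)
        clean = clean + rng.standard_normal(clean.shape) * np.sqrt(var)
    return TimeResolvedImage(
        times=time_grid,
        wavelengths=wavelength_grid,
        intensity=clean,
        irf=IRFModel(center=truth.irf_center, sigma=sigma),
        time_range=TIME_RANGES[time_range][0],
        metadata={"seed": int(seed), "lifetimes_true": list(truth.lifetimes)},
    )


def gen_streak_set(
    truth: KineticGroundTruth,
    seed: int,
    n_time_points: int = 256,
    wavelength_step: float = 5.0,
) -> list:
    """The standard measurement: one image per streak time range."""
    wl = default_wavelength_grid(wavelength_step)
    return [
        gen_streak(truth, default_time_grid(tr, n_time_points), wl, seed + tr, time_range=tr)
        for tr in range(len(TIME_RANGES))
    ]


def gen_absorption(
    bands: Sequence[tuple],
    wavelength_grid: np.ndarray,
    temperature: float = 77.0,
) -> SpectrumRecord:
    """Absorption spectrum as a sum of Gaussian bands (center, sigma, amplitude)."""
    if len(bands) == 0:
        raise ValueError("at least one band required")
    wavelength_grid = np.asarray(wavelength_grid, dtype=float)
    values = np.zeros_like(wavelength_grid)
    for center, sigma, amp in bands:
        if sigma <= 0:
            raise ValueError(f"band width must be positive, got {sigma}")
        values += amp * _gauss(wavelength_grid, center, sigma)
    return SpectrumRecord(
        wavelengths=wavelength_grid,
        values=values,
        kind="absorption",
        temperature=temperature,
        metadata={"band_centers": [b[0] for b in bands]},
    )


def gen_emission(
    red_form_center: float = 722.0,
    free_chl_center: float = 678.0,
    free_chl_fraction: float = 0.1,
    wavelength_grid: np.ndarray | None = None,
    red_form_sigma: float = 12.0,
    free_chl_sigma: float = 8.0,
    temperature: float = 77.0,
) -> SpectrumRecord:
    """77 K emission: dominant red-form band plus a free-chlorophyll band.

    ``free_chl_fraction`` is the fraction of the total band area carried by
    the free-chlorophyll (non-transferring) band.
    """
    if not 0.0 <= free_chl_fraction <= 1.0:
        raise ValueError(
            f"free_chl_fraction must lie in [0, 1], got {free_chl_fraction}"
        )
    if wavelength_grid is None:
        wavelength_grid = np.arange(640.0, 800.0 + 0.25, 0.5)
    wavelength_grid = np.asarray(wavelength_grid, dtype=float)
    red = _gauss(wavelength_grid, red_form_center, red_form_sigma) / red_form_sigma
    free = _gauss(wavelength_grid, free_chl_center, free_chl_sigma) / free_chl_sigma
    values = (1.0 - free_chl_fraction) * red + free_chl_fraction * free
    return SpectrumRecord(
        wavelengths=wavelength_grid,
        values=values,
        kind="emission",
        temperature=temperature,
        metadata={
            "red_form_center": red_form_center,
            "free_chl_center": free_chl_center,
            "free_chl_fraction": free_chl_fraction,
        },
    )


@dataclass(frozen=True)
class FractionArchetype:
    """Expected distribution of a protein class across gradient fractions.

    ``profile`` gives each fraction's expected share of a member protein's
    total intensity (non-negative, sums to 1); ``dispersion`` is the sigma of
    the multiplicative log-normal noise applied per cell.
    """

    name: str
    profile: tuple
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        prof = np.asarray(self.profile, dtype=float)
        if np.any(prof < 0):
            raise ValueError("profile shares must be non-negative")
        if abs(prof.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile must sum to 1, got {prof.sum()}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


GRADIENT_FRACTIONS: tuple = ("LHC monomers", "LHC trimers", "PSII core", "PSI-LHC")


def default_archetypes() -> list:
    """Protein archetypes emulating a whole-gradient proteome.

    PSI-core and PSI-antenna proteins sediment almost entirely in the
    PSI-LHC band; the remaining archetypes populate the other bands (free
    LHC monomers/trimers, the PSII core) or spread across several, as the
    bulk of a thylakoid proteome does. Covering every band matters: the
    per-fraction normalisation divides by summed intensities, so a gradient
    in which only the PSI band carried protein would distort all shares.
    """
    return [
        FractionArchetype("PSI-core", (0.02, 0.03, 0.05, 0.90)),
        FractionArchetype("PSI-antenna", (0.04, 0.04, 0.04, 0.88)),
        FractionArchetype("LHC-monomer", (0.85, 0.05, 0.05, 0.05)),
        FractionArchetype("LHC-trimer", (0.05, 0.85, 0.05, 0.05)),
        FractionArchetype("PSII-core", (0.05, 0.05, 0.85, 0.05)),
        FractionArchetype("mixed", (0.35, 0.35, 0.25, 0.05)),
    ]


def gen_fraction_table(
    archetypes: Sequence[FractionArchetype],
    n_proteins_per_archetype: int,
    seed: int,
    fractions: Sequence[str] = GRADIENT_FRACTIONS,
    base_intensity: float = 1e9,
) -> pd.DataFrame:
    """Protein-by-fraction non-normalized intensity table.

    Each protein draws a log-normal total intensity, split across fractions
    according to its archetype profile with per-cell multiplicative
    log-normal noise (mean-one). Rows are labelled ``<archetype>_<i>``; the
    archetype name is recoverable from the row label for benchmarking.
    """
    if len(archetypes) == 0:
        raise ValueError("at least one archetype required")
    if n_proteins_per_archetype < 1:
        raise ValueError("need at least one protein per archetype")
    for arch in archetypes:
        if len(arch.profile) != len(fractions):
            raise ValueError(
                f"archetype {arch.name!r} profile length {len(arch.profile)} "
                f"!= number of fractions {len(fractions)}"
            )
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for arch in archetypes:
        prof = np.asarray(arch.profile, dtype=float)
        for i in range(n_proteins_per_archetype):
            total = base_intensity * rng.lognormal(mean=0.0, sigma=1.0)
            if arch.dispersion > 0:
                noise = rng.lognormal(
                    mean=-0.5 * arch.dispersion**2,
                    sigma=arch.dispersion,
                    size=prof.size,
                )
            else:
                noise = np.ones(prof.size)
            rows.append(total * prof * noise)
            index.append(f"{arch.name}_{i}")
    return pd.DataFrame(rows, index=index, columns=list(fractions))


def gen_pigment_areas(
    target_mol_per_100chl: Mapping[str, float],
    response_factors: Mapping[str, float],
    chl_area: float = 1e6,
    chl_rf: float = 1000.0,
) -> pd.DataFrame:
    """Invert pigment quantification: peak areas realising target contents.

    Returns a table (pigment, area, response_factor) including the Chl a
    reference row, such that quantifying it recovers
    ``target_mol_per_100chl`` exactly.
    """
    if chl_area <= 0 or chl_rf <= 0:
        raise ValueError("Chl reference area and response factor must be positive")
    chl_mol = chl_area / chl_rf
    records = [{"pigment": "chlorophyll-a", "area": chl_area, "response_factor": chl_rf}]
    for pigment, target in target_mol_per_100chl.items():
        rf = response_factors[pigment]
        if rf <= 0:
            raise ValueError(f"response factor for {pigment!r} must be positive")
        if target < 0:
            raise ValueError(f"target content for {pigment!r} must be >= 0")
        records.append(
            {
                "pigment": pigment,
                "area": target / 100.0 * chl_mol * rf,
                "response_factor": rf,
            }
        )
    return pd.DataFrame.from_records(records)
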