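"""Configuration-driven pipeline tying the analysis stages together.

A run is described by a YAML/dict config: a seed, an output directory, the
ordered list of stages to execute and one parameter block per stage. The
``simulate`` stage writes every synthetic fixture; downstream stages either
consume explicit input paths or fall back to the fixtures produced earlier
in the same run. All randomness flows from the single config seed, so a
rerun with the same config is reproducible.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, fractions as fractions_mod, io, pigments as pigments_mod
from . import spectra as spectra_mod, synthetic
from .globalfit import (
    average_decay_time,
    classify_components,
    fit_global,
    relative_amplitudes,
)
__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULT_STAGES = ("simulate", "fit", "spectra", "fractions", "pigments")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("psitrap_out")
    stages: tuple = DEFAULT_STAGES
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    pigments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _stage_simulate(config: PipelineConfig, report: dict) -> dict:
    params = config.simulate
    sample = params.get("sample", "alpha")
    truth = (
        synthetic.KineticGroundTruth.beta_dm()
        if sample == "beta"
        else synthetic.KineticGroundTruth.alpha_dm()
    )
    out = config.outdir
    outputs = {}
    images = synthetic.gen_streak_set(
        truth,
        config.seed,
        n_time_points=params.get("n_time_points", 256),
        wavelength_step=params.get("wavelength_step", 5.0),
    )
    image_paths = []
    for image in images:
        p = io.write_time_resolved(image, out / f"streak_{image.time_range}.csv")
        image_paths.append(str(p))
    outputs["streak_images"] = image_paths

    absorption = synthetic.gen_absorption(
        synthetic.QY_BANDS_77K, np.arange(600.0, 750.0 + 0.25, 0.5)
    )
    outputs["absorption"] = str(io.write_spectrum(absorption, out / "absorption_77K.tsv"))
    emission = synthetic.gen_emission()
    outputs["emission"] = str(io.write_spectrum(emission, out / "emission_77K.tsv"))

    table = synthetic.gen_fraction_table(
        synthetic.default_archetypes(),
        params.get("n_proteins_per_archetype", 30),
        config.seed,
    )
    outputs["fraction_table"] = str(io.write_table(table, out / "fraction_intensities.tsv"))

    rfs = {name: 1000.0 for name in synthetic.ALPHA_DM_PIGMENTS}
    rfs["vaucheriaxanthin"] = pigments_mod.vaucheriaxanthin_rf(rfs["violaxanthin"])
    areas = synthetic.gen_pigment_areas(synthetic.ALPHA_DM_PIGMENTS, rfs)
    outputs["pigment_areas"] = str(
        io.write_table(areas, out / "pigment_areas.tsv", index=False)
    )
    return outputs


def _stage_fit(config: PipelineConfig, report: dict) -> dict:
    params = config.fit
    paths = params.get("images")
    if not paths:
        paths = report["stages"].get("simulate", {}).get("streak_images")
    if not paths:
        raise ValueError("fit stage needs input images (config or simulate stage)")
    images = [io.read_time_resolved(p) for p in paths]
    n = params.get("n_components", 4)
    fixed = []
    if params.get("fix_slowest") is not None:
        fixed = [(n - 1, float(params["fix_slowest"]))]
    fit = fit_global(
        images,
        n,
        init_lifetimes=params.get("init_lifetimes"),
        fixed=fixed,
        seed=config.seed,
    )
    classification = classify_components(
        fit, params.get("lifetime_threshold", 1000.0)
    )
    shares = relative_amplitudes(fit)
    tau_av = average_decay_time(fit, classification.connected_indices)
    das_path = config.outdir / "das.tsv"
    import pandas as pd

    das_table = pd.DataFrame(
        fit.das.T,
        index=pd.Index(fit.wavelengths, name="wavelength_nm"),
        columns=[f"DAS_{i + 1}" for i in range(fit.n_components)],
    )
    io.write_table(das_table, das_path)
    result = {
        "lifetimes_ps": [float(t) for t in fit.lifetimes],
        "fixed": [bool(f) for f in fit.fixed],
        "relative_amplitudes_percent": [float(100 * s) for s in shares],
        "labels": list(classification.labels),
        "average_decay_time_ps": float(tau_av),
        "rms": float(fit.rms),
        "das_table": str(das_path),
    }
    io.write_json(result, config.outdir / "fit.json")
    return result


def _stage_spectra(config: PipelineConfig, report: dict) -> dict:
    params = config.spectra
    path = params.get("absorption") or report["stages"].get("simulate", {}).get(
        "absorption"
    )
    if not path:
        raise ValueError("spectra stage needs an absorption spectrum")
    spec = io.read_spectrum(path)
    bands = spectra_mod.second_derivative_bands(
        spec,
        window=params.get("window", 11),
        polyorder=params.get("polyorder", 3),
        min_depth=params.get("min_depth", 0.05),
    )
    result = {
        "band_positions_nm": [float(p) for p in bands.positions],
        "band_depths": [float(d) for d in bands.depths],
    }
    emission_path = params.get("emission") or report["stages"].get(
        "simulate", {}
    ).get("emission")
    if emission_path:
        emission = io.read_spectrum(emission_path)
        result["emission_maximum_nm"] = float(
            spectra_mod.emission_maximum(emission, params.get("emission_range", (700.0, 780.0)))
        )
    io.write_json(result, config.outdir / "spectra.json")
    return result


def _stage_fractions(config: PipelineConfig, report: dict) -> dict:
    params = config.fractions
    path = params.get("input") or report["stages"].get("simulate", {}).get(
        "fraction_table"
    )
    if not path:
        raise ValueError("fractions stage needs an intensity table")
    table = io.read_table(path)
    dist = fractions_mod.distribution(table)
    target = params.get("target", "PSI-LHC")
    calls = fractions_mod.enrichment_call(dist, target, params.get("threshold", 0.75))
    dist_path = config.outdir / "fraction_distribution.tsv"
    io.write_table(dist, dist_path)
    result = {
        "distribution_table": str(dist_path),
        "target_fraction": target,
        "n_enriched": int(calls.sum()),
        "enriched_proteins": sorted(calls.index[calls]),
        "excluded_proteins": dist.attrs.get("excluded", []),
    }
    io.write_json(result, config.outdir / "fractions.json")
    return result


def _stage_pigments(config: PipelineConfig, report: dict) -> dict:
    params = config.pigments
    path = params.get("input") or report["stages"].get("simulate", {}).get(
        "pigment_areas"
    )
    if not path:
        raise ValueError("pigments stage needs a peak-area table")
    areas = io.read_table(path, index_col=None)
    quant = pigments_mod.quantify(areas)
    ratio = pigments_mod.chl_car_ratio(quant)
    quant_path = config.outdir / "pigment_quant.tsv"
    io.write_table(quant, quant_path, index=False)
    result = {
        "quant_table": str(quant_path),
        "mol_per_100chl": {
            str(row.pigment): float(row.mol_per_100chl) for row in quant.itertuples()
        },
        "chl_car_ratio": ratio if isinstance(ratio, float) else list(ratio),
    }
    io.write_json(result, config.outdir / "pigments.json")
    return result


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "spectra": _stage_spectra,
    "fractions": _stage_fractions,
    "pigments": _stage_pigments,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a JSON run report.

    A stage failure flushes the partial report (flagged ``failed``) before
    the exception propagates.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "psitrap_version": __version__,
        "seed": int(config.seed),
        "stages": {},
        "status": "ok",
    }
    report_path = config.outdir / "run_report.json"
    for stage in config.stages:
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, report)
        except Exception:
            report["status"] = "failed"
            report["failed_stage"] = stage
            report["traceback"] = traceback.format_exc()
            io.write_json(report, report_path)
            raise
    io.write_json(report, report_path)
    return report
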