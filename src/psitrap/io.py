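"""File I/O for streak images, spectra and tables.

Streak images are stored as CSV (first row = wavelength header, first
column = time in ps) with ``# key: value`` comment lines carrying the IRF
and time-range metadata, or equivalently as HDF5. Spectra are two-column
TSV with the same comment-header convention; fraction and pigment tables
are plain TSV with a header row.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import IRFModel, SpectrumRecord, TimeResolvedImage

__all__ = [
    "write_time_resolved",
    "read_time_resolved",
    "write_spectrum",
    "read_spectrum",
    "write_table",
    "read_table",
]


def _meta_header(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _parse_meta(lines: list) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, value = body.split(":", 1)
            meta[key.strip()] = value.strip()
    return meta


def write_time_resolved(image: TimeResolvedImage, path: str | Path, dialect: str = "csv") -> Path:
    path = Path(path)
    if dialect == "csv":
        meta = {
            "irf_center_ps": repr(float(image.irf.center)),
            "irf_sigma_ps": repr(float(image.irf.sigma)),
            "time_range": image.time_range,
        }
        with open(path, "w") as fh:
            fh.write(_meta_header(meta))
            fh.write(
                "time_ps," + ",".join(repr(float(w)) for w in image.wavelengths) + "\n"
            )
            for t, row in zip(image.times, image.intensity):
                fh.write(
                    repr(float(t)) + "," + ",".join(repr(float(v)) for v in row) + "\n"
                )
    elif dialect == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=image.times)
            fh.create_dataset("wavelengths", data=image.wavelengths)
            fh.create_dataset("intensity", data=image.intensity)
            fh.attrs["irf_center_ps"] = image.irf.center
            fh.attrs["irf_sigma_ps"] = image.irf.sigma
            fh.attrs["time_range"] = image.time_range
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_time_resolved(path: str | Path, dialect: str | None = None) -> TimeResolvedImage:
    """Read a streak image; the dialect is inferred from the suffix if omitted."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if dialect == "hdf5":
        with h5py.File(path, "r") as fh:
            return TimeResolvedImage(
                times=fh["times"][:],
                wavelengths=fh["wavelengths"][:],
                intensity=fh["intensity"][:],
                irf=IRFModel(
                    center=float(fh.attrs.get("irf_center_ps", 0.0)),
                    sigma=float(fh.attrs.get("irf_sigma_ps", 0.0)),
                ),
                time_range=str(fh.attrs.get("time_range", "")),
            )
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    comments, data_lines = [], []
    with open(path) as fh:
        for line in fh:
            (comments if line.startswith("#") else data_lines).append(line)
    if len(data_lines) < 2:
        raise ValueError(f"{path}: no data rows found")
    meta = _parse_meta(comments)
    header = data_lines[0].strip().split(",")
    wavelengths = np.array([float(w) for w in header[1:]])
    times, rows = [], []
    for lineno, line in enumerate(data_lines[1:], start=2):
        fields = line.strip().split(",")
        if len(fields) != wavelengths.size + 1:
            raise ValueError(
                f"{path}: row {lineno} has {len(fields)} fields, "
                f"expected {wavelengths.size + 1}"
            )
        try:
            times.append(float(fields[0]))
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno} is malformed: {exc}") from None
    return TimeResolvedImage(
        times=np.array(times),
        wavelengths=wavelengths,
        intensity=np.array(rows),
        irf=IRFModel(
            center=float(meta.get("irf_center_ps", 0.0)),
            sigma=float(meta.get("irf_sigma_ps", 0.0)),
        ),
        time_range=meta.get("time_range", ""),
    )


def write_spectrum(spec: SpectrumRecord, path: str | Path) -> Path:
    path = Path(path)
    meta = {"kind": spec.kind, "temperature_K": repr(float(spec.temperature))}
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("wavelength_nm\tvalue\n")
        for w, v in zip(spec.wavelengths, spec.values):
            fh.write(f"{float(w)!r}\t{float(v)!r}\n")
    return path


def read_spectrum(path: str | Path) -> SpectrumRecord:
    path = Path(path)
    comments, data_lines = [], []
    with open(path) as fh:
        for line in fh:
            (comments if line.startswith("#") else data_lines).append(line)
    meta = _parse_meta(comments)
    frame = pd.read_csv(
        _io.StringIO("".join(data_lines)), sep="\t", float_precision="round_trip"
    )
    return SpectrumRecord(
        wavelengths=frame.iloc[:, 0].to_numpy(dtype=float),
        values=frame.iloc[:, 1].to_numpy(dtype=float),
        kind=meta.get("kind", "absorption"),
        temperature=float(meta.get("temperature_K", 295.0)),
    )


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
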