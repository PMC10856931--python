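"""Readers and writers for the scan, table and configuration formats.

All tabular data are plain CSV (comma separator, dot decimal, UTF-8,
mandatory header) with units encoded in the column names; metadata
(threshold, detector, seed) travel in ``# key: value`` comment lines at the
top of the file so that a write/read round trip is lossless.  Source
configurations are YAML; anisotropy tables are CSV matrices with a blank
first cell, the theta grid (degrees) across the first row and the r grid
(cm) down the first column.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .characterize import CurrentScan
from .clinical import ScanSeries
from .exceptions import ConfigurationError, DataError
from .tg43 import AnisotropyTable, SourceSpec

__all__ = [
    "read_anisotropy",
    "read_current_scan",
    "read_scan_series",
    "read_source_config",
    "write_anisotropy",
    "write_current_scan",
    "write_scan_series",
    "write_source_config",
]

_CURRENT_COLS = ["current_mA", "gross_counts", "dark_counts", "window_s"]


def _read_meta(path) -> tuple[dict, str]:
    """Split leading '# key: value' comment lines from the CSV body."""
    meta: dict = {}
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _meta_header(**meta) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items() if v not in (None, ""))


def write_current_scan(scan: CurrentScan, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(threshold=scan.threshold, detector=scan.detector,
                              seed=scan.seed))
        scan.to_frame().to_csv(fh, index=False)


def read_current_scan(path) -> CurrentScan:
    """Read a laboratory current scan; validates columns, monotone currents
    and non-negative counts, naming the offending row on failure."""
    meta, body = _read_meta(path)
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in _CURRENT_COLS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    for col in ("gross_counts", "dark_counts"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise DataError(f"{path}: negative {col} at row {bad[0]}")
    diffs = np.diff(df["current_mA"].to_numpy())
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise DataError(f"{path}: currents not strictly increasing at row {row}")
    seed = meta.get("seed")
    return CurrentScan(
        current_ma=df["current_mA"].to_numpy(float),
        gross_counts=df["gross_counts"].to_numpy(np.int64),
        dark_counts=df["dark_counts"].to_numpy(np.int64),
        window_s=df["window_s"].to_numpy(float),
        threshold=float(meta.get("threshold", 0.5)),
        detector=meta.get("detector", ""),
        seed=int(seed) if seed is not None else None,
    )


def write_scan_series(series: ScanSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(threshold=series.threshold, detector=series.detector,
                              source=series.source_name, seed=series.seed))
        series.data.to_csv(fh, index=False)


def read_scan_series(path) -> ScanSeries:
    """Read a phantom scan series in either bench (y, z) or radial geometry.

    A file mixing both conventions is rejected.
    """
    meta, body = _read_meta(path)
    df = pd.read_csv(_io.StringIO(body))
    has_yz = {"y_cm", "z_cm"} <= set(df.columns)
    has_r = "r_cm" in df.columns
    if has_yz and has_r:
        raise DataError(f"{path}: file mixes y_cm/z_cm and r_cm geometry columns")
    if not has_yz and not has_r:
        raise DataError(f"{path}: need either y_cm/z_cm or r_cm columns")
    for c in ("pcr_khz", "sigma_khz", "window_s"):
        if c not in df.columns:
            raise DataError(f"{path}: missing column {c!r}")
    bad = df.index[df["sigma_khz"] <= 0]
    if len(bad):
        raise DataError(f"{path}: non-positive sigma_khz at row {bad[0]}")
    seed = meta.get("seed")
    return ScanSeries(
        data=df,
        threshold=float(meta.get("threshold", 1.5)),
        detector=meta.get("detector", ""),
        source_name=meta.get("source", ""),
        seed=int(seed) if seed is not None else None,
    )


def write_anisotropy(table: AnisotropyTable, path) -> None:
    """CSV matrix: blank first cell, theta grid (deg) in the first row,
    r grid (cm) in the first column, F values in the body."""
    frame = pd.DataFrame(table.values, index=table.r_grid, columns=table.theta_grid)
    frame.to_csv(path, index_label="")


def read_anisotropy(path) -> AnisotropyTable:
    frame = pd.read_csv(path, index_col=0)
    try:
        theta = frame.columns.to_numpy(dtype=float)
        r = frame.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: anisotropy grids must be numeric") from exc
    return AnisotropyTable(r_grid=r, theta_grid=theta,
                           values=frame.to_numpy(dtype=float))


def write_source_config(src: SourceSpec, path, anisotropy_file: str | None = None) -> None:
    """Write a source description; the anisotropy table, if any, goes to a
    sibling CSV referenced by relative path."""
    path = Path(path)
    doc = {
        "name": src.name,
        "air_kerma_strength": src.air_kerma_strength,
        "dose_rate_constant": src.dose_rate_constant,
        "capsule_length_cm": src.capsule_length,
        "radial_coeffs": list(src.radial_coeffs),
        "radial_decay": src.radial_decay,
        "r0_cm": src.r0,
        "theta0_deg": math.degrees(src.theta0),
    }
    if src.anisotropy is None:
        doc["anisotropy_file"] = "point"
    else:
        aniso = anisotropy_file or (path.stem + "_anisotropy.csv")
        write_anisotropy(src.anisotropy, path.parent / aniso)
        doc["anisotropy_file"] = aniso
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_source_config(path) -> SourceSpec:
    """Read a YAML source configuration (see the writer for the schema).

    ``anisotropy_file: point`` selects point-source mode; otherwise the
    table is loaded from the path, resolved relative to the config file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: not a key-value source configuration")
    required = ["air_kerma_strength", "dose_rate_constant", "capsule_length_cm",
                "radial_coeffs", "radial_decay", "anisotropy_file"]
    missing = [k for k in required if k not in doc]
    if missing:
        raise ConfigurationError(f"{path}: missing key(s) {missing}")
    coeffs = doc["radial_coeffs"]
    if not isinstance(coeffs, (list, tuple)) or len(coeffs) != 6:
        raise ConfigurationError(
            f"{path}: radial_coeffs must list the 6 coefficients a_n, n = -2..3"
        )
    aniso_ref = doc["anisotropy_file"]
    if isinstance(aniso_ref, str) and aniso_ref.strip().lower() == "point":
        table = None
    else:
        table = read_anisotropy(path.parent / aniso_ref)
    return SourceSpec(
        air_kerma_strength=float(doc["air_kerma_strength"]),
        dose_rate_constant=float(doc["dose_rate_constant"]),
        capsule_length=float(doc["capsule_length_cm"]),
        radial_coeffs=tuple(float(c) for c in coeffs),
        radial_decay=float(doc["radial_decay"]),
        anisotropy=table,
        r0=float(doc.get("r0_cm", 2.0)),
        theta0=math.radians(float(doc.get("theta0_deg", 90.0))),
        name=str(doc.get("name", "source")),
    )
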