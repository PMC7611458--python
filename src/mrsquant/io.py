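"""Plain-text file formats: spectra (JSON/CSV), water series (CSV),
cohort manifests (TSV), and report tables with ``#`` metadata headers.

All round-trips satisfy write-then-read identity to machine precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .specfit import Spectrum
from .waterfit import WaterSeries

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "site",
    "edss",
    "duration_yrs",
    "lesion_age_months",
    "spectrum_path",
    "water_path",
]


class SchemaError(ValueError):
    pass


# -- spectra ----------------------------------------------------------------


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "id": spectrum.id,
        "acq": spectrum.acq.to_dict(),
        "ppm": [float(v) for v in spectrum.ppm],
        "intensity": [float(v) for v in spectrum.intensity],
    }
    path.write_text(json.dumps(doc))


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    for key in ("ppm", "intensity", "acq"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    if len(doc["ppm"]) != len(doc["intensity"]):
        raise SchemaError(f"{path}: ppm and intensity lengths differ")
    return Spectrum(
        ppm=np.array(doc["ppm"]),
        intensity=np.array(doc["intensity"]),
        acq=AcquisitionParams.from_dict(doc["acq"]),
        id=doc.get("id", ""),
    )


# -- water series -----------------------------------------------------------


def write_water_series(series: WaterSeries, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# voxel_id: {series.voxel_id}", "te_ms,integral"]
    for te, v in zip(series.te_ms, series.integral):
        lines.append(f"{float(te)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_water_series(path: str | Path) -> WaterSeries:
    path = Path(path)
    voxel_id = ""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "voxel_id:" in line:
                    voxel_id = line.split("voxel_id:", 1)[1].strip()
                continue
            if line.lower().startswith("te_ms"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise SchemaError(f"{path}:{lineno}: non-numeric value") from e
    if not rows:
        raise SchemaError(f"{path}: empty water series")
    te = np.array([r[0] for r in rows])
    integral = np.array([r[1] for r in rows])
    if np.any(np.diff(te) <= 0):
        warnings.warn(f"{path}: TE values not sorted; sorting on read", stacklevel=2)
        order = np.argsort(te)
        te, integral = te[order], integral[order]
    return WaterSeries(te_ms=te, integral=integral, voxel_id=voxel_id)


# -- manifest ---------------------------------------------------------------


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")
    if check_files:
        base = path.parent
        for _, row in df.iterrows():
            for col in ("spectrum_path", "water_path"):
                p = base / row[col]
                if not p.exists():
                    raise FileNotFoundError(
                        f"manifest entry for subject {row['subject_id']} "
                        f"({row['site']}): missing file {p}"
                    )
    return df


# -- report tables ----------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """TSV with ``#``-prefixed metadata header lines."""
    path = Path(path)
    header = "".join(f"# {k}: {v}\n" for k, v in (metadata or {}).items())
    path.write_text(header + df.to_csv(sep="\t", index=False))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
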