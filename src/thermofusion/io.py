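"""Readers and writers for thermal matrices, grayscale renderings and the
clinical table.

A thermal matrix file is a whitespace-separated grid of per-pixel
temperatures in °C, one image row per line. Grayscale PNGs are an 8-bit
min–max-scaled rendering per image; reading one back requires the
temperature range the intensities map to. The clinical table is a CSV
with one row per patient and the literal string ``"not answered"`` for
missing discrete answers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import (
    CONTINUOUS_FEATURES,
    DISCRETE_FEATURES,
    ClinicalRecord,
    ThermalStudy,
)

NOT_ANSWERED = "not answered"


def write_thermal_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.3f")


def read_thermal_matrix(path: str | Path) -> np.ndarray:
    """Parse a plain-text temperature grid; rejects ragged or non-numeric
    files, naming the offending line."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token on line {lineno}") from exc
            if len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(rows[-1])} values, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty thermal matrix file")
    return np.asarray(rows)


def write_png(matrix: np.ndarray, path: str | Path) -> tuple[float, float]:
    """Render one matrix as an 8-bit grayscale PNG (min–max scaled).

    Returns the (min, max) temperature range needed to invert the scaling.
    """
    m = np.asarray(matrix, dtype=float)
    lo, hi = float(m.min()), float(m.max())
    scale = (hi - lo) or 1.0
    img = np.round((m - lo) / scale * 255.0).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
    return lo, hi

def read_png(path: str | Path, temp_min: float, temp_max: float) -> np.ndarray:
    """Read an 8-bit grayscale raster, mapping intensity linearly onto
    ``[temp_min, temp_max]``."""
    img = np.asarray(Image.open(path).convert("L"), dtype=float)
    return temp_min + img / 255.0 * (temp_max - temp_min)


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"patient_id": r.patient_id}
        for name in DISCRETE_FEATURES:
            value = r.discrete.get(name, "")
            row[name] = value if value else NOT_ANSWERED
        for name in CONTINUOUS_FEATURES:
            value = r.continuous.get(name)
            row[name] = "" if value is None else value
        row["diagnosis"] = r.diagnosis
        rows.append(row)
    columns = ["patient_id", *DISCRETE_FEATURES, *CONTINUOUS_FEATURES, "diagnosis"]
    return pd.DataFrame(rows, columns=columns)


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        continuous: dict[str, float | None] = {}
        for name in CONTINUOUS_FEATURES:
            raw = row.get(name, "")
            continuous[name] = None if raw == "" else float(raw)
        records.append(
            ClinicalRecord(
                patient_id=row["patient_id"],
                discrete={name: str(row.get(name, NOT_ANSWERED)) for name in DISCRETE_FEATURES},
                continuous=continuous,
                diagnosis=str(row["diagnosis"]),
            )
        )
    return records


def write_cohort(studies: list[ThermalStudy], records: list[ClinicalRecord],
                 out_dir: str | Path, *, write_pngs: bool = False,
                 manifest_extra: dict | None = None) -> dict:
    """Write one matrix file per view per patient plus the clinical CSV and
    a manifest JSON; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_dir = out_dir / "thermal"
    matrix_dir.mkdir(exist_ok=True)
    files = []
    study_meta = []
    for study in studies:
        for view, matrix in sorted(study.views.items()):
            fname = f"{study.patient_id}_{view}.txt"
            write_thermal_matrix(matrix, matrix_dir / fname)
            files.append(f"thermal/{fname}")
            if write_pngs:
                png = f"{study.patient_id}_{view}.png"
                write_png(matrix, matrix_dir / png)
                files.append(f"thermal/{png}")
        study_meta.append(
            {
                "patient_id": study.patient_id,
                "views": sorted(study.views),
                "protocol": study.protocol,
                "qc_flags": sorted(study.qc_flags),
                "defect_views": study.defect_views,
                "dynamic_views": sorted(study.dynamic_views),
                "diagnosis": study.diagnosis,
            }
        )
        for view, matrix in sorted(study.dynamic_views.items()):
            fname = f"{study.patient_id}_{view}_dynamic.txt"
            write_thermal_matrix(matrix, matrix_dir / fname)
            files.append(f"thermal/{fname}")
    write_clinical_csv(records, out_dir / "clinical.csv")
    files.append("clinical.csv")
    manifest = {
        "n_patients": len(studies),
        "files": files,
        "studies": study_meta,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(out_dir: str | Path) -> tuple[list[ThermalStudy], list[ClinicalRecord]]:
    """Load a cohort previously written by :func:`write_cohort`."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    studies = []
    for meta in manifest["studies"]:
        pid = meta["patient_id"]
        views = {
            v: read_thermal_matrix(out_dir / "thermal" / f"{pid}_{v}.txt")
            for v in meta["views"]
        }
        dynamic = {
            v: read_thermal_matrix(out_dir / "thermal" / f"{pid}_{v}_dynamic.txt")
            for v in meta.get("dynamic_views", [])
        }
        studies.append(
            ThermalStudy(
                patient_id=pid,
                views=views,
                protocol=meta.get("protocol", {}),
                qc_flags=set(meta.get("qc_flags", [])),
                diagnosis=meta.get("diagnosis"),
                defect_views=meta.get("defect_views", {}),
                dynamic_views=dynamic,
            )
        )
    records = read_clinical_csv(out_dir / "clinical.csv")
    return studies, records
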