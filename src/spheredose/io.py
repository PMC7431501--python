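"""File I/O: volumes (NIfTI, TIFF stack + JSON sidecar), sphere tables (CSV),
treatment records (JSON/CSV).

Every volume written by the package carries a JSON sidecar (``<stem>.json``)
holding the unit tag, grid origin and a provenance block; NIfTI spacing
lives in the header affine, TIFF spacing only in the sidecar (so the
sidecar is mandatory for TIFF input).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .grid import Volume, VoxelGrid
from .nuclide import TreatmentRecord
from .spheres import SphereTable

SPHERE_COLUMNS = ["x_mm", "y_mm", "z_mm", "activity_bq"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    meta = {
        "unit": volume.unit,
        "origin_mm": list(volume.grid.origin),
        "spacing_mm": list(volume.grid.spacing),
        "provenance": _jsonable(volume.provenance),
    }
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.grid.spacing) + [1.0])
        affine[:3, 3] = volume.grid.origin
        img = nib.Nifti1Image(np.asarray(volume.data), affine)
        img.header.set_zooms(volume.grid.spacing)
        nib.save(img, str(path))
    elif path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), np.asarray(volume.data), photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path, expected_unit: str | None = None) -> Volume:
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
    elif path.name.endswith((".tif", ".tiff")):
        if "spacing_mm" not in meta:
            raise ValueError(
                f"TIFF volume {path.name} lacks the required sidecar field 'spacing_mm' "
                f"(expected {sidecar.name})")
        data = tifffile.imread(str(path))
        spacing = tuple(float(s) for s in meta["spacing_mm"])
        origin = tuple(float(o) for o in meta.get("origin_mm", (0, 0, 0)))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")

    unit = meta.get("unit")
    if unit is None:
        raise ValueError(f"volume {path.name} has no unit tag (missing/empty sidecar)")
    if expected_unit is not None and unit != expected_unit:
        raise ValueError(f"volume {path.name} carries unit {unit!r}, expected {expected_unit!r}")
    grid = VoxelGrid(tuple(data.shape), spacing, origin)
    return Volume(grid, data, unit, provenance=meta.get("provenance", {}))


def write_sphere_table(table: SphereTable, path) -> None:
    df = pd.DataFrame(
        np.column_stack([table.positions_mm, table.activities_bq]),
        columns=SPHERE_COLUMNS)
    df.to_csv(path, index=False)
    prov = _jsonable(table.provenance)
    if prov:
        Path(path).with_suffix(".json").write_text(json.dumps(prov, indent=1))


def read_sphere_table(path) -> SphereTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed sphere table {path.name}: {e}") from None
    missing = [c for c in SPHERE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sphere table {path.name} lacks columns {missing}")
    bad = df[SPHERE_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed rows in {path.name} at line(s) {lines[:10]}")
    sidecar = path.with_suffix(".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SphereTable(df[SPHERE_COLUMNS[:3]].to_numpy(float),
                       df["activity_bq"].to_numpy(float), provenance=prov)


def write_treatment_record(record: TreatmentRecord, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(record), indent=1))


def read_treatment_record(path) -> TreatmentRecord:
    return TreatmentRecord(**json.loads(Path(path).read_text()))


TREATMENT_COLUMNS = ["label", "infused_activity_gbq", "days_post_calibration",
                     "target_region_volume_ml", "perfused_fraction",
                     "tissue_density_g_per_ml", "target_dose_gy"]


def write_treatment_table(records: list[TreatmentRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[TREATMENT_COLUMNS].to_csv(
        path, index=False)


def read_treatment_table(path) -> list[TreatmentRecord]:
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        kw = {k: row[k] for k in TREATMENT_COLUMNS if k in df.columns and pd.notna(row[k])}
        recs.append(TreatmentRecord(**kw))
    return recs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
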