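"""Series serialization: NRRD volumes plus a JSON manifest.

One NRRD file per dose grid, mask and displacement field.  Masks are
stored as 8-bit 0/1, doses as float64 (round-trips within 1e-6 Gy), and
displacement fields as 3-component vector volumes.  The manifest records
prescription, margin policy and per-fraction file names, delivered plan
and edit class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import (
    DisplacementField,
    DoseGrid,
    FractionRecord,
    GridGeometry,
    Prescription,
    SeriesRecord,
    StructureMask,
    ValidationError,
)

MANIFEST_NAME = "series.json"


def _to_image(array: np.ndarray, geom: GridGeometry, vector: bool = False) -> sitk.Image:
    img = sitk.GetImageFromArray(array, isVector=vector)
    # SimpleITK spacing/origin are (x, y, z); storage order is (z, y, x)
    img.SetSpacing(tuple(reversed(geom.spacing)))
    img.SetOrigin(tuple(reversed(geom.origin)))
    return img


def _from_image(img: sitk.Image) -> tuple[np.ndarray, GridGeometry]:
    arr = sitk.GetArrayFromImage(img)
    shape = arr.shape[:3]
    geom = GridGeometry(shape, tuple(reversed(img.GetSpacing())), tuple(reversed(img.GetOrigin())))
    return arr, geom


def _write_nrrd(path: Path, array: np.ndarray, geom: GridGeometry, vector: bool = False) -> None:
    sitk.WriteImage(_to_image(array, geom, vector), str(path), useCompression=True)


def _read_nrrd(path: Path) -> tuple[np.ndarray, GridGeometry]:
    if not path.is_file():
        raise FileNotFoundError(f"missing volume file: {path}")
    return _from_image(sitk.ReadImage(str(path)))


def write_series(series: SeriesRecord, out_dir: str | Path) -> Path:
    """Write a series to ``out_dir``; returns the manifest path.

    ``read_series(write_series(s))`` reproduces ``s`` bit-exactly for masks
    and within 1e-6 Gy per voxel for doses.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise IOError(f"cannot create output directory {out_dir}")

    geom = series.reference_dose.geometry
    _write_nrrd(out_dir / "reference_dose.nrrd", series.reference_dose.values, geom)
    _write_nrrd(
        out_dir / "reference_ctv.nrrd", series.reference_ctv.voxels.astype(np.uint8), geom
    )

    fraction_entries = []
    for f in series.fractions:
        tag = f"fx{f.index:03d}"
        files = {
            "ictv": f"{tag}_ictv.nrrd",
            "scheduled_dose": f"{tag}_scheduled.nrrd",
            "dvf": f"{tag}_dvf.nrrd",
        }
        _write_nrrd(out_dir / files["ictv"], f.ictv.voxels.astype(np.uint8), f.ictv.geometry)
        _write_nrrd(out_dir / files["scheduled_dose"], f.scheduled_dose.values, geom)
        _write_nrrd(out_dir / files["dvf"], f.dvf.vectors, f.dvf.geometry, vector=True)
        if f.adapted_dose is not None:
            files["adapted_dose"] = f"{tag}_adapted.nrrd"
            _write_nrrd(out_dir / files["adapted_dose"], f.adapted_dose.values, geom)
        oar_files = {}
        for m in f.oars:
            oar_files[m.label] = f"{tag}_{m.label}.nrrd"
            _write_nrrd(out_dir / oar_files[m.label], m.voxels.astype(np.uint8), m.geometry)
        fraction_entries.append(
            {
                "index": f.index,
                "files": files,
                "oar_files": oar_files,
                "delivered_plan": f.delivered_plan,
                "edit_class": f.edit_class,
            }
        )

    manifest = {
        "series_id": series.series_id,
        "prescription_Gy": series.prescription.total_gy,
        "dose_per_fraction_Gy": series.prescription.per_fraction_gy,
        "ptv_margin_mm": series.ptv_margin_mm,
        "reference": {"dose": "reference_dose.nrrd", "ctv": "reference_ctv.nrrd"},
        "fractions": fraction_entries,
    }
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_series(manifest_path: str | Path) -> SeriesRecord:
    """Load a series from a JSON manifest; all domain invariants are checked."""
    manifest_path = Path(manifest_path)
    if not manifest_path.is_file():
        raise FileNotFoundError(f"missing manifest file: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())

    dose_arr, geom = _read_nrrd(root / manifest["reference"]["dose"])
    reference_dose = DoseGrid(dose_arr, geom)
    ctv_arr, ctv_geom = _read_nrrd(root / manifest["reference"]["ctv"])
    reference_ctv = StructureMask(ctv_arr.astype(bool), ctv_geom, "CTV")

    fractions = []
    for entry in manifest["fractions"]:
        idx = entry["index"]
        files = entry["files"]
        sched_arr, sched_geom = _read_nrrd(root / files["scheduled_dose"])
        ictv_arr, ictv_geom = _read_nrrd(root / files["ictv"])
        if ictv_geom.shape != sched_geom.shape:
            raise ValidationError(
                f"fraction {idx}: iCTV mask shape {ictv_geom.shape} disagrees with "
                f"dose grid shape {sched_geom.shape}"
            )
        dvf_arr, dvf_geom = _read_nrrd(root / files["dvf"])
        adapted = None
        if "adapted_dose" in files:
            a_arr, a_geom = _read_nrrd(root / files["adapted_dose"])
            adapted = DoseGrid(a_arr, a_geom)
        oars = [
            StructureMask(_read_nrrd(root / fname)[0].astype(bool), sched_geom, label)
            for label, fname in entry.get("oar_files", {}).items()
        ]
        fractions.append(
            FractionRecord(
                index=idx,
                ictv=StructureMask(ictv_arr.astype(bool), ictv_geom, "iCTV"),
                scheduled_dose=DoseGrid(sched_arr, sched_geom),
                dvf=DisplacementField(dvf_arr, dvf_geom),
                adapted_dose=adapted,
                oars=oars,
                delivered_plan=entry["delivered_plan"],
                edit_class=entry["edit_class"],
            )
        )

    return SeriesRecord(
        reference_ctv=reference_ctv,
        reference_dose=reference_dose,
        prescription=Prescription(
            manifest["prescription_Gy"], manifest["dose_per_fraction_Gy"]
        ),
        ptv_margin_mm=manifest["ptv_margin_mm"],
        fractions=fractions,
        series_id=manifest.get("series_id", "series"),
    )
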