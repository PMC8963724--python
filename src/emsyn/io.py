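"""File formats.

Volumes travel as HDF5 (one dataset per file, voxel pitch in attributes) or
multi-page TIFF stacks (one page per z-slice). In-memory arrays are indexed
``[x, y, z]``; a TIFF page holds rows = y, columns = x, so the on-disk page
``i`` is ``array[:, :, i].T``. Tables (cell types, ground truth, contacts,
synapses) are plain CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .contacts import Contact, contact_location
from .core import (
    CellType,
    CellTypeMap,
    GroundTruth,
    LikelihoodMap,
    SegmentationVolume,
    VoxelGeometry,
)

__all__ = [
    "read_segmentation",
    "write_segmentation",
    "read_likelihood",
    "write_likelihood",
    "read_cell_types",
    "write_cell_types",
    "read_ground_truth",
    "write_ground_truth",
    "contacts_to_frame",
    "write_contacts",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _to_pages(volume: np.ndarray) -> np.ndarray:
    # (x, y, z) -> (z, y, x): page per section, rows y, cols x.
    return np.ascontiguousarray(volume.transpose(2, 1, 0))


def _from_pages(pages: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def write_segmentation(path: str | Path, seg: SegmentationVolume) -> None:
    path = Path(path)
    if path.suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, _to_pages(seg.labels.astype(np.int32)))
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=seg.labels, compression="gzip")
        ds.attrs["dx_nm"] = seg.geometry.dx
        ds.attrs["dy_nm"] = seg.geometry.dy
        ds.attrs["dz_nm"] = seg.geometry.dz
        ds.attrs["axis_order"] = "xyz"


def read_segmentation(
    path: str | Path, geometry: VoxelGeometry | None = None
) -> SegmentationVolume:
    path = Path(path)
    if path.suffix in _TIFF_SUFFIXES:
        labels = _from_pages(np.asarray(tifffile.imread(path)))
        return SegmentationVolume(labels, geometry or VoxelGeometry())
    with h5py.File(path, "r") as f:
        ds = f["labels"]
        labels = ds[()]
        if geometry is None and "dx_nm" in ds.attrs:
            geometry = VoxelGeometry(
                float(ds.attrs["dx_nm"]), float(ds.attrs["dy_nm"]), float(ds.attrs["dz_nm"])
            )
    return SegmentationVolume(labels, geometry or VoxelGeometry())


def write_likelihood(path: str | Path, lmap: LikelihoodMap) -> None:
    path = Path(path)
    if path.suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, _to_pages(lmap.values.astype(np.float32)))
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("values", data=lmap.values.astype(np.float32), compression="gzip")
        ds.attrs["role"] = lmap.role
        ds.attrs["axis_order"] = "xyz"


def read_likelihood(path: str | Path, role: str | None = None) -> LikelihoodMap:
    path = Path(path)
    if path.suffix in _TIFF_SUFFIXES:
        values = _from_pages(np.asarray(tifffile.imread(path)))
        return LikelihoodMap(values, role or "SC")
    with h5py.File(path, "r") as f:
        ds = f["values"]
        values = ds[()]
        stored = ds.attrs.get("role")
    return LikelihoodMap(values, role or (str(stored) if stored else "SC"))


def write_cell_types(path: str | Path, types: CellTypeMap) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["segment_id", "type"])
        for seg_id, t in sorted(types.items()):
            w.writerow([seg_id, t.value])


def read_cell_types(path: str | Path) -> CellTypeMap:
    df = pd.read_csv(path)
    return CellTypeMap(
        {int(r.segment_id): CellType(r.type) for r in df.itertuples(index=False)}
    )


def write_ground_truth(path: str | Path, truth: dict[int, GroundTruth]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["contact_id", "label"])
        for cid, label in sorted(truth.items()):
            w.writerow([cid, label.value])


def read_ground_truth(path: str | Path) -> dict[int, GroundTruth]:
    df = pd.read_csv(path)
    return {int(r.contact_id): GroundTruth(r.label) for r in df.itertuples(index=False)}


def contacts_to_frame(contacts: list[Contact]) -> pd.DataFrame:
    """Contacts as a table (one row per contact; voxel sets are not stored)."""
    rows = []
    for c in contacts:
        loc = contact_location(c)
        rows.append(
            {
                "contact_id": c.id,
                "seg_a": c.pair[0],
                "seg_b": c.pair[1],
                "voxel_count": c.voxel_count,
                "fx": c.face_counts[0],
                "fy": c.face_counts[1],
                "fz": c.face_counts[2],
                "area_nm2": c.area_nm2,
                "loc_x": loc[0],
                "loc_y": loc[1],
                "loc_z": loc[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contact_id",
            "seg_a",
            "seg_b",
            "voxel_count",
            "fx",
            "fy",
            "fz",
            "area_nm2",
            "loc_x",
            "loc_y",
            "loc_z",
        ],
    )


def write_contacts(path: str | Path, contacts: list[Contact], extra: pd.DataFrame | None = None) -> None:
    """Write the contacts CSV, optionally joined with per-contact extras
    (features, scores, decisions) indexed by contact_id."""
    df = contacts_to_frame(contacts)
    if extra is not None:
        df = df.merge(extra, on="contact_id", how="left")
    df.to_csv(path, index=False)
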