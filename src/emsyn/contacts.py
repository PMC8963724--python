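"""Inter-fragment contact extraction from labelled volumes.

A *contact* is the two-voxel-thick interface between one unordered pair of
segments: the set of voxels, on both sides, where the segment ID changes
between 6-neighbors. Contact voxels of a pair are grouped into connected
components (26-connectivity in voxel index space) and each component is one
contact. Alongside the voxel set we count, per axis, the number of adjacent
voxel pairs whose IDs differ ("faces"); anisotropic face areas turn those
counts into a physical contact area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SegmentationVolume, VoxelGeometry

__all__ = [
    "Contact",
    "fill_background",
    "extract_contacts",
    "filter_small_contacts",
    "contact_area",
    "contact_location",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Contact:
    """One connected interface component between an unordered segment pair.

    ``voxels`` holds the coordinates of the interface voxels from *both*
    sides (shape ``(n, 3)``); ``face_counts`` are the per-axis counts of
    differing-ID adjacent voxel pairs belonging to this component, counted
    once per pair (not per side). ``area_nm2`` is derived from the face
    counts and the voxel geometry.
    """

    id: int
    pair: tuple[int, int]  # (a, b) with a < b
    voxels: np.ndarray
    face_counts: tuple[int, int, int]
    area_nm2: float

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.shape[0])

    def __post_init__(self) -> None:
        a, b = self.pair
        if not a < b:
            raise ValueError("contact pair must be ordered (a < b)")
        if self.voxels.shape[0] < 1:
            raise ValueError("a contact must contain at least one voxel")
        if sum(self.face_counts) < 1:
            raise ValueError("a contact must contain at least one face")


def fill_background(segmentation: SegmentationVolume) -> SegmentationVolume:
    """Dilate segments until background voxels are saturated.

    Every background (ID 0) voxel adopts the ID of its nearest segment, with
    distance measured in physical units (nm) so that the anisotropic section
    thickness is respected. Distance ties are broken toward the smaller
    segment ID, making the result deterministic. Originally labelled voxels
    are never changed.
    """
    lab = segmentation.labels
    if (lab != 0).sum() == 0:
        raise ValueError("cannot saturate an all-background volume")
    if segmentation.is_saturated:
        return segmentation

    ids = segmentation.segment_ids()
    sampling = segmentation.geometry.pitch
    if len(ids) == 1:
        filled = np.full_like(lab, ids[0])
        return SegmentationVolume(filled, segmentation.geometry)

    # One EDT per label, ascending; a strict '<' keeps the smaller ID on ties.
    best_dist = np.full(lab.shape, np.inf)
    best_id = np.zeros(lab.shape, dtype=lab.dtype)
    for seg_id in ids:
        dist = ndimage.distance_transform_edt(lab != seg_id, sampling=sampling)
        closer = dist < best_dist
        best_dist[closer] = dist[closer]
        best_id[closer] = seg_id
    filled = np.where(lab != 0, lab, best_id)
    return SegmentationVolume(filled, segmentation.geometry)


def _linear_index(voxels: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    return (voxels[:, 0] * dims[1] + voxels[:, 1]) * dims[2] + voxels[:, 2]


def extract_contacts(segmentation: SegmentationVolume) -> list[Contact]:
    """Extract all inter-fragment contacts from a saturated volume.

    Returns one :class:`Contact` per connected component of per-pair
    interface voxels, enumerated in ascending ``(a, b, min linear voxel
    index)`` order so that contact IDs are reproducible.
    """
    if not segmentation.is_saturated:
        raise ValueError("segmentation must be saturated (no background); run fill_background first")
    lab = segmentation.labels
    dims = lab.shape

    # Gather every differing-ID adjacent voxel pair ("face") per axis.
    face_lo = []  # coordinate of the lower voxel of the face
    face_axis = []
    face_a = []
    face_b = []
    for axis in range(3):
        lo_sl = [slice(None)] * 3
        hi_sl = [slice(None)] * 3
        lo_sl[axis] = slice(None, -1)
        hi_sl[axis] = slice(1, None)
        la = lab[tuple(lo_sl)]
        lb = lab[tuple(hi_sl)]
        diff = la != lb
        coords = np.argwhere(diff)
        if coords.size == 0:
            continue
        va = la[diff]
        vb = lb[diff]
        face_lo.append(coords)
        face_axis.append(np.full(coords.shape[0], axis, dtype=np.int8))
        face_a.append(np.minimum(va, vb))
        face_b.append(np.maximum(va, vb))
    if not face_lo:
        return []

    lo = np.concatenate(face_lo)
    ax = np.concatenate(face_axis)
    pa = np.concatenate(face_a)
    pb = np.concatenate(face_b)

    pair_keys = pa.astype(np.int64) * (int(lab.max()) + 1) + pb.astype(np.int64)
    order = np.lexsort((pb, pa))
    contacts: list[Contact] = []
    unique_keys, start_idx = np.unique(pair_keys[order], return_index=True)
    boundaries = np.append(start_idx, order.size)

    unit = np.eye(3, dtype=lo.dtype)
    for i in range(unique_keys.size):
        sel = order[boundaries[i]: boundaries[i + 1]]
        a, b = int(pa[sel[0]]), int(pb[sel[0]])
        f_lo = lo[sel]
        f_ax = ax[sel]
        f_hi = f_lo + unit[f_ax]
        vox = np.unique(np.concatenate([f_lo, f_hi]), axis=0)

        # Connected components of the two-sided voxel set, within a bbox.
        origin = vox.min(axis=0)
        shape = vox.max(axis=0) - origin + 1
        mask = np.zeros(shape, dtype=bool)
        rel = vox - origin
        mask[tuple(rel.T)] = True
        comp, n_comp = ndimage.label(mask, structure=_STRUCT26)
        vox_comp = comp[tuple(rel.T)]
        # Both voxels of a face are 6-adjacent, hence in the same component.
        face_comp = comp[tuple((f_lo - origin).T)]

        for c in range(1, n_comp + 1):
            cvox = vox[vox_comp == c]
            fsel = face_comp == c
            counts = tuple(int((f_ax[fsel] == axis).sum()) for axis in range(3))
            contacts.append(
                Contact(
                    id=-1,
                    pair=(a, b),
                    voxels=cvox,
                    face_counts=counts,  # type: ignore[arg-type]
                    area_nm2=_area_from_counts(counts, segmentation.geometry),
                )
            )

    contacts.sort(
        key=lambda c: (c.pair[0], c.pair[1], int(_linear_index(c.voxels, dims).min()))
    )
    for i, c in enumerate(contacts):
        c.id = i
    return contacts


def _area_from_counts(face_counts, geometry: VoxelGeometry) -> float:
    fa = geometry.face_areas
    return float(sum(n * a for n, a in zip(face_counts, fa)))


def filter_small_contacts(contacts: list[Contact], min_voxels: int = 200) -> list[Contact]:
    """Drop noise contacts with ``voxel_count <= min_voxels`` (inclusive removal).

    At the default threshold of 200 voxels a removed contact is roughly
    0.03 um^2 or smaller. Input order (and contact IDs) are preserved.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be non-negative")
    return [c for c in contacts if c.voxel_count > min_voxels]


def contact_area(contact: Contact, geometry: VoxelGeometry) -> float:
    """Contact area in nm^2 from per-axis face counts.

    ``area = fx*(dy*dz) + fy*(dx*dz) + fz*(dx*dy)`` — each ID-change location
    contributes the area of the voxel face it crosses.
    """
    return _area_from_counts(contact.face_counts, geometry)


def _median_half_down(values: np.ndarray) -> int:
    """Median rounded to the nearest integer with .5 ties toward the lower value."""
    s = np.sort(values)
    n = s.size
    med = (float(s[(n - 1) // 2]) + float(s[n // 2])) / 2.0
    return int(math.ceil(med - 0.5))


def contact_location(contact: Contact) -> tuple[int, int, int]:
    """Representative voxel of a contact: the per-axis median coordinate,
    rounded to the nearest integer with ties toward the lower coordinate."""
    if contact.voxel_count < 1:
        raise ValueError("empty contact has no location")
    return tuple(_median_half_down(contact.voxels[:, axis]) for axis in range(3))  # type: ignore[return-value]
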