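"""Core data model for EM connectomics volumes.

Conventions used throughout the package:

* Voxel indices are 0-based, with axis order ``(x, y, z)``; ``z`` is the
  sectioning axis (the axis along which physical resolution is coarsest).
  A :class:`SegmentationVolume` therefore stores its labels as an array of
  shape ``(nx, ny, nz)`` indexed as ``labels[x, y, z]``.
* Physical voxel pitch is expressed in nanometres per axis; extents derived
  from it are reported in micrometres.
* Segment ID 0 denotes background (unreconstructed space); every nonzero ID
  is a neuronal fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CellType",
    "GroundTruth",
    "VoxelGeometry",
    "SegmentationVolume",
    "LikelihoodMap",
    "CellTypeMap",
    "voxel_dims_to_physical",
    "boundary_mask",
]


class CellType(str, Enum):
    """Anatomical type of a neuronal fragment in the cerebellar molecular layer.

    PF: parallel fiber (granule-cell axon); PC: Purkinje cell; IN: molecular
    layer inhibitory interneuron; CF: climbing fiber. OTHER covers glia and
    any fragment whose type is unknown; OTHER fragments never take part in
    synaptically relevant contacts.
    """

    PF = "PF"
    PC = "PC"
    IN = "IN"
    CF = "CF"
    OTHER = "OTHER"


class GroundTruth(str, Enum):
    """Expert vote on a contact. AMBIGUOUS contacts are excluded from both
    classifier training and accuracy evaluation."""

    SYNAPTIC = "SYNAPTIC"
    NON_SYNAPTIC = "NON_SYNAPTIC"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class VoxelGeometry:
    """Anisotropic voxel pitch in nanometres.

    ``dx``/``dy`` are the in-plane (block-face) pixel pitch and ``dz`` the
    section thickness. The default (12, 12, 50) matches serial block-face
    SEM at 12 nm lateral resolution and 50 nm nominal cutting thickness.
    """

    dx: float = 12.0
    dy: float = 12.0
    dz: float = 50.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel pitch must be strictly positive on all axes")

    @property
    def pitch(self) -> np.ndarray:
        """Per-axis pitch ``(dx, dy, dz)`` in nm."""
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def face_areas(self) -> tuple[float, float, float]:
        """Area in nm^2 of a voxel face normal to each axis.

        A face normal to x lies in the YZ plane (area ``dy*dz``), and so on.
        At the default pitch these are 600, 600 and 144 nm^2.
        """
        return (self.dy * self.dz, self.dx * self.dz, self.dx * self.dy)


@dataclass
class SegmentationVolume:
    """A 3D grid of non-negative integer segment IDs with voxel geometry."""

    labels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        if any(d <= 0 for d in self.labels.shape):
            raise ValueError("all volume dimensions must be positive")
        if self.labels.min() < 0:
            raise ValueError("segment IDs must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def is_saturated(self) -> bool:
        """True when no background (ID 0) voxels remain."""
        return bool((self.labels != 0).all())

    def segment_ids(self) -> np.ndarray:
        """Sorted nonzero segment IDs present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids != 0]


@dataclass
class LikelihoodMap:
    """Per-voxel likelihood in [0, 1]; ``role`` is ``"SC"`` (synaptic contact)
    or ``"VC"`` (vesicle cloud)."""

    values: np.ndarray
    role: str = "SC"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("likelihood map must be 3D")
        if self.role not in ("SC", "VC"):
            raise ValueError("role must be 'SC' or 'VC'")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"likelihood values outside [0, 1]: [{lo}, {hi}]")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


class CellTypeMap:
    """Mapping from segment ID to :class:`CellType`.

    IDs without an explicit entry default to ``OTHER``, which makes the map a
    total function over every fragment present in a volume.
    """

    def __init__(self, mapping: dict[int, CellType] | None = None):
        self._map: dict[int, CellType] = {}
        for seg_id, t in (mapping or {}).items():
            self._map[int(seg_id)] = CellType(t)

    def __setitem__(self, seg_id: int, t: CellType) -> None:
        self._map[int(seg_id)] = CellType(t)

    def __getitem__(self, seg_id: int) -> CellType:
        return self._map.get(int(seg_id), CellType.OTHER)

    def __contains__(self, seg_id: int) -> bool:
        return int(seg_id) in self._map

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        return isinstance(other, CellTypeMap) and self._map == other._map


def voxel_dims_to_physical(
    dims: tuple[int, int, int], geometry: VoxelGeometry
) -> tuple[tuple[float, float, float], float]:
    """Convert voxel counts to physical extents (um per axis) and volume (um^3).

    ``extent_i = dims_i * pitch_i / 1000``; the volume is the product of the
    three extents. For example a 992 x 992 x 248 volume at (12, 12, 50) nm is
    11.904 x 11.904 x 12.4 um, i.e. about 1757 um^3.
    """
    if len(dims) != 3 or any(int(d) <= 0 for d in dims):
        raise ValueError("dims must be three positive voxel counts")
    pitch = geometry.pitch
    extents = tuple(float(int(d) * p / 1000.0) for d, p in zip(dims, pitch))
    volume = float(np.prod(extents))
    return extents, volume  # type: ignore[return-value]


def boundary_mask(segmentation: SegmentationVolume) -> np.ndarray:
    """Binary mask of voxels that touch a different segment ID.

    A voxel is marked iff at least one of its 6-neighbors carries a different
    ID; faces on the volume border count as having no neighbor there. The
    mask is symmetric: both sides of every ID change are marked. Background
    (ID 0) participates like any other label, so an unsaturated volume marks
    the segment/background interface on both sides as well.
    """
    lab = segmentation.labels
    mask = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = lab[tuple(lo)] != lab[tuple(hi)]
        mask[tuple(lo)] |= diff
        mask[tuple(hi)] |= diff
    return mask
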