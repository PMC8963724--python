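"""Synthetic cerebellar-molecular-layer volumes with planted ground truth.

The generator emulates the tissue geometry the detection pipeline was
designed for, on the same anisotropic 12 x 12 x 50 nm voxel grid:

* Parallel fibers (PF) are tubes running the full Z extent, densely packed
  as a jittered-grid Voronoi partition of the XY plane — so PF-PF interfaces
  (irrelevant contacts) are abundant, as in real tissue where PF bundles
  produce most contacts.
* Purkinje cells (PC) are laminae stacked along Z: a dendritic wall along
  one side of Y, split into one slab per PC at distinct Z positions, which
  reproduces the laminar organization PF-PC statistics rely on.
* Interneurons (IN) and climbing fibers (CF) reuse the tube geometry (a
  deliberately simplified stand-in for their arbors); INs are placed as an
  adjacent cluster with one member on the PC wall so that IN-IN and IN-PC
  interfaces exist, and CFs are placed on the wall for CF-PC interfaces.

Synapses are planted on randomly chosen relevant contacts; each planted
synapse gets an ellipsoidal vesicle-cloud blob rasterized strictly inside
the presynaptic fragment next to the contact. Oracle likelihood maps then
stand in for the voxel classifiers: the SC map is ~1 on planted contact
voxels and ~0 elsewhere, the VC map ~1 on the blobs, each degraded by
bounded additive noise. All randomness flows from a single seed.

Unplanted relevant contacts are the relevant-but-non-synaptic distractors,
and the packing geometry itself supplies irrelevant (e.g. PF-PF) contacts,
so the type-restriction and SVM stages are genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .candidates import ConnectivityRules, select_relevant_contacts
from .contacts import (
    Contact,
    _median_half_down,
    contact_location,
    extract_contacts,
    filter_small_contacts,
)
from .core import (
    CellType,
    CellTypeMap,
    GroundTruth,
    LikelihoodMap,
    SegmentationVolume,
    VoxelGeometry,
)

__all__ = [
    "SynthConfig",
    "PlantedSynapse",
    "GenerationError",
    "generate_neuropil",
    "oracle_sc_likelihood",
    "oracle_vc_likelihood",
    "planted_truth",
]


class GenerationError(RuntimeError):
    """Requested fragments or blobs cannot be packed into the volume."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    The defaults produce a 192 x 192 x 96 voxel volume (about 2.3 x 2.3 x
    4.8 um at the default pitch) holding 38 PF tubes, 3 PC laminae, 6 INs
    and 2 CFs, with 70% of relevant contacts carrying a planted synapse —
    roughly thirty synapses spanning all five connectable type pairs,
    matching the scale of one training subvolume of a real annotation
    effort. ``sc_noise``/``vc_noise`` bound
    the additive uniform noise on the oracle likelihood maps (0 = the
    noise-free correctness oracle). ``vc_blob_size`` is the target voxel
    count range of planted vesicle-cloud blobs; blobs are kept comfortably
    above the pipeline's 1000-voxel VC filter. ``min_contact_voxels`` should
    match the pipeline's small-contact filter so planting only targets
    contacts that survive it.
    """

    dims: tuple[int, int, int] = (192, 192, 96)
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    n_pf: int = 38
    n_pc: int = 3
    n_in: int = 6
    n_cf: int = 2
    synapse_rate: float = 0.7
    sc_noise: float = 0.0
    vc_noise: float = 0.0
    vc_blob_size: tuple[int, int] = (1400, 1900)
    pc_wall: int = 24
    min_contact_voxels: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synapse_rate < 0:
            raise ValueError("synapse_rate must be non-negative")
        if not (0.0 <= self.sc_noise <= 1.0 and 0.0 <= self.vc_noise <= 1.0):
            raise ValueError("noise levels must lie in [0, 1]")
        if self.n_pc < 1 or self.n_pf < 1:
            raise ValueError("need at least one PC lamina and one PF tube")


@dataclass
class PlantedSynapse:
    """Ground-truth record of one planted synapse.

    ``location`` is the median voxel of the planted contact; the blob
    arrays carry the exact voxels used by the oracle likelihood maps.
    """

    pre_segment: int
    post_segment: int
    location: tuple[int, int, int]
    vc_centroid: tuple[float, float, float]
    vc_size: int
    contact_voxels: np.ndarray
    vc_voxels: np.ndarray

    @property
    def pair(self) -> tuple[int, int]:
        a, b = sorted((self.pre_segment, self.post_segment))
        return (a, b)


def _tube_seeds(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid seed points for the tube Voronoi partition of XY."""
    nx, ny, _ = config.dims
    wall = config.pc_wall
    n_tubes = config.n_pf + config.n_in + config.n_cf
    width, height = nx, ny - wall
    if width < 16 or height < 16:
        raise GenerationError("volume too small to host a tube region")
    aspect = width / height
    gy = max(1, int(round(np.sqrt(n_tubes / aspect))))
    gx = int(np.ceil(n_tubes / gy))
    while gx * gy < n_tubes:
        gx += 1
    cell_w, cell_h = width / gx, height / gy
    if min(cell_w, cell_h) < 14:
        raise GenerationError(
            f"{n_tubes} tubes cannot be packed at >=14-voxel pitch into {width}x{height}"
        )
    cells = [(i, j) for j in range(gy) for i in range(gx)]
    chosen = rng.permutation(len(cells))[:n_tubes]
    seeds = np.empty((n_tubes, 2))
    for k, idx in enumerate(sorted(chosen)):
        i, j = cells[idx]
        seeds[k, 0] = (i + 0.5) * cell_w + rng.uniform(-0.2, 0.2) * cell_w
        seeds[k, 1] = wall + (j + 0.5) * cell_h + rng.uniform(-0.2, 0.2) * cell_h
    return seeds


def _assign_tube_types(
    labels: np.ndarray,
    tube_ids: np.ndarray,
    seeds: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> CellTypeMap:
    """Type each tube; CFs and one IN sit on the PC wall, INs cluster."""
    wall_row = labels[:, config.pc_wall, 0]
    wall_tubes = [int(t) for t in np.unique(wall_row)]
    need_on_wall = config.n_cf + (1 if config.n_in else 0)
    if len(wall_tubes) < need_on_wall + 1:
        raise GenerationError("too few tubes touch the PC wall for the requested CF/IN counts")

    types = CellTypeMap({int(pc): CellType.PC for pc in range(1, config.n_pc + 1)})
    remaining = set(int(t) for t in tube_ids)

    cf_ids = rng.choice(wall_tubes, size=config.n_cf, replace=False) if config.n_cf else []
    for t in cf_ids:
        types[int(t)] = CellType.CF
        remaining.discard(int(t))

    if config.n_in:
        in_candidates = [t for t in wall_tubes if t in remaining]
        in_seed = int(rng.choice(in_candidates))
        seed_xy = seeds[int(in_seed - tube_ids[0])]
        others = sorted(
            (t for t in remaining if t != in_seed),
            key=lambda t: float(np.sum((seeds[int(t - tube_ids[0])] - seed_xy) ** 2)),
        )
        in_ids = [in_seed] + [int(t) for t in others[: config.n_in - 1]]
        for t in in_ids:
            types[int(t)] = CellType.IN
            remaining.discard(int(t))

    for t in remaining:
        types[int(t)] = CellType.PF
    return types


def _paint_volume(config: SynthConfig, seeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize PC laminae and the tube Voronoi partition into a label grid."""
    nx, ny, nz = config.dims
    wall = config.pc_wall
    labels = np.zeros((nx, ny, nz), dtype=np.int32)

    # PC laminae: the dendritic wall y < wall split into n_pc slabs along z.
    z_edges = np.linspace(0, nz, config.n_pc + 1).astype(int)
    for j in range(config.n_pc):
        labels[:, :wall, z_edges[j]: z_edges[j + 1]] = j + 1

    # Tubes: nearest-seed assignment in the XY plane, extruded along z.
    tube_ids = np.arange(config.n_pc + 1, config.n_pc + 1 + seeds.shape[0], dtype=np.int32)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(wall, ny), indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    nearest = cKDTree(seeds).query(pts, k=1)[1]
    tube_plane = tube_ids[nearest].reshape(nx, ny - wall)
    labels[:, wall:, :] = tube_plane[:, :, None]
    return labels, tube_ids


def _choose_presynaptic(
    contact: Contact, types: CellTypeMap, rules: ConnectivityRules, rng: np.random.Generator
) -> int:
    a, b = contact.pair
    ta, tb = types[a], types[b]
    a_ok = rules.direction_allowed(ta, tb)
    b_ok = rules.direction_allowed(tb, ta)
    if a_ok and b_ok:
        return int(rng.choice([a, b]))
    if a_ok:
        return a
    if b_ok:
        return b
    raise GenerationError(f"contact pair {ta}-{tb} has no allowed direction")


def _plant_blob(
    labels: np.ndarray,
    contact: Contact,
    pre: int,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize an ellipsoidal vesicle-cloud blob inside the pre fragment.

    The blob is centered at an interior voxel (>= 2-3 voxels from the
    fragment boundary) as close as possible to the contact's presynaptic
    side, then clipped to the fragment so it can never cross a boundary.
    The interior-distance transform is computed on a local window around
    the contact; the padding exceeds every margin tested, so in-window
    values at or above those margins are exact.
    """
    dims = labels.shape

    pre_side = contact.voxels[labels[tuple(contact.voxels.T)] == pre]
    if pre_side.shape[0] == 0:
        raise GenerationError("contact has no voxels on the presynaptic side")
    c = np.array([_median_half_down(pre_side[:, axis]) for axis in range(3)])

    target = int(rng.integers(config.vc_blob_size[0], config.vc_blob_size[1] + 1))
    scale = (target / 1642.0) ** (1.0 / 3.0)
    radii = np.array([7.0, 7.0, 8.0]) * scale

    window, pad = 14, 8
    lo = np.maximum(c - window, 0)
    hi = np.minimum(c + window + 1, dims)
    plo = np.maximum(c - window - pad, 0)
    phi = np.minimum(c + window + pad + 1, dims)
    padded = tuple(slice(a, b) for a, b in zip(plo, phi))
    edt = ndimage.distance_transform_edt(labels[padded] == pre)
    inner = tuple(slice(a - pa, b - pa) for a, b, pa in zip(lo, hi, plo))
    center = None
    for margin in (4.0, 3.0, 2.0):
        cand = np.argwhere(edt[inner] >= margin)
        if cand.shape[0]:
            cand = cand + lo
            d2 = np.sum((cand - c) ** 2, axis=1)
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d2))
            center = cand[order[0]]
            break
    if center is None:
        raise GenerationError(f"no interior voxel near contact {contact.id} in fragment {pre}")

    for attempt in range(3):
        r = radii * (1.0 + 0.45 * attempt)
        blo = np.maximum((center - np.ceil(r)).astype(int), 0)
        bhi = np.minimum((center + np.ceil(r)).astype(int) + 1, dims)
        bsl = tuple(slice(a, b) for a, b in zip(blo, bhi))
        grid = np.mgrid[bsl].astype(float)
        ell = sum(((grid[i] - center[i]) / r[i]) ** 2 for i in range(3)) <= 1.0
        blob = np.argwhere(ell & (labels[bsl] == pre)) + blo
        if blob.shape[0] >= max(1050, int(0.55 * target)):
            return blob
    raise GenerationError(
        f"blob of {target} voxels cannot fit inside fragment {pre} near contact {contact.id}"
    )


def generate_neuropil(
    config: SynthConfig | None = None,
    rules: ConnectivityRules | None = None,
) -> tuple[SegmentationVolume, CellTypeMap, list[PlantedSynapse]]:
    """Generate a space-filling typed volume with planted synapses.

    Deterministic for a fixed ``config.seed``. The returned volume has no
    background, every planted synapse lies on a genuine inter-fragment
    interface between connectable types, and each planted vesicle blob is
    confined to its presynaptic fragment within matching distance of the
    contact.
    """
    config = config or SynthConfig()
    rules = rules or ConnectivityRules()
    rng = np.random.default_rng(config.seed)

    seeds = _tube_seeds(config, rng)
    labels, tube_ids = _paint_volume(config, seeds)
    types = _assign_tube_types(labels, tube_ids, seeds, config, rng)
    seg = SegmentationVolume(labels, config.geometry)

    contacts = filter_small_contacts(extract_contacts(seg), config.min_contact_voxels)
    relevant = select_relevant_contacts(contacts, types, rules)

    planted: list[PlantedSynapse] = []
    for contact in relevant:
        if rng.random() >= config.synapse_rate:
            continue
        pre = _choose_presynaptic(contact, types, rules, rng)
        post = contact.pair[0] if contact.pair[1] == pre else contact.pair[1]
        blob = _plant_blob(labels, contact, pre, config, rng)
        d = float(cKDTree(blob.astype(float)).query(contact.voxels.astype(float), k=1)[0].min())
        if d > 5.0:
            raise GenerationError(
                f"planted blob ended up {d:.1f} voxels from its contact (> 5)"
            )
        planted.append(
            PlantedSynapse(
                pre_segment=pre,
                post_segment=post,
                location=contact_location(contact),
                vc_centroid=tuple(blob.mean(axis=0)),
                vc_size=int(blob.shape[0]),
                contact_voxels=contact.voxels.copy(),
                vc_voxels=blob,
            )
        )
    return seg, types, planted


def oracle_sc_likelihood(
    segmentation: SegmentationVolume,
    planted: list[PlantedSynapse],
    config: SynthConfig | None = None,
) -> LikelihoodMap:
    """Stand-in for a voxel synaptic-contact classifier.

    Noise-free, planted contact voxels carry likelihood 1 and everything
    else 0 (non-synaptic boundary voxels included). Additive uniform noise
    bounded by ``sc_noise`` is then applied and the result clipped to
    [0, 1]. Off-boundary values are irrelevant to the pipeline, which only
    ever reads the map through contact masks.
    """
    config = config or SynthConfig()
    base = np.zeros(segmentation.dims, dtype=float)
    for p in planted:
        base[tuple(p.contact_voxels.T)] = 1.0
    if config.sc_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        base += rng.uniform(-config.sc_noise, config.sc_noise, size=base.shape)
        np.clip(base, 0.0, 1.0, out=base)
    return LikelihoodMap(base, role="SC")


def oracle_vc_likelihood(
    segmentation: SegmentationVolume,
    planted: list[PlantedSynapse],
    config: SynthConfig | None = None,
) -> LikelihoodMap:
    """Stand-in for a voxel vesicle-cloud classifier.

    Planted blobs carry likelihood 1 (they are rasterized strictly inside
    their presynaptic fragment, so boundary masking keeps each resulting VC
    single-host); background noise is bounded by ``vc_noise``.
    """
    config = config or SynthConfig()
    base = np.zeros(segmentation.dims, dtype=float)
    for p in planted:
        base[tuple(p.vc_voxels.T)] = 1.0
    if config.vc_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        base += rng.uniform(-config.vc_noise, config.vc_noise, size=base.shape)
        np.clip(base, 0.0, 1.0, out=base)
    return LikelihoodMap(base, role="VC")


def planted_truth(
    contacts: list[Contact], planted: list[PlantedSynapse]
) -> dict[int, GroundTruth]:
    """Ground-truth labels for extracted contacts from the planting record.

    Each planted synapse must match exactly one contact (same unordered
    pair, planted location among the contact's voxels); that contact is
    SYNAPTIC and every other contact in the list NON_SYNAPTIC. A planted
    synapse matching zero or several contacts indicates an inconsistent
    extraction and raises.
    """
    labels = {c.id: GroundTruth.NON_SYNAPTIC for c in contacts}
    for p in planted:
        loc = np.asarray(p.location)
        hits = [
            c.id
            for c in contacts
            if c.pair == p.pair and bool((c.voxels == loc).all(axis=1).any())
        ]
        if len(hits) != 1:
            raise ValueError(
                f"planted synapse at {p.location} matches {len(hits)} contacts; expected exactly 1"
            )
        labels[hits[0]] = GroundTruth.SYNAPTIC
    return labels
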