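"""Vesicle-cloud segmentation, candidate matching, and synapse assignment.

A vesicle cloud (VC) — the cluster of presynaptic neurotransmitter vesicles
— is segmented from the VC-likelihood map by a boundary-masked affinity
watershed: likelihood values are replicated onto the three lattice-edge
axes as affinities, edges crossing a neuronal boundary are zeroed so a VC
can never hang across two fragments, seed basins grow by hysteresis from a
high-affinity cut down to a low cut, and basins below a size threshold are
discarded as noise. A synapse candidate that has a VC within a small voxel
distance inside either of its two partner fragments is accepted as a
synapse; the fragment hosting that VC is the presynaptic side, and the
synapse is excitatory or inhibitory according to the presynaptic type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .candidates import EXCITATORY_PRE, INHIBITORY_PRE, ConnectivityRules
from .contacts import Contact
from .core import CellTypeMap, LikelihoodMap, SegmentationVolume

__all__ = [
    "VCConfig",
    "VesicleCloud",
    "Synapse",
    "AffinityGraph",
    "build_vc_affinity",
    "segment_vesicle_clouds",
    "match_vc",
    "assign_synapse",
]

logger = logging.getLogger(__name__)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class VCConfig:
    """Parameters of the VC stage.

    ``t_high``/``t_low`` are the hysteresis watershed cuts (seed basins need
    affinity >= t_high; basins grow down to t_low); ``min_basin`` removes
    tiny seed basins before growth. ``size_min`` is the final VC size filter
    (clouds with fewer voxels are discarded; the keep rule is inclusive,
    >= size_min). ``max_distance`` is the largest voxel-index-space Euclidean
    distance between a candidate contact and its nearest VC for the
    candidate to be accepted as a synapse — inclusive, so distance exactly
    ``max_distance`` still matches. ``strict_direction`` rejects a match
    whose implied presynaptic->postsynaptic type pair is not a connectable
    pair instead of emitting a flagged synapse.
    """

    t_high: float = 0.9
    t_low: float = 0.5
    min_basin: int = 100
    size_min: int = 1000
    max_distance: float = 5.0
    strict_direction: bool = False

    def __post_init__(self) -> None:
        if self.size_min < 0 or self.min_basin < 0:
            raise ValueError("size thresholds must be non-negative")
        if self.max_distance < 0:
            raise ValueError("max_distance must be non-negative")
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise ValueError("need 0 <= t_low <= t_high <= 1")


@dataclass
class VesicleCloud:
    """A connected high-VC-likelihood component confined to one fragment."""

    id: int
    voxels: np.ndarray  # (n, 3)
    host_segment: int

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class Synapse:
    """An accepted synaptic contact with direction, VC, and E/I class."""

    contact_id: int
    pre_segment: int
    post_segment: int
    vc_id: int
    distance: float
    synapse_class: str  # "EXCITATORY" | "INHIBITORY"
    direction_conflict: bool = False

    def __post_init__(self) -> None:
        if self.pre_segment == self.post_segment:
            raise ValueError("pre- and postsynaptic fragments must differ")


@dataclass
class AffinityGraph:
    """Edge-weighted 6-neighbor lattice over a volume.

    ``ax``/``ay``/``az`` hold the affinity of edges along each axis (shape
    reduced by one on that axis). References to the likelihood and
    segmentation the graph was built from are kept so the watershed can
    respect fragment boundaries.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    likelihood: np.ndarray
    labels: np.ndarray


def build_vc_affinity(
    vc_map: LikelihoodMap, segmentation: SegmentationVolume
) -> AffinityGraph:
    """Replicate the VC likelihood onto the three edge axes, masking boundaries.

    The affinity of an edge is the minimum likelihood of its two incident
    voxels; any edge whose endpoints lie in different segments is set to 0,
    which prevents a vesicle cloud from spanning two fragments.
    """
    if vc_map.dims != segmentation.dims:
        raise ValueError("likelihood map and segmentation dimensions differ")
    lik = vc_map.values
    lab = segmentation.labels
    edges = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        aff = np.minimum(lik[tuple(lo)], lik[tuple(hi)])
        aff[lab[tuple(lo)] != lab[tuple(hi)]] = 0.0
        edges.append(aff)
    return AffinityGraph(edges[0], edges[1], edges[2], lik, lab)


def segment_vesicle_clouds(
    affinity: AffinityGraph, config: VCConfig | None = None
) -> list[VesicleCloud]:
    """Hysteresis watershed of the boundary-masked affinity graph.

    Within each fragment, voxels at likelihood >= ``t_low`` form the growth
    region; 6-connected components of voxels at >= ``t_high`` (equivalently,
    of edges with affinity >= t_high, since boundary-crossing edges are
    zeroed) seed the basins; basins smaller than ``min_basin`` at seed stage
    are dropped; regions holding several seeds are split by a watershed on
    the negated likelihood. Clouds below ``size_min`` voxels are discarded.
    VC IDs are assigned in ascending (host segment, minimum linear voxel
    index) order.
    """
    config = config or VCConfig()
    lik = affinity.likelihood
    lab = affinity.labels
    lowmask = lik >= config.t_low
    highmask = lik >= config.t_high

    clouds: list[VesicleCloud] = []
    hosts = np.unique(lab[lowmask])
    for host in hosts:
        region_mask = lowmask & (lab == host)
        comp, n_comp = ndimage.label(region_mask, structure=_STRUCT6)
        if n_comp == 0:
            continue
        for obj_idx, sl in enumerate(ndimage.find_objects(comp), start=1):
            if sl is None:
                continue
            local = comp[sl] == obj_idx
            seeds, n_seeds = ndimage.label(local & highmask[sl], structure=_STRUCT6)
            if n_seeds == 0:
                continue
            # Drop sub-min_basin seed components.
            sizes = ndimage.sum_labels(np.ones_like(seeds), seeds, index=np.arange(1, n_seeds + 1))
            kept = [i + 1 for i, s in enumerate(sizes) if s >= config.min_basin]
            if not kept:
                continue
            if len(kept) == 1:
                basin_vox = np.argwhere(local)
                basins = [basin_vox]
            else:
                markers = np.where(np.isin(seeds, kept), seeds, 0)
                split = watershed(-lik[sl], markers=markers, mask=local, connectivity=1)
                basins = [np.argwhere(split == k) for k in kept]
            origin = np.array([s.start for s in sl])
            for bvox in basins:
                if bvox.shape[0] < config.size_min:
                    continue
                clouds.append(
                    VesicleCloud(id=-1, voxels=bvox + origin, host_segment=int(host))
                )

    dims = lab.shape
    clouds.sort(
        key=lambda v: (
            v.host_segment,
            int(((v.voxels[:, 0] * dims[1] + v.voxels[:, 1]) * dims[2] + v.voxels[:, 2]).min()),
        )
    )
    for i, v in enumerate(clouds):
        v.id = i
    return clouds


def match_vc(
    candidate: Contact,
    vcs: list[VesicleCloud],
    config: VCConfig | None = None,
    trees: dict[int, cKDTree] | None = None,
) -> tuple[int, float] | None:
    """Nearest eligible vesicle cloud of a synapse candidate.

    Only VCs hosted in either of the contact's two partner fragments are
    eligible. The distance is the minimum Euclidean distance in voxel-index
    units between any VC voxel and any contact voxel. Returns ``(vc_id,
    distance)`` for the closest eligible VC (ties toward the smaller vc_id),
    or ``None`` when the closest one is farther than ``max_distance``.

    ``trees`` optionally caches one KD-tree per vc_id across calls.
    """
    config = config or VCConfig()
    pair = set(candidate.pair)
    best: tuple[float, int] | None = None
    pts = candidate.voxels.astype(float)
    for vc in vcs:
        if vc.host_segment not in pair:
            continue
        if trees is not None:
            tree = trees.get(vc.id)
            if tree is None:
                tree = trees[vc.id] = cKDTree(vc.voxels.astype(float))
        else:
            tree = cKDTree(vc.voxels.astype(float))
        d = float(tree.query(pts, k=1)[0].min())
        if best is None or (d, vc.id) < best:
            best = (d, vc.id)
    if best is None or best[0] > config.max_distance:
        return None
    return best[1], best[0]


def assign_synapse(
    candidate: Contact,
    vc: VesicleCloud,
    types: CellTypeMap,
    rules: ConnectivityRules | None = None,
    distance: float = 0.0,
    strict_direction: bool = False,
) -> Synapse | None:
    """Direction and class assignment for a matched candidate.

    The fragment hosting the VC is presynaptic; the other partner is
    postsynaptic. The synapse class follows the excitatory (PF, CF) vs
    inhibitory (IN, PC) nature of the presynaptic type. If the implied
    (pre-type -> post-type) pair is not connectable, the synapse is emitted
    with ``direction_conflict=True`` — or rejected (``None`` returned, with
    a log entry) when ``strict_direction`` is set.
    """
    rules = rules or ConnectivityRules()
    if vc.host_segment not in candidate.pair:
        raise ValueError("vesicle cloud is hosted in neither partner of the contact")
    pre = vc.host_segment
    post = candidate.pair[0] if candidate.pair[1] == pre else candidate.pair[1]
    pre_type, post_type = types[pre], types[post]
    conflict = not rules.direction_allowed(pre_type, post_type)
    if conflict and strict_direction:
        logger.warning(
            "contact %d: VC-implied direction %s->%s is not connectable; match rejected",
            candidate.id,
            pre_type.value,
            post_type.value,
        )
        return None
    if pre_type in EXCITATORY_PRE:
        synapse_class = "EXCITATORY"
    elif pre_type in INHIBITORY_PRE:
        synapse_class = "INHIBITORY"
    else:
        raise ValueError(f"presynaptic type {pre_type} has no excitatory/inhibitory nature")
    return Synapse(
        contact_id=candidate.id,
        pre_segment=pre,
        post_segment=post,
        vc_id=vc.id,
        distance=float(distance),
        synapse_class=synapse_class,
        direction_conflict=conflict,
    )
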