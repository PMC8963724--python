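"""Structural and connectivity statistics over an accepted synapse table.

The synapse table is a pandas DataFrame with one row per accepted synapse,
carrying at least the columns ``contact_id, pre_seg, post_seg, pre_type,
post_type, synapse_class, vc_id, distance, area_um2, loc_x, loc_y, loc_z``
(locations are median contact voxels in index units). Everything here is
invariant under row permutation.

Median convention: whenever an even count forces a tie, the lower value
wins, matching the contact-location rule.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import CellType, CellTypeMap, SegmentationVolume

__all__ = [
    "synapse_table",
    "area_stats_by_type",
    "corrected_area",
    "synapse_density",
    "bouton_multiplicity",
    "laminar_profile",
    "intersynapse_intervals",
    "pf_pc_conditional_connectivity",
]

TABLE_COLUMNS = [
    "synapse_id",
    "contact_id",
    "pre_seg",
    "post_seg",
    "pre_type",
    "post_type",
    "synapse_class",
    "vc_id",
    "distance",
    "area_um2",
    "loc_x",
    "loc_y",
    "loc_z",
]


def synapse_table(synapses, contacts, types: CellTypeMap) -> pd.DataFrame:
    """Assemble the analysis table from pipeline outputs.

    ``synapses`` is a list of :class:`~emsyn.vesicles.Synapse`; ``contacts``
    the contact list they reference (areas in nm^2 are converted to um^2,
    locations are the contacts' median voxels).
    """
    from .contacts import contact_location

    by_id = {c.id: c for c in contacts}
    rows = []
    for i, s in enumerate(synapses):
        c = by_id[s.contact_id]
        loc = contact_location(c)
        rows.append(
            {
                "synapse_id": i,
                "contact_id": s.contact_id,
                "pre_seg": s.pre_segment,
                "post_seg": s.post_segment,
                "pre_type": types[s.pre_segment].value,
                "post_type": types[s.post_segment].value,
                "synapse_class": s.synapse_class,
                "vc_id": s.vc_id,
                "distance": s.distance,
                "area_um2": c.area_nm2 / 1e6,
                "loc_x": loc[0],
                "loc_y": loc[1],
                "loc_z": loc[2],
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def area_stats_by_type(table: pd.DataFrame) -> dict:
    """Median, quartiles, count and total synapse area per type pair and class.

    Areas are in um^2. Returned as
    ``{"by_pair": {"PF-PC": {...}, ...}, "by_class": {"EXCITATORY": {...}, ...},
    "total_area_um2": float}``; empty groups are simply absent.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty synapse table")

    def _summary(areas: pd.Series) -> dict:
        return {
            "n": int(areas.size),
            "median_um2": float(areas.median()),
            "q25_um2": float(areas.quantile(0.25)),
            "q75_um2": float(areas.quantile(0.75)),
            "total_um2": float(areas.sum()),
        }

    by_pair = {
        f"{pre}-{post}": _summary(g["area_um2"])
        for (pre, post), g in table.groupby(["pre_type", "post_type"], sort=True)
    }
    by_class = {
        cls: _summary(g["area_um2"]) for cls, g in table.groupby("synapse_class", sort=True)
    }
    return {
        "by_pair": by_pair,
        "by_class": by_class,
        "total_area_um2": float(table["area_um2"].sum()),
    }


def corrected_area(size_before: float, fraction: float) -> float:
    """Undo the contact-over-PSD overestimation of a synapse area.

    Contacts systematically overstate the synaptically relevant (PSD)
    area; the overestimation fraction is defined as
    ``(size_before - size_after) / size_after``, so the corrected area is
    ``size_before / (1 + fraction)``. A typical fraction of 0.20 turns a
    0.29 um^2 median contact area into about 0.24 um^2.
    """
    if fraction <= -1.0:
        raise ValueError("fraction must exceed -1")
    return size_before / (1.0 + fraction)


def synapse_density(table: pd.DataFrame, volume_um3: float) -> dict[str, float]:
    """Synapses per um^3 of analyzed volume, keyed by 'PRE-POST' type pair."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    if table.empty:
        return {}
    counts = table.groupby(["pre_type", "post_type"], sort=True).size()
    return {f"{pre}-{post}": float(n) / volume_um3 for (pre, post), n in counts.items()}


def bouton_multiplicity(table: pd.DataFrame) -> tuple[dict[int, int], float]:
    """Synapses-per-bouton histogram and multi-synaptic fraction.

    A vesicle cloud is the proxy of one bouton; grouping the table by
    ``vc_id`` counts the postsynaptic sites each bouton innervates. Returns
    ``(histogram {n_synapses: n_boutons}, fraction of boutons with >= 2)``.
    """
    if table.empty:
        return {}, 0.0
    if table["vc_id"].isna().any():
        raise ValueError("every synapse row must carry a vc_id")
    sizes = table.groupby("vc_id").size()
    hist = sizes.value_counts().sort_index()
    histogram = {int(k): int(v) for k, v in hist.items()}
    fraction_multi = float((sizes >= 2).sum()) / float(sizes.size)
    return histogram, fraction_multi


def _weighted_median_index(counts: np.ndarray) -> int:
    """Index of the lower-middle element of values repeated by ``counts``."""
    total = int(counts.sum())
    target = (total + 1) // 2  # rank of the lower-middle order statistic
    return int(np.searchsorted(np.cumsum(counts), target))


def laminar_profile(
    segmentation: SegmentationVolume,
    types: CellTypeMap,
    target_type: CellType = CellType.PC,
) -> dict:
    """Volume distribution of target-type fragments along the sectioning axis.

    For each fragment of ``target_type``: per-z-slice voxel counts, the
    median slice (lower-middle on ties) and its physical position in um.
    Fragments are ordered by median position; the gaps between consecutive
    medians estimate the laminar spacing.
    """
    lab = segmentation.labels
    dz_um = segmentation.geometry.dz / 1000.0
    frag_ids = [int(s) for s in segmentation.segment_ids() if types[int(s)] == target_type]
    if not frag_ids:
        raise ValueError(f"no fragment of type {target_type} in the volume")
    fragments = {}
    for seg_id in frag_ids:
        counts = (lab == seg_id).sum(axis=(0, 1))
        med = _weighted_median_index(counts)
        fragments[seg_id] = {
            "z_counts": counts,
            "median_slice": med,
            "median_um": med * dz_um,
        }
    ordered = sorted(frag_ids, key=lambda s: (fragments[s]["median_um"], s))
    medians = [fragments[s]["median_um"] for s in ordered]
    gaps = [float(b - a) for a, b in zip(medians, medians[1:])]
    return {"fragments": fragments, "ordered_ids": ordered, "adjacent_distances_um": gaps}


def intersynapse_intervals(
    table: pd.DataFrame,
    dz_nm: float = 50.0,
    pre_type: str = "PF",
    post_type: str = "PC",
) -> list[float]:
    """Z-gaps (um) between consecutive synapses of one presynaptic fragment.

    For every presynaptic fragment, its ``pre_type -> post_type`` synapse
    z-locations (median contact voxel times section thickness) are sorted
    and consecutive differences collected; fragments with fewer than two
    such synapses contribute nothing. Input row order is irrelevant.
    """
    sel = table[(table["pre_type"] == pre_type) & (table["post_type"] == post_type)]
    intervals: list[float] = []
    for _, g in sel.groupby("pre_seg"):
        z_um = np.sort(g["loc_z"].to_numpy(dtype=float)) * dz_nm / 1000.0
        intervals.extend(np.diff(z_um).tolist())
    return intervals


def pf_pc_conditional_connectivity(
    table: pd.DataFrame, pcs_ordered: list[int]
) -> pd.DataFrame:
    """P(PF connects to PC m+k | PF connects to PC m), averaged over m.

    Connectivity is at cell level: one or more synapses makes a PF-PC pair
    connected, multiplicity is ignored. For each laminar offset k >= 1 the
    fraction of PFs connected to both PC m and PC m+k, among those connected
    to PC m, is averaged over the valid m (laminae with no connected PF are
    skipped). Returns a DataFrame with columns ``k, mean, sem, n_m``; a flat
    profile means a PF innervates nearby PCs independently.
    """
    if len(pcs_ordered) < 2:
        return pd.DataFrame(columns=["k", "mean", "sem", "n_m"])
    sel = table[(table["pre_type"] == "PF") & (table["post_type"] == "PC")]
    connected = {
        pc: set(sel.loc[sel["post_seg"] == pc, "pre_seg"].tolist()) for pc in pcs_ordered
    }
    rows = []
    n_pc = len(pcs_ordered)
    for k in range(1, n_pc):
        fracs = []
        for m in range(n_pc - k):
            base = connected[pcs_ordered[m]]
            if not base:
                continue
            both = base & connected[pcs_ordered[m + k]]
            fracs.append(len(both) / len(base))
        if not fracs:
            continue
        mean = float(np.mean(fracs))
        sem = float(np.std(fracs, ddof=1) / math.sqrt(len(fracs))) if len(fracs) > 1 else float("nan")
        rows.append({"k": k, "mean": mean, "sem": sem, "n_m": len(fracs)})
    return pd.DataFrame(rows, columns=["k", "mean", "sem", "n_m"])
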