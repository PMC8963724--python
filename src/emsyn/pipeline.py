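"""End-to-end detection pipeline.

Stage order (each stage selects a subset of the previous one, so contact
counts fall monotonically along the funnel):

    saturate -> extract -> size filter -> type restriction -> SC features
    -> candidate selection (SVM + NHSCLV) -> VC segmentation -> VC matching
    -> direction / class assignment

`detect` runs everything downstream of the inputs; `train_from_truth` fits
the SCLSVM from a labelled volume (ambiguous contacts excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import synapse_table
from .candidates import (
    CandidateConfig,
    ConnectivityRules,
    SCLSVMModel,
    classify_candidates,
    compute_sc_features,
    score_contacts,
    select_relevant_contacts,
    train_sclsvm,
)
from .contacts import extract_contacts, fill_background, filter_small_contacts
from .core import CellTypeMap, GroundTruth, LikelihoodMap, SegmentationVolume
from .vesicles import VCConfig, assign_synapse, build_vc_affinity, match_vc, segment_vesicle_clouds

__all__ = ["PipelineConfig", "DetectionResult", "detect", "train_from_truth"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place; defaults are the printed operating
    point of the method (200-voxel contact filter, percentiles 95/85/99,
    SVM threshold -0.2, NHSCLV 400 @ 0.9, VC size 1000, match distance 5)."""

    min_contact_voxels: int = 200
    candidate: CandidateConfig = field(default_factory=CandidateConfig)
    vc: VCConfig = field(default_factory=VCConfig)
    rules: ConnectivityRules = field(default_factory=ConnectivityRules)


@dataclass
class DetectionResult:
    contacts: list  # all extracted contacts surviving the size filter
    relevant: list
    candidates: list
    vesicle_clouds: list
    synapses: list
    table: pd.DataFrame  # analysis-ready synapse table
    contact_extras: pd.DataFrame  # per relevant contact: features + decisions
    funnel: dict[str, int]


def _prepare_contacts(seg: SegmentationVolume, config: PipelineConfig):
    if not seg.is_saturated:
        logger.info("saturating background before contact extraction")
        seg = fill_background(seg)
    contacts = extract_contacts(seg)
    kept = filter_small_contacts(contacts, config.min_contact_voxels)
    return seg, contacts, kept


def train_from_truth(
    seg: SegmentationVolume,
    types: CellTypeMap,
    sc_map: LikelihoodMap,
    truth: dict[int, GroundTruth],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> SCLSVMModel:
    """Fit the SCLSVM from expert contact labels on a training volume.

    Features are computed for the labelled contacts (ambiguous ones are
    dropped); contact IDs in ``truth`` refer to the deterministic IDs
    assigned by extraction on this volume.
    """
    config = config or PipelineConfig()
    _, _, contacts = _prepare_contacts(seg, config)
    feats, labels = [], []
    for c in contacts:
        lbl = truth.get(c.id)
        if lbl is None or lbl == GroundTruth.AMBIGUOUS:
            continue
        feats.append(compute_sc_features(c, sc_map, config.candidate))
        labels.append(lbl == GroundTruth.SYNAPTIC)
    return train_sclsvm(feats, labels, seed=seed)


def detect(
    seg: SegmentationVolume,
    types: CellTypeMap,
    sc_map: LikelihoodMap,
    vc_map: LikelihoodMap,
    model: SCLSVMModel,
    config: PipelineConfig | None = None,
) -> DetectionResult:
    """Run the full funnel and return synapses plus every intermediate table."""
    config = config or PipelineConfig()
    if sc_map.dims != seg.dims or vc_map.dims != seg.dims:
        raise ValueError("likelihood map dimensions must match the segmentation")

    seg, all_contacts, contacts = _prepare_contacts(seg, config)
    relevant = select_relevant_contacts(contacts, types, config.rules)

    features = [compute_sc_features(c, sc_map, config.candidate) for c in relevant]
    scores, is_candidate = (
        score_contacts(features, model, config.candidate)
        if relevant
        else (np.zeros(0), np.zeros(0, dtype=bool))
    )
    candidates = classify_candidates(relevant, features, model, config.candidate)

    affinity = build_vc_affinity(vc_map, seg)
    vcs = segment_vesicle_clouds(affinity, config.vc)

    synapses = []
    trees: dict = {}
    match_info = {}
    for cand in candidates:
        m = match_vc(cand, vcs, config.vc, trees=trees)
        if m is None:
            continue
        vc_id, dist = m
        vc = vcs[vc_id]
        syn = assign_synapse(
            cand, vc, types, config.rules,
            distance=dist, strict_direction=config.vc.strict_direction,
        )
        if syn is not None:
            synapses.append(syn)
            match_info[cand.id] = (vc_id, dist)

    table = synapse_table(synapses, contacts, types)
    candidate_ids = {c.id for c in candidates}
    extras = pd.DataFrame(
        {
            "contact_id": [c.id for c in relevant],
            "p95": [f.p95 for f in features],
            "p_range": [f.p_range for f in features],
            "n_high": [f.n_high for f in features],
            "svm_score": scores,
            "is_candidate": [c.id in candidate_ids for c in relevant],
            "is_synapse": [c.id in match_info for c in relevant],
        }
    )
    funnel = {
        "contacts": len(all_contacts),
        "size_filtered": len(contacts),
        "relevant": len(relevant),
        "candidates": len(candidates),
        "vesicle_clouds": len(vcs),
        "synapses": len(synapses),
    }
    for stage, count in funnel.items():
        logger.info("funnel %-14s %6d", stage, count)
    return DetectionResult(
        contacts=contacts,
        relevant=relevant,
        candidates=candidates,
        vesicle_clouds=vcs,
        synapses=synapses,
        table=table,
        contact_extras=extras,
        funnel=funnel,
    )
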