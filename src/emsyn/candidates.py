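"""Cell-type restriction and SC-likelihood based synapse-candidate selection.

The molecular layer has only five connectable ordered type pairs
(CF->PC, PF->PC, PF->IN, IN->PC, IN->IN); a contact whose unordered type
pair is not among these is irrelevant and discarded outright. Remaining
contacts are scored from the distribution of synaptic-contact (SC)
likelihood over their voxels: a synaptic contact shows a distribution
narrowly peaked at high values, captured by two percentile features — the
95th percentile (bias toward high values) and the 99th minus 85th
percentile range (peak width). A two-feature SVM draws the decision
boundary; independently, a contact with at least ``nhsclv_count`` voxels at
likelihood >= ``high_cut`` is rescued as a candidate regardless of its SVM
score (the NHSCLV rule), which recovers synapses whose relevant zone is a
small part of a large contact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .contacts import Contact
from .core import CellType, CellTypeMap, LikelihoodMap

__all__ = [
    "ConnectivityRules",
    "ContactFeatures",
    "CandidateConfig",
    "SCLSVMModel",
    "select_relevant_contacts",
    "compute_sc_features",
    "train_sclsvm",
    "score_contacts",
    "classify_candidates",
]

DEFAULT_ALLOWED_PAIRS: tuple[tuple[CellType, CellType], ...] = (
    (CellType.CF, CellType.PC),
    (CellType.PF, CellType.PC),
    (CellType.PF, CellType.IN),
    (CellType.IN, CellType.PC),
    (CellType.IN, CellType.IN),
)

#: Neurotransmitter nature of each presynaptic type. Granule-cell axons (PF)
#: and climbing fibers (CF) are glutamatergic; molecular-layer interneurons
#: and Purkinje cells are GABAergic.
EXCITATORY_PRE = frozenset({CellType.PF, CellType.CF})
INHIBITORY_PRE = frozenset({CellType.IN, CellType.PC})


@dataclass(frozen=True)
class ConnectivityRules:
    """Allowed ordered (presynaptic -> postsynaptic) type pairs."""

    allowed: tuple[tuple[CellType, CellType], ...] = DEFAULT_ALLOWED_PAIRS

    def __post_init__(self) -> None:
        for pre, post in self.allowed:
            if CellType.OTHER in (pre, post):
                raise ValueError("OTHER fragments can never be connectable")

    @property
    def unordered(self) -> frozenset[frozenset[CellType]]:
        """Unordered type pairs used for the relevance restriction."""
        return frozenset(frozenset((a, b)) for a, b in self.allowed)

    def is_relevant(self, type_a: CellType, type_b: CellType) -> bool:
        return frozenset((type_a, type_b)) in self.unordered

    def direction_allowed(self, pre: CellType, post: CellType) -> bool:
        return (pre, post) in self.allowed


@dataclass(frozen=True)
class ContactFeatures:
    """Percentile summary of SC likelihood over one contact's voxels."""

    p95: float
    p_range: float  # 99th minus 85th percentile
    n_high: int  # voxels with likelihood >= high_cut

    def __post_init__(self) -> None:
        if not 0.0 <= self.p95 <= 1.0:
            raise ValueError("p95 must lie in [0, 1]")
        if self.p_range < 0:
            raise ValueError("percentile range cannot be negative")


@dataclass(frozen=True)
class CandidateConfig:
    """Thresholds of the candidate-selection stage.

    ``svm_threshold`` is in decision-function units of the trained model
    (standardized features), so the default -0.2 is meaningful only relative
    to a model trained the same way; it deliberately sits below the usual
    zero cut to trade false positives (removable later) for false negatives
    (unrecoverable). ``nhsclv_count``/``high_cut`` parameterize the
    voxel-count rescue rule: 400 or more voxels at likelihood 0.9 or higher.
    """

    svm_threshold: float = -0.2
    nhsclv_count: int = 400
    high_cut: float = 0.9
    percentiles: tuple[float, float, float] = (95.0, 85.0, 99.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.high_cut <= 1.0:
            raise ValueError("high_cut must lie in [0, 1]")
        if self.nhsclv_count < 0:
            raise ValueError("nhsclv_count must be non-negative")


def select_relevant_contacts(
    contacts: list[Contact],
    types: CellTypeMap,
    rules: ConnectivityRules | None = None,
) -> list[Contact]:
    """Keep exactly the contacts whose unordered type pair is connectable.

    Fragments missing from the type map are treated as OTHER (never
    relevant) with a warning. The output is a subset of the input, in input
    order; the operation is idempotent.
    """
    rules = rules or ConnectivityRules()
    missing: set[int] = set()
    out = []
    for c in contacts:
        a, b = c.pair
        for seg in (a, b):
            if seg not in types:
                missing.add(seg)
        if rules.is_relevant(types[a], types[b]):
            out.append(c)
    if missing:
        warnings.warn(
            f"{len(missing)} segment(s) without a type entry treated as OTHER",
            stacklevel=2,
        )
    return out


def compute_sc_features(
    contact: Contact, sc_map: LikelihoodMap, config: CandidateConfig | None = None
) -> ContactFeatures:
    """Percentile features of the SC likelihood masked to one contact.

    Percentiles use linear interpolation between order statistics and are
    computed over exactly the contact's (two-sided) voxel values; likelihood
    values off the contact are ignored entirely.
    """
    config = config or CandidateConfig()
    if contact.voxel_count < 1:
        raise ValueError("cannot compute features of an empty contact")
    vals = sc_map.values[tuple(contact.voxels.T)]
    p_hi, p_lo_rng, p_hi_rng = config.percentiles
    p95 = float(np.percentile(vals, p_hi))
    p_range = float(np.percentile(vals, p_hi_rng) - np.percentile(vals, p_lo_rng))
    n_high = int((vals >= config.high_cut).sum())
    return ContactFeatures(p95=p95, p_range=max(p_range, 0.0), n_high=n_high)


def _feature_matrix(features: list[ContactFeatures]) -> np.ndarray:
    return np.array([[f.p95, f.p_range] for f in features], dtype=float)


class SCLSVMModel:
    """SC-likelihood SVM over the (p95, p_range) plane.

    Wraps a standardize-then-SVC pipeline whose decision score is oriented
    positive toward the synaptic class. Only linear-kernel models are
    persisted to JSON: the decision function is then a plain affine map of
    the standardized features, and loading rebuilds it from those four
    parameter arrays without any library-internal state.
    """

    def __init__(
        self,
        pipeline: Pipeline | None,
        kernel: str,
        linear_params: dict | None = None,
    ):
        self._pipeline = pipeline
        self.kernel = kernel
        self._linear = linear_params
        if pipeline is None and linear_params is None:
            raise ValueError("a model needs either a fitted pipeline or linear parameters")

    def _linear_parameters(self) -> dict:
        if self._linear is not None:
            return self._linear
        if self.kernel != "linear":
            raise NotImplementedError("only linear-kernel models expose affine parameters")
        scaler: StandardScaler = self._pipeline.named_steps["scale"]
        svc: SVC = self._pipeline.named_steps["svm"]
        return {
            "scaler_mean": np.asarray(scaler.mean_, dtype=float),
            "scaler_scale": np.asarray(scaler.scale_, dtype=float),
            "coef": np.asarray(svc.coef_[0], dtype=float),
            "intercept": float(svc.intercept_[0]),
        }

    def score(self, features: list[ContactFeatures] | np.ndarray) -> np.ndarray:
        X = features if isinstance(features, np.ndarray) else _feature_matrix(features)
        if X.size == 0:
            return np.zeros(0)
        if self._pipeline is not None:
            return np.asarray(self._pipeline.decision_function(X), dtype=float)
        p = self._linear
        Z = (X - p["scaler_mean"]) / p["scaler_scale"]
        return Z @ p["coef"] + p["intercept"]

    def to_json(self) -> str:
        p = self._linear_parameters()
        return json.dumps(
            {
                "model": "sclsvm",
                "version": 1,
                "kernel": "linear",
                "features": ["p95", "p_range"],
                "scaler_mean": np.asarray(p["scaler_mean"]).tolist(),
                "scaler_scale": np.asarray(p["scaler_scale"]).tolist(),
                "coef": np.asarray(p["coef"]).tolist(),
                "intercept": float(p["intercept"]),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SCLSVMModel":
        doc = json.loads(text)
        if doc.get("model") != "sclsvm" or doc.get("kernel") != "linear":
            raise ValueError("not a persisted linear SCLSVM model")
        params = {
            "scaler_mean": np.asarray(doc["scaler_mean"], dtype=float),
            "scaler_scale": np.asarray(doc["scaler_scale"], dtype=float),
            "coef": np.asarray(doc["coef"], dtype=float),
            "intercept": float(doc["intercept"]),
        }
        return cls(None, "linear", linear_params=params)


def train_sclsvm(
    features: list[ContactFeatures],
    synaptic: list[bool] | np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> SCLSVMModel:
    """Fit the SCLSVM on labelled (p95, p_range) examples.

    ``synaptic`` holds one boolean per feature record; ambiguous contacts
    must be excluded by the caller. Training requires both classes and is
    deterministic for a fixed seed.
    """
    y = np.asarray(synaptic, dtype=int)
    X = _feature_matrix(features)
    if X.shape[0] != y.size:
        raise ValueError("one label per feature record is required")
    if np.unique(y).size < 2:
        raise ValueError("training requires at least one example of each class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    return SCLSVMModel(pipe, kernel)


def score_contacts(
    features: list[ContactFeatures], model: SCLSVMModel, config: CandidateConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SVM scores and candidate decisions for a list of feature records.

    A contact is a candidate iff ``score >= svm_threshold`` or
    ``n_high >= nhsclv_count`` — both thresholds inclusive, and the NHSCLV
    rule can rescue contacts far below the SVM threshold.
    """
    config = config or CandidateConfig()
    scores = model.score(features)
    n_high = np.array([f.n_high for f in features])
    is_candidate = (scores >= config.svm_threshold) | (n_high >= config.nhsclv_count)
    return scores, is_candidate


def classify_candidates(
    contacts: list[Contact],
    features: list[ContactFeatures],
    model: SCLSVMModel,
    config: CandidateConfig | None = None,
) -> list[Contact]:
    """Return the synapse-candidate subset of ``contacts`` (order preserved)."""
    if len(contacts) != len(features):
        raise ValueError("one feature record per contact is required")
    _, keep = score_contacts(features, model, config)
    return [c for c, k in zip(contacts, keep) if k]
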