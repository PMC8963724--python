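# Methods

This note documents the models, conventions, and numerical choices behind
`emsyn`, and what the synthetic benchmark does and does not establish.

## Data model and conventions

Volumes are arrays indexed `[x, y, z]` with `z` the sectioning axis. The
voxel pitch defaults to 12 × 12 × 50 nm: serial block-face SEM at 12 nm
lateral resolution and 50 nm nominal cutting thickness. Physical extents
are `dims_i · pitch_i / 1000` µm. Segment ID 0 is background
(unreconstructed space); every other ID is one neuronal fragment. Fragment
types come from a segment-ID → type table; IDs missing from the table are
`OTHER` (glia, unidentified processes) and can never take part in a
relevant contact.

Out-of-volume neighbors do not exist: a voxel on the volume border has no
neighbor across the border, so the border itself is never a segment
boundary. Medians of even-sized sets resolve ties toward the lower value,
everywhere (contact locations, laminar medians); this keeps every reported
location an actual voxel coordinate and makes all statistics reproducible
bit for bit.

## Background saturation

Contacts are defined on a saturated volume. `fill_background` assigns each
background voxel to its nearest segment with distance measured in physical
units (so the 50 nm sections weigh correctly), implemented as one Euclidean
distance transform per segment ID, ascending, with a strict comparison —
equidistant voxels therefore go to the smaller ID. This is O(#labels ·
volume); it is exact and deterministic, which we prioritized over the
single-pass nearest-site transform whose tie behavior is unspecified.

## Contact extraction

An interface voxel pair is two 6-neighbors with different IDs; collecting
both sides yields the two-voxel-thick contact voxel set of each unordered
segment pair. Per pair, voxels are grouped into connected components under
26-connectivity — a deliberate choice: thin oblique interfaces fragment
under 6- or 18-connectivity, and one anatomical apposition should be one
contact. Face counts are tallied once per interface voxel pair (not per
side) and assigned to the component containing the pair's lower voxel
(both voxels are 6-adjacent, hence always in the same component). Contact
IDs are assigned in ascending `(a, b, min linearized voxel index)` order so
repeated runs and different machines produce identical tables.

The 200-voxel noise filter counts the two-sided voxel set, and removal is
inclusive: a contact of exactly 200 voxels is dropped. Note the two-sided
voxel sets of *different* pairs can overlap along triple junctions (a voxel
can border two different neighbors); voxel sets of contacts of the same
pair are always disjoint.

## Candidate selection

Percentiles over a contact's SC-likelihood values use linear interpolation
between order statistics (NumPy's default); the convention matters only in
the tails of small contacts and is fixed for reproducibility. The SVM is a
linear-kernel SVC on standardized `(p95, p99−p85)` features, C = 1. A
linear kernel keeps the decision score a single interpretable margin axis;
with two features and a loosely separating gray zone there is no evidence a
curved boundary is needed, and the kernel is configurable. Because the
score scale depends on the fitted standardization, the decision threshold
(default −0.2) is configuration, not a constant — it is only meaningful for
a model trained with this package's feature pipeline. Both candidate rules
are inclusive (`score ≥ threshold`, `n_high ≥ 400` at `likelihood ≥ 0.9`)
and independent, so the NHSCLV rule can rescue a contact whose relevant
zone is a small fraction of a large interface. Candidate sets are monotone
in both thresholds by construction.

Only linear models are persisted (JSON of scaler mean/scale and the affine
decision coefficients); non-linear kernels would require serializing
support vectors and are out of scope.

## Vesicle clouds

The VC likelihood becomes a 6-neighbor affinity graph: an edge carries the
minimum of its two incident likelihoods, and edges crossing a segment
boundary are zeroed, so no cloud can span two fragments. Segmentation is a
hysteresis watershed: within one fragment, 6-connected components of
voxels at likelihood ≥ `t_high` (0.9) seed basins, seeds smaller than
`min_basin` (100) are noise, the growth region is likelihood ≥ `t_low`
(0.5), and regions holding several seeds are split by a watershed on the
negated likelihood. The three watershed parameters are exposed in
`VCConfig`; the defaults were chosen as conventional hysteresis settings
(seeds well above the growth cut, a noise floor an order of magnitude
below the final size filter). The final filter keeps clouds with ≥ 1 000
voxels (inclusive keep).

Candidate–cloud distance is Euclidean in voxel-index units, the minimum
over all (cloud voxel, contact voxel) pairs, computed with a KD-tree per
cloud. Index-space distance ignores anisotropy; at a 5-voxel threshold the
alternative physical-space reading would make the criterion ~20× tighter
along z, which contradicts how a cloud sitting a section away from its
contact should still match. Matching is per candidate — one cloud may
serve several candidates, which is exactly what multi-synaptic boutons
require. The match threshold is inclusive (distance ≤ 5 matches).

Direction: the cloud's host fragment is presynaptic. If the implied
(pre → post) type pair is not connectable the synapse is still emitted with
a `direction_conflict` flag by default (`strict_direction=False` follows
the permissive "either partner" matching rule); strict mode rejects it and
logs. Synapse class follows the presynaptic transmitter: PF and CF
(glutamatergic) → excitatory; IN and PC (GABAergic) → inhibitory.

## Evaluation

Ambiguous expert labels are excluded from TP/FP/FN entirely. Zero
denominators raise an explicit error rather than silently reporting zero;
`tp = 0` with nonzero denominators is the defined (0, 0) point, and
`F_β(0,0) = 0` by continuous extension. PR curves re-run the detector per
grid value; the best parameter maximizes F_β with ties resolved toward the
stricter setting. Reports round to three decimals.

## Connectivity statistics

Areas convert to µm² from face counts. The PSD-correction
`after = before / (1 + fraction)` inverts the overestimation fraction
definition `(before − after)/after`. Densities divide accepted-synapse
counts per type pair by the full analyzed volume in µm³ — counts, not
areas, and the accepted table, not ground truth. Bouton multiplicity
groups the synapse table by vesicle-cloud ID. Laminar profiles count
voxels per z-slice per PC and take the lower-middle weighted median slice.
Inter-synapse intervals sort each PF's PF→PC synapse z-locations and take
consecutive differences. Conditional connectivity is cell-level (≥ 1
synapse = connected, multiplicity ignored): for offset k the fraction of
PFs connected to both PC m and PC m+k among those connected to PC m,
averaged over m with the standard error across m; laminae with no
connected PF are skipped.

## Synthetic neuropil

The generator emulates what the pipeline consumes — labels and likelihoods
— not EM texture. Geometry: a PC "dendritic wall" occupies one side of the
y-axis, split into `n_pc` laminae along z; the rest of the cross-section is
a jittered-grid Voronoi partition extruded along the full z extent, giving
densely packed PF tubes (and, by reuse of the tube shape, IN and CF
fragments — a deliberate simplification of their arbors). CFs and one IN
are placed on tubes touching the wall and INs form an adjacent cluster, so
all five connectable pair types and the irrelevant PF–PF distractors occur.
The defaults (192 × 192 × 96 voxels, 38 PF / 3 PC / 6 IN / 2 CF, planting
rate 0.7) yield roughly thirty planted synapses per volume; the smaller
training volume (128 × 128 × 64) uses the same tissue statistics.

Each planted synapse marks one whole relevant contact as synaptic and
rasterizes an ellipsoidal vesicle blob (target 1 400–1 900 voxels, base
radii 7 × 7 × 8 scaled by the cube root of the target) strictly inside the
presynaptic fragment, centered on the interior voxel (boundary margin ≥ 2)
nearest the contact's presynaptic side; blobs that cannot reach a
comfortable size above the 1 000-voxel filter after clipping raise a
generation error rather than silently producing undetectable truth. Oracle
maps put likelihood 1 on planted contact voxels (SC) and blob voxels (VC),
0 elsewhere, then add uniform noise bounded by `sc_noise`/`vc_noise` and
clip to [0, 1]. All randomness flows from the single config seed.

What passing proves — and does not. Noise-free end-to-end recovery
(F1 = 1.0) and recovery under ±0.2 bounded noise validate the plumbing:
masking, component logic, feature computation, matching, and assignment
are internally consistent and the stages compose correctly. They do not
certify accuracy on real EM data: real likelihood maps have structured,
spatially correlated errors, contacts have irregular morphology, and the
expert ground truth contains ambiguous cases — none of which the uniform
noise model imitates. Accuracy figures on real tissue must come from real
annotated volumes.

## Problem sizes and determinism

Tests run the full pipeline at 192 × 192 × 96 (one noise-free seed and
five noisy seeds) and the unit suites at ≤ 96³, with brute-force
equivalence checks on ~110 randomized volumes up to 16³ — sizes chosen so
the whole suite completes in well under a minute per end-to-end run on one
CPU while still exercising every stage at meaningful density. Every
stochastic component takes an explicit seed; reruns are byte-identical.

## Known limitations

* The SVM threshold −0.2 is not transferable to models trained elsewhere;
  retune it on a PR curve for any new classifier or feature scaling.
* Contact area overestimates PSD area for elongated interfaces; only the
  scalar 20 %-typical correction is implemented, not per-contact PSD
  trimming.
* `fill_background` is exact but linear in the number of labels; for
  volumes with tens of thousands of fragments a coarser approximate
  saturation would be preferable.
* The generator's fragments are convex tubes and slabs; it cannot produce
  wrap-around contacts, spines, or concave interfaces.
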