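"""Connectivity-based parcellation of seed ROIs.

Pipeline per seed ROI: a target-labeled tractogram is rasterized into one
track-density image per target (streamlines counted once per voxel, full
path, masked to the seed ROI), each map is normalized by its mean intensity
over the seed ROI, and every seed voxel is assigned to the target whose
normalized map is largest (winner-take-all hard segmentation; voxels with
no streamline from any target stay unclassified).  Mean-normalization makes
the classification invariant to a global rescaling of any one target's
counts, so targets of very different sizes compete on comparable terms.

The two-step scheme parcellates the striatum against the cortical target
groups first, then uses the resulting striatal territories as the targets
for midbrain parcellation, so midbrain labels inherit striatal territory
names.

Group-level maximum probability maps keep, per label, the voxels carrying
that label in at least a threshold fraction of subjects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .phantom import TERRITORY_LABELS
from .tracking import Status, TrackingParams, seed_tractography

log = logging.getLogger(__name__)

UNCLASSIFIED = 0


@dataclass
class TargetDensityMap:
    """Per-target streamline count image restricted to seed-ROI voxels."""

    target: str
    counts: np.ndarray          # int volume, zero outside the seed ROI
    seed_roi: str = ""


@dataclass
class NormalizedDensityMap:
    target: str
    values: np.ndarray          # mean-normalized intensities over the seed ROI
    seed_roi: str = ""
    empty: bool = False         # all-zero source map: can never win a voxel


@dataclass
class Parcellation:
    """Hard voxel-to-label map over a seed ROI (0 = unclassified)."""

    labels: np.ndarray          # int volume
    seed_mask: np.ndarray       # bool volume
    label_names: tuple = TERRITORY_LABELS
    provenance: dict = dc_field(default_factory=dict)

    def volume(self, label):
        """Voxel count of one named parcel (or of 'unclassified')."""
        if label == "unclassified":
            return int(np.sum(self.seed_mask & (self.labels == UNCLASSIFIED)))
        k = self.label_names.index(label) + 1
        return int(np.sum(self.labels == k))

    @property
    def seed_volume(self):
        return int(self.seed_mask.sum())

    @property
    def unclassified_fraction(self):
        return self.volume("unclassified") / self.seed_volume

    def mask_of(self, label):
        k = self.label_names.index(label) + 1
        return self.labels == k


@dataclass
class MaxProbabilityMap:
    """Per-label subject-overlap counts over a group of parcellations."""

    counts: np.ndarray          # (K, X, Y, Z) ints in [0, n]
    n: int
    label_names: tuple
    threshold: float = 0.5

    def min_subjects(self, threshold=None):
        t = self.threshold if threshold is None else threshold
        return max(1, math.ceil(t * self.n))

    def thresholded(self, threshold=None):
        """Binary map per label: voxels labeled in >= ceil(threshold*n) subjects."""
        k = self.min_subjects(threshold)
        return {name: self.counts[i] >= k
                for i, name in enumerate(self.label_names)}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _rasterize_voxels(points, inv_affine, grid_shape):
    """Nearest-voxel indices of points plus segment midpoints (supersampled
    below voxel size so consecutive 1.25 mm steps cannot skip a voxel)."""
    mids = 0.5 * (points[:-1] + points[1:])
    pts = np.concatenate([points, mids]) if len(mids) else points
    idx = np.rint(pts @ inv_affine[:3, :3].T + inv_affine[:3, 3]).astype(np.int64)
    inb = np.all((idx >= 0) & (idx < np.array(grid_shape)), axis=1)
    return idx[inb]


def tdi_map(tractogram, seed_mask, endpoints_only=False):
    """Track-density map per target, masked by the binarized seed ROI.

    Only streamlines that reached a target contribute, each incrementing a
    voxel at most once along its full path (or only at its endpoint with
    ``endpoints_only``).  Returns ``{target_name: TargetDensityMap}``.
    """
    if len(tractogram) == 0:
        raise ValueError("tractogram is empty")
    shape = seed_mask.shape
    nvox = int(np.prod(shape))
    inv = np.linalg.inv(_tract_affine(tractogram, seed_mask))
    K = len(tractogram.target_names)
    maps = {name: np.zeros(shape, dtype=np.int64)
            for name in tractogram.target_names}
    reached = np.flatnonzero(tractogram.statuses == Status.REACHED_TARGET)
    for k in range(1, K + 1):
        sel = reached[tractogram.target_idx[reached] == k]
        if len(sel) == 0:
            continue
        pair_ids = []
        for j, i in enumerate(sel):
            pts = tractogram.points[i, : tractogram.lengths[i]]
            if endpoints_only:
                pts = pts[-1:]
            vox = _rasterize_voxels(pts, inv, shape)
            if len(vox):
                rav = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
                pair_ids.append(np.unique(rav) + j * nvox)
        if pair_ids:
            rav = np.concatenate(pair_ids) % nvox
            counts = np.bincount(rav, minlength=nvox).reshape(shape)
            maps[tractogram.target_names[k - 1]] = counts
    out = {}
    for name, counts in maps.items():
        out[name] = TargetDensityMap(
            target=name, counts=(counts * seed_mask).astype(np.int64),
            seed_roi=tractogram.seed_roi)
    return out


def _tract_affine(tractogram, seed_mask):
    # tractogram coordinates are mm in the same space as the seed volume;
    # the affine travels with the field, default identity
    a = getattr(tractogram, "affine", None)
    return np.eye(4) if a is None else np.asarray(a, float)


def normalize_map(tdm: TargetDensityMap, seed_mask) -> NormalizedDensityMap:
    """Divide each voxel's count by the mean count over all seed-ROI voxels.

    The mean is taken over *all* seed voxels (zeros included), so the output
    averages to one over the seed ROI.  An all-zero map passes through
    unchanged and is flagged: it can never win a voxel.
    """
    counts = tdm.counts.astype(float)
    mean = counts[seed_mask].mean()
    if mean <= 0:
        log.warning("density map for target %r is all-zero", tdm.target)
        return NormalizedDensityMap(tdm.target, counts, tdm.seed_roi, empty=True)
    return NormalizedDensityMap(tdm.target, counts / mean, tdm.seed_roi)


def classify(normalized_maps, seed_mask, label_names=None,
             provenance=None) -> Parcellation:
    """Winner-take-all hard segmentation of the seed ROI.

    Each seed voxel goes to the map with the highest normalized intensity;
    ties break to the lowest-index label in the fixed order; voxels where
    every map is zero stay unclassified.
    """
    if len(normalized_maps) < 2:
        raise ValueError("classification needs at least two target maps")
    if label_names is None:
        label_names = tuple(m.target for m in normalized_maps)
    shapes = {m.values.shape for m in normalized_maps}
    if len(shapes) != 1 or normalized_maps[0].values.shape != seed_mask.shape:
        raise ValueError("normalized maps and seed ROI have mismatched grids")
    stack = np.stack([m.values for m in normalized_maps])
    winner = np.argmax(stack, axis=0) + 1          # first max wins ties
    allzero = np.all(stack <= 0, axis=0)
    labels = np.where(seed_mask & ~allzero, winner, UNCLASSIFIED)
    labels = labels.astype(np.int16)
    return Parcellation(labels=labels, seed_mask=seed_mask,
                        label_names=tuple(label_names),
                        provenance=provenance or {})


def parcellate_seed(seed_mask, targets_vol, field, params, target_names,
                    seed_roi="", endpoints_only=False, provenance=None):
    """seed_tractography -> TDI -> mean-normalize -> winner-take-all."""
    tg = seed_tractography(seed_mask, targets_vol, field, params,
                           target_names=target_names, seed_roi=seed_roi)
    maps = tdi_map(tg, seed_mask, endpoints_only=endpoints_only)
    norm = [normalize_map(maps[name], seed_mask) for name in target_names]
    prov = dict(provenance or {})
    prov.update(seed_roi=seed_roi, n_streamlines=params.n_streamlines)
    return classify(norm, seed_mask, label_names=target_names,
                    provenance=prov), tg


def two_step_parcellate(striatum_mask, cortical_targets_vol, midbrain_mask,
                        field, params: TrackingParams,
                        label_names=TERRITORY_LABELS, endpoints_only=False,
                        provenance=None, return_tractograms=False):
    """Two-step scheme: striatum vs cortex, then midbrain vs striatal parcels.

    Step 1 parcellates the striatal seed against the cortical target groups;
    step 2 reuses the classified striatal parcels as target masks for the
    midbrain seed, so midbrain labels inherit the striatal territory names.
    A striatal parcel that came out empty is dropped from step 2 with a
    warning (its midbrain label then cannot occur).
    """
    for name, m in (("striatum", striatum_mask), ("midbrain", midbrain_mask)):
        if not m.any():
            raise ValueError(f"{name} seed ROI is empty")
    if np.any(striatum_mask & midbrain_mask) or np.any(
            (striatum_mask | midbrain_mask) & (cortical_targets_vol > 0)):
        raise ValueError("seed and target ROIs must be mutually disjoint")

    ss = np.random.SeedSequence(params.rng_seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))

    p1 = TrackingParams(**{**params.__dict__, "rng_seed": s1})
    striatal, tg1 = parcellate_seed(
        striatum_mask, cortical_targets_vol, field, p1, label_names,
        seed_roi="striatum", endpoints_only=endpoints_only,
        provenance=provenance)

    step2_targets = np.zeros_like(cortical_targets_vol)
    for k, lab in enumerate(label_names, start=1):
        parcel = striatal.labels == k
        if not parcel.any():
            log.warning("striatal parcel %r is empty; midbrain label %r "
                        "cannot occur", lab, lab)
            continue
        step2_targets[parcel] = k

    p2 = TrackingParams(**{**params.__dict__, "rng_seed": s2})
    midbrain, tg2 = parcellate_seed(
        midbrain_mask, step2_targets, field, p2, label_names,
        seed_roi="midbrain", endpoints_only=endpoints_only,
        provenance=provenance)

    if return_tractograms:
        return striatal, midbrain, tg1, tg2
    return striatal, midbrain


def build_mpm(parcellations, threshold=0.5) -> MaxProbabilityMap:
    """Group maximum probability map from per-subject parcellations.

    Per label and voxel, counts the subjects carrying that label; the
    thresholded map keeps voxels labeled in at least ``ceil(threshold * n)``
    subjects (with 50% this is 12/24 and 15/30).
    """
    if not parcellations:
        raise ValueError("no parcellations given")
    shapes = {p.labels.shape for p in parcellations}
    labelsets = {p.label_names for p in parcellations}
    if len(shapes) != 1:
        raise ValueError("parcellations are on mixed grids")
    if len(labelsets) != 1:
        raise ValueError("parcellations carry different label sets")
    names = parcellations[0].label_names
    counts = np.zeros((len(names),) + parcellations[0].labels.shape,
                      dtype=np.int32)
    for p in parcellations:
        for k in range(len(names)):
            counts[k] += (p.labels == k + 1)
    return MaxProbabilityMap(counts=counts, n=len(parcellations),
                             label_names=names, threshold=threshold)


def dice_score(a, b):
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.sum(a & b) / denom


def parcellation_dice(parc: Parcellation, truth_labels) -> dict:
    """Per-label Dice of a parcellation against a ground-truth label volume."""
    return {
        name: dice_score(parc.labels == k + 1, truth_labels == k + 1)
        for k, name in enumerate(parc.label_names)
    }
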