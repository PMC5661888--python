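"""From voxel probabilities to a 3-D nodule mask by slice propagation.

Given a user-supplied 2-D bounding box on one *starting slice*, every voxel
inside the box is classified, the probability map is thresholded (p >= 0.5
is nodule), and connected-component selection keeps the region nearest the
box centre. The same box is then applied to the preceding and subsequent
slices repeatedly; on each propagated slice the component nearest the
preceding slice's kept-region centroid is retained. Propagation in a
direction stops when (1) the selected component is empty or (2) the kept
area falls strictly below 30% of the preceding slice's kept area; the
violating slice is excluded.

Classifiers are anything with ``predict_voxels(volume, coords) -> probs``;
adapters wrap the trained network, a constant output, or the ground-truth
mask (the "oracle", which isolates the propagation logic from model
quality in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import GeometryError, SegmentationStartError
from .patches import PatchSpec, patch_arrays
from .volumes import BoundingBox2D, CtVolume, NoduleMask, clip_box

AREA_RATIO_STOP = 0.30
DEFAULT_THRESHOLD = 0.5


class CfcnnVoxelClassifier:
    """Adapter: per-voxel probabilities from a trained two-branch network."""

    def __init__(self, model, spec: PatchSpec = PatchSpec(), batch_size: int = 512):
        self.model = model
        self.spec = spec
        self.batch_size = batch_size

    def predict_voxels(self, volume: CtVolume, coords) -> np.ndarray:
        coords = list(coords)
        probs = np.empty(len(coords))
        for start in range(0, len(coords), self.batch_size):
            chunk = coords[start : start + self.batch_size]
            x3, x2 = patch_arrays(volume, chunk, self.spec)
            probs[start : start + len(chunk)] = self.model.predict_proba(x3, x2)[:, 1]
        return probs


class OracleVoxelClassifier:
    """Probabilities read straight off a ground-truth mask (p_in / p_out)."""

    def __init__(self, mask: NoduleMask, p_in: float = 1.0, p_out: float = 0.0):
        self.mask = mask
        self.p_in = p_in
        self.p_out = p_out

    def predict_voxels(self, volume: CtVolume, coords) -> np.ndarray:
        return np.array(
            [self.p_in if self.mask.labels[c] else self.p_out for c in map(tuple, coords)]
        )


class ConstantVoxelClassifier:
    def __init__(self, p: float):
        self.p = p

    def predict_voxels(self, volume: CtVolume, coords) -> np.ndarray:
        return np.full(len(list(coords)), self.p)


@dataclass
class ProbabilityMap:
    slice_index: int
    box: BoundingBox2D
    probs: np.ndarray  # (box rows, box cols), values in [0, 1]


@dataclass
class SegmentationResult:
    mask: NoduleMask
    per_slice_area: dict[int, int]
    stop_reason_up: str  # toward earlier slices
    stop_reason_down: str  # toward later slices
    start_box: BoundingBox2D
    probability_maps: dict[int, ProbabilityMap] = field(default_factory=dict)


def classify_slice(
    classifier,
    volume: CtVolume,
    box: BoundingBox2D,
    threshold: float = DEFAULT_THRESHOLD,
    slice_index: int | None = None,
) -> tuple[np.ndarray, ProbabilityMap]:
    """Binary full-plane mask for one slice: p >= threshold inside the box."""
    s = box.slice_index if slice_index is None else slice_index
    if not 0 <= s < volume.shape[0]:
        raise GeometryError(f"slice {s} outside volume of {volume.shape[0]} slices")
    cbox = clip_box(
        BoundingBox2D(s, box.row_start, box.row_stop, box.col_start, box.col_stop),
        volume.shape,
    )
    rows = np.arange(cbox.row_start, cbox.row_stop)
    cols = np.arange(cbox.col_start, cbox.col_stop)
    coords = [(s, int(r), int(c)) for r in rows for c in cols]
    probs = np.asarray(classifier.predict_voxels(volume, coords)).reshape(
        rows.size, cols.size
    )
    out = np.zeros(volume.shape[1:], dtype=np.uint8)
    out[cbox.row_start : cbox.row_stop, cbox.col_start : cbox.col_stop] = (
        probs >= threshold
    ).astype(np.uint8)
    return out, ProbabilityMap(slice_index=s, box=cbox, probs=probs)


def select_component(
    candidate: np.ndarray, context: str, reference: tuple[float, float]
) -> np.ndarray:
    """Keep the 8-connected in-plane component nearest the reference point.

    ``reference`` is the box centre for the starting slice, or the preceding
    slice's kept-region centroid during propagation. Ties on centroid
    distance keep the larger region, then the lower first-voxel linear
    index. An empty candidate passes through (it feeds the stop rule).
    """
    if context not in ("starting", "propagated"):
        raise GeometryError(f"unknown selection context {context!r}")
    candidate = np.asarray(candidate).astype(bool)
    if not candidate.any():
        return np.zeros_like(candidate, dtype=np.uint8)
    labels, n = measure.label(candidate, connectivity=2, return_num=True)
    if n == 1:
        return candidate.astype(np.uint8)
    ref = np.asarray(reference, dtype=float)
    ranked = []
    for lab in range(1, n + 1):
        comp = labels == lab
        coords = np.argwhere(comp)
        centroid = coords.mean(axis=0)
        d = float(np.hypot(*(centroid - ref)))
        first_index = int(coords[0][0] * candidate.shape[1] + coords[0][1])
        ranked.append((d, -coords.shape[0], first_index, lab))
    ranked.sort()
    return (labels == ranked[0][3]).astype(np.uint8)


def _centroid(mask2d: np.ndarray) -> tuple[float, float]:
    coords = np.argwhere(mask2d.astype(bool))
    return tuple(coords.mean(axis=0))  # type: ignore[return-value]


def propagate(
    classifier,
    volume: CtVolume,
    start_box: BoundingBox2D,
    threshold: float = DEFAULT_THRESHOLD,
) -> SegmentationResult:
    """Segment the starting slice, then walk outward slice by slice."""
    start_box = clip_box(start_box, volume.shape)
    s0 = start_box.slice_index
    cand, pmap0 = classify_slice(classifier, volume, start_box, threshold)
    kept = select_component(cand, "starting", start_box.center)
    if not kept.any():
        raise SegmentationStartError(
            "starting slice produced no nodule voxels "
            f"(max p = {pmap0.probs.max():.3f}, mean p = {pmap0.probs.mean():.3f}, "
            f"threshold = {threshold})"
        )
    mask = np.zeros(volume.shape, dtype=np.uint8)
    mask[s0] = kept
    areas = {s0: int(kept.sum())}
    pmaps = {s0: pmap0}

    stop_reasons = {}
    for direction, reason_key in ((-1, "up"), (+1, "down")):
        prev_area = areas[s0]
        prev_centroid = _centroid(kept)
        s = s0 + direction
        reason = "volume_end"
        while 0 <= s < volume.shape[0]:
            cand_s, pmap = classify_slice(
                classifier, volume, start_box, threshold, slice_index=s
            )
            sel = select_component(cand_s, "propagated", prev_centroid)
            if not sel.any():
                reason = "empty_slice"
                break
            area = int(sel.sum())
            if area < AREA_RATIO_STOP * prev_area:
                reason = "area_ratio"
                break
            mask[s] = sel
            areas[s] = area
            pmaps[s] = pmap
            prev_area = area
            prev_centroid = _centroid(sel)
            s += direction
        stop_reasons[reason_key] = reason

    return SegmentationResult(
        mask=NoduleMask(mask),
        per_slice_area=areas,
        stop_reason_up=stop_reasons["up"],
        stop_reason_down=stop_reasons["down"],
        start_box=start_box,
        probability_maps=pmaps,
    )


def segment(
    classifier,
    volume: CtVolume,
    start_box: BoundingBox2D,
    threshold: float = DEFAULT_THRESHOLD,
) -> SegmentationResult:
    """Full pipeline: classify inside the box, select, propagate in 3-D."""
    return propagate(classifier, volume, start_box, threshold)


def apply_area_stop_rule(areas: list[float], ratio: float = AREA_RATIO_STOP) -> int:
    """Number of kept slices when walking an area sequence in one direction.

    Pure helper for the stop rule: given candidate areas slice by slice
    (first entry = the starting slice, which is exempt from the ratio),
    returns how many are kept before an empty slice or a strict drop below
    ``ratio`` times the preceding kept area stops the walk. Exposed for
    direct testing of the rule's boundary behaviour.
    """
    kept = 0
    prev = None
    for area in areas:
        if area <= 0:
            break
        if prev is not None and area < ratio * prev:
            break
        if prev is None and kept == 0:
            prev = area  # the reference slice itself is exempt
            kept += 1
            continue
        prev = area
        kept += 1
    return kept
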