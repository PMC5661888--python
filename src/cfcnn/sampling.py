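"""Difficulty-weighted selection of training voxels.

Nodule voxels are a small minority of any CT slice, and uniformly drawn
background patches are dominated by easy dark lung field. Sampling is
therefore confined to an expanded per-slice bounding box (the tight nodule
box grown by 8 voxels on each side) and weighted by segmentation
difficulty:

* a **nodule** voxel i gets weight ``PW_i = exp(-min_{j in N} d(i, j)) / Z``
  where N is the non-nodule voxel set — nodule-edge voxels, which carry the
  boundary texture, are preferred over nodule-core voxels;
* a **background** voxel i gets ``NW_i = I_i * exp(-min_{j in P} d(i, j)) / Z``
  where P is the nodule voxel set and ``I_i`` is the box-min-max-normalised
  intensity — preferring bright structures hugging the nodule (wall,
  vessels) and suppressing the dark lung field.

Distances are 2-D within-slice Euclidean distances in voxel units; each
class's weights are normalised to sum to 1 per slice. From each slice, 40%
of its nodule voxels and the *same number* of background voxels are drawn
without replacement, so every sample set is class-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateClassError, DomainError
from .volumes import BoundingBox2D, clip_box

BOX_EXPANSION = 8  # voxels added on every side of the tight nodule box
DEFAULT_FRACTION = 0.40


@dataclass
class WeightMap:
    """Per-voxel sampling weights for one slice's expanded box."""

    slice_index: int
    expanded_box: BoundingBox2D
    pw: np.ndarray  # full-plane array, zero outside nodule voxels
    nw: np.ndarray  # full-plane array, zero outside box or on nodule voxels


@dataclass
class SampleSet:
    """Balanced labeled voxel coordinates drawn from weight maps."""

    samples: list[tuple[str, tuple[int, int, int], int]]
    seed: int
    warnings: list[str]

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.samples])

    def coords(self) -> list[tuple[int, int, int]]:
        return [c for _, c, _ in self.samples]


def expand_box(
    mask_slice: np.ndarray, slice_index: int = 0, expansion: int = BOX_EXPANSION
) -> BoundingBox2D:
    """Tight box of a slice's nodule voxels grown by ``expansion`` per side."""
    mask_slice = np.asarray(mask_slice).astype(bool)
    if mask_slice.ndim != 2:
        raise DomainError("mask slice must be 2-D")
    rows = np.flatnonzero(mask_slice.any(axis=1))
    cols = np.flatnonzero(mask_slice.any(axis=0))
    if rows.size == 0:
        raise DomainError("slice contains no nodule voxels")
    box = BoundingBox2D(
        slice_index=slice_index,
        row_start=int(rows[0]) - expansion,
        row_stop=int(rows[-1]) + 1 + expansion,
        col_start=int(cols[0]) - expansion,
        col_stop=int(cols[-1]) + 1 + expansion,
    )
    return clip_box(box, (slice_index + 1, *mask_slice.shape))


def _box_view(arr: np.ndarray, box: BoundingBox2D) -> np.ndarray:
    return arr[box.row_start : box.row_stop, box.col_start : box.col_stop]


def compute_nodule_weights(mask_slice: np.ndarray, box: BoundingBox2D) -> np.ndarray:
    """exp(-distance to nearest background) per nodule voxel, summing to 1.

    Distances are exact Euclidean distances to the nearest non-nodule voxel
    inside the expanded box.
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    sub = _box_view(mask_slice, box)
    n_nodule = int(sub.sum())
    if n_nodule == 0 or n_nodule == sub.size:
        raise DegenerateClassError("box must contain both nodule and background voxels")
    dist = ndimage.distance_transform_edt(sub)
    w = np.where(sub, np.exp(-dist), 0.0)
    w /= w.sum()
    out = np.zeros_like(mask_slice, dtype=float)
    _box_view(out, box)[...] = w
    return out


def compute_background_weights(
    mask_slice: np.ndarray, intensity_slice: np.ndarray, box: BoundingBox2D
) -> np.ndarray:
    """I_i * exp(-distance to nearest nodule voxel) per background voxel.

    ``I_i`` is the intensity min-max normalised over the expanded box; when
    the intensity factor annihilates every background voxel (a constant
    box, or a uniformly dark background where every voxel sits at the box
    minimum), the weights degenerate to purely distance-based ones.
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    sub = _box_view(mask_slice, box)
    n_nodule = int(sub.sum())
    if n_nodule == 0 or n_nodule == sub.size:
        raise DegenerateClassError("box must contain both nodule and background voxels")
    inten = _box_view(np.asarray(intensity_slice, dtype=float), box)
    lo, hi = inten.min(), inten.max()
    if hi > lo:
        norm = (inten - lo) / (hi - lo)
    else:
        norm = np.ones_like(inten)
    dist = ndimage.distance_transform_edt(~sub)
    w = np.where(~sub, norm * np.exp(-dist), 0.0)
    if w.sum() == 0:  # intensity factor wiped everything out
        w = np.where(~sub, np.exp(-dist), 0.0)
    w /= w.sum()
    out = np.zeros_like(mask_slice, dtype=float)
    _box_view(out, box)[...] = w
    return out


def build_weight_maps(volume, mask) -> list[WeightMap]:
    """One :class:`WeightMap` per slice of the mask that contains nodule."""
    maps = []
    for s in range(mask.labels.shape[0]):
        mslice = mask.labels[s].astype(bool)
        if not mslice.any():
            continue
        box = expand_box(mslice, slice_index=s)
        sub = _box_view(mslice, box)
        if sub.all():  # no background inside the box; cannot weight
            continue
        pw = compute_nodule_weights(mslice, box)
        nw = compute_background_weights(mslice, volume.voxels[s], box)
        maps.append(WeightMap(slice_index=s, expanded_box=box, pw=pw, nw=nw))
    return maps


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _draw_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k sequential probability-proportional draws (Gumbel keys).

    Sorting exponential(1)/w keys is equivalent to drawing items one at a
    time with probability proportional to their remaining weights.
    """
    support = np.flatnonzero(weights > 0)
    keys = rng.exponential(size=support.size) / weights[support]
    return support[np.argsort(keys)[:k]]


def sample_training_voxels(
    weight_maps: list[WeightMap],
    volume_id: str = "",
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
) -> SampleSet:
    """Balanced per-slice weighted draw of nodule and background voxels.

    Per slice, ``round(fraction * n_nodule_voxels)`` nodule voxels are drawn
    without replacement with probability proportional to PW, and the same
    number of background voxels proportionally to NW. Requests exceeding the
    available voxels are clamped with a warning record.
    """
    if not 0 < fraction <= 1:
        raise DomainError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    samples: list[tuple[str, tuple[int, int, int], int]] = []
    warnings: list[str] = []
    for wm in weight_maps:
        n_nodule = int((wm.pw > 0).sum())
        k = _round_half_away(fraction * n_nodule)
        if k == 0:
            continue
        n_bg = int((wm.nw > 0).sum())
        if k > n_bg:
            warnings.append(
                f"slice {wm.slice_index}: requested {k} background voxels, "
                f"only {n_bg} available; clamped"
            )
            k = n_bg
        shape = wm.pw.shape
        for field_arr, label in ((wm.pw, 1), (wm.nw, 0)):
            idx = _draw_without_replacement(field_arr.ravel(), k, rng)
            for flat in idx:
                r, c = divmod(int(flat), shape[1])
                samples.append((volume_id, (wm.slice_index, r, c), label))
    return SampleSet(samples=samples, seed=seed, warnings=warnings)


def sample_cohort(
    phantoms, fraction: float = DEFAULT_FRACTION, seed: int = 0
) -> SampleSet:
    """Weighted sampling across a list of phantoms, one sub-seed each."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(phantoms)) % (2**31 - 1)
    all_samples: list[tuple[str, tuple[int, int, int], int]] = []
    warnings: list[str] = []
    for ph, child in zip(phantoms, child_seeds):
        maps = build_weight_maps(ph.volume, ph.mask)
        sset = sample_training_voxels(
            maps, volume_id=ph.volume.volume_id, fraction=fraction, seed=int(child)
        )
        all_samples.extend(sset.samples)
        warnings.extend(sset.warnings)
    return SampleSet(samples=all_samples, seed=seed, warnings=warnings)
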