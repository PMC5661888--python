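"""Patch extraction for the two network branches.

For a target voxel the network sees two inputs:

* a **tri-slice 3-D patch**: the 35x35 axial neighbourhood on the target's
  slice plus the preceding and subsequent slices, stacked as three channels
  and z-scored jointly over all voxels of the patch;
* a **two-scale 2-D patch**: the 65x65 and 35x35 axial neighbourhoods of the
  target on its own slice, the large one downscaled to 35x35 by third-order
  spline interpolation, stacked as two channels.

Patches that reach past the volume border are completed by reflect padding
(mirroring without repeating the edge sample), in-plane and along the slice
axis alike.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .errors import ConfigError, GeometryError
from .volumes import CtVolume


@dataclass(frozen=True)
class PatchSpec:
    """Geometry and normalisation settings for patch extraction."""

    size_2d: int = 35
    size_2d_large: int = 65
    n_slices: int = 3
    pad_mode: str = "reflect"
    spline_order: int = 3
    normalize_2d: bool = True

    def __post_init__(self) -> None:
        if self.size_2d % 2 == 0 or self.size_2d_large % 2 == 0:
            raise ConfigError("patch sizes must be odd")
        if self.size_2d_large <= self.size_2d:
            raise ConfigError("large patch must exceed the native patch size")
        if self.n_slices % 2 == 0:
            raise ConfigError("n_slices must be odd")


@dataclass
class PatchPair:
    """The two branch inputs for one target voxel."""

    three_d: np.ndarray  # (n_slices, size_2d, size_2d), z-scored
    two_d: np.ndarray  # (2, size_2d, size_2d): [rescaled large, native]
    target: tuple[int, int, int]
    x_mean: float
    x_std: float


def zscore(patch: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Joint z-score f(x) = (x - mean) / std; a constant patch maps to zeros.

    "Constant" is judged relative to the patch's magnitude so that float
    round-off on a flat region is not amplified into O(1) noise.
    """
    mean = float(patch.mean())
    std = float(patch.std())
    if std <= 1e-10 * max(1.0, abs(mean)):
        return np.zeros_like(patch, dtype=float), mean, std
    return (patch - mean) / std, mean, std


def _check_voxel(volume: CtVolume, voxel) -> tuple[int, int, int]:
    s, r, c = (int(v) for v in voxel)
    ns, nr, nc = volume.shape
    if not (0 <= s < ns and 0 <= r < nr and 0 <= c < nc):
        raise GeometryError(f"voxel {(s, r, c)} outside volume of shape {volume.shape}")
    return s, r, c


def _crop_reflect(arr: np.ndarray, center: tuple[int, ...], half: tuple[int, ...]) -> np.ndarray:
    """Crop a (2h+1)-per-axis window around ``center``, reflect-padding as needed."""
    pads = []
    slices = []
    for ax, (c, h) in enumerate(zip(center, half)):
        lo = c - h
        hi = c + h + 1
        pad_lo = max(0, -lo)
        pad_hi = max(0, hi - arr.shape[ax])
        pads.append((pad_lo, pad_hi))
        slices.append(slice(lo + pad_lo, hi - pad_hi))
    window = arr[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        window = np.pad(window, pads, mode="reflect")
    return window


def extract_3d_patch(volume: CtVolume, voxel, spec: PatchSpec = PatchSpec()) -> np.ndarray:
    """The z-scored tri-slice patch (n_slices, size, size) centred on ``voxel``."""
    s, r, c = _check_voxel(volume, voxel)
    h2 = spec.size_2d // 2
    hs = spec.n_slices // 2
    raw = _crop_reflect(volume.voxels, (s, r, c), (hs, h2, h2)).astype(float)
    normed, _, _ = zscore(raw)
    return normed


@lru_cache(maxsize=None)
def _spline_operator(n: int, out_size: int, order: int) -> np.ndarray:
    """The (out_size, n) matrix applying 1-D interpolating-spline resampling.

    Spline interpolation at fixed sample positions is linear in the data, so
    the whole axis resampling collapses to one matrix built column-by-column
    from unit impulses. Output sample k lies at input coordinate
    k*(n-1)/(out_size-1): the grids share both endpoints and (for odd sizes)
    the centre sample, so the target voxel stays at the patch centre.
    """
    grid = np.arange(n, dtype=float)
    coords = np.linspace(0.0, n - 1.0, out_size)
    op = np.empty((out_size, n))
    impulse = np.zeros(n)
    for i in range(n):
        impulse[:] = 0.0
        impulse[i] = 1.0
        op[:, i] = InterpolatedUnivariateSpline(grid, impulse, k=order)(coords)
    return op


def _rescale_2d(patch: np.ndarray, out_size: int, order: int) -> np.ndarray:
    """Resample a square patch to ``out_size`` with an interpolating spline.

    The tensor-product interpolating spline (not-a-knot boundaries)
    reproduces polynomial fields up to the spline order exactly, everywhere
    including the patch border; applied as two cached matrix products.
    """
    op = _spline_operator(patch.shape[0], out_size, order)
    return op @ patch.astype(float) @ op.T


def extract_2d_multiscale_patch(
    volume: CtVolume, voxel, spec: PatchSpec = PatchSpec()
) -> np.ndarray:
    """The two-channel multi-scale axial patch (2, size, size) for ``voxel``.

    Channel 0 is the large-context patch after spline downscaling, channel 1
    the native patch; each channel is z-scored independently when
    ``spec.normalize_2d`` is set.
    """
    s, r, c = _check_voxel(volume, voxel)
    plane = volume.voxels[s]
    h_small = spec.size_2d // 2
    h_large = spec.size_2d_large // 2
    small = _crop_reflect(plane, (r, c), (h_small, h_small)).astype(float)
    large = _crop_reflect(plane, (r, c), (h_large, h_large))
    rescaled = _rescale_2d(large, spec.size_2d, spec.spline_order)
    channels = [rescaled, small]
    if spec.normalize_2d:
        channels = [zscore(ch)[0] for ch in channels]
    return np.stack(channels)


def extract_patch_pair(
    volume: CtVolume, voxel, spec: PatchSpec = PatchSpec()
) -> PatchPair:
    s, r, c = _check_voxel(volume, voxel)
    h2 = spec.size_2d // 2
    hs = spec.n_slices // 2
    raw = _crop_reflect(volume.voxels, (s, r, c), (hs, h2, h2)).astype(float)
    normed, mean, std = zscore(raw)
    two_d = extract_2d_multiscale_patch(volume, voxel, spec)
    return PatchPair(
        three_d=normed, two_d=two_d, target=(s, r, c), x_mean=mean, x_std=std
    )


def batch_patches(
    volume: CtVolume, voxels, spec: PatchSpec = PatchSpec()
) -> list[PatchPair]:
    """Order-preserving batch extraction; equals per-voxel extraction."""
    return [extract_patch_pair(volume, v, spec) for v in voxels]


def patch_arrays(
    volume: CtVolume, voxels, spec: PatchSpec = PatchSpec(), dtype=np.float32
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (N, n_slices, s, s) and (N, 2, s, s) arrays for a voxel list.

    Memory-lean variant of :func:`batch_patches` for training/inference;
    float32 by default since stored patch banks dominate memory.
    """
    voxels = list(voxels)
    n = len(voxels)
    x3 = np.empty((n, spec.n_slices, spec.size_2d, spec.size_2d), dtype=dtype)
    x2 = np.empty((n, 2, spec.size_2d, spec.size_2d), dtype=dtype)
    for i, v in enumerate(voxels):
        x3[i] = extract_3d_patch(volume, v, spec)
        x2[i] = extract_2d_multiscale_patch(volume, v, spec)
    return x3, x2
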