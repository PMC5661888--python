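"""Segmentation agreement metrics and consensus ground-truth fusion.

For a ground-truth mask Gt and an automatic mask Auto (V counts voxels):

* ``DSC  = 2 V(Gt & Auto) / (V(Gt) + V(Auto))`` — dice similarity;
* ``O    = V(Gt & Auto) / V(Gt | Auto)`` — Jaccard overlap;
* ``SEN  = V(Gt & Auto) / V(Gt)``, ``PPV = V(Gt & Auto) / V(Auto)``;
* ``ASD`` — symmetric average surface distance in millimetres: the mean of
  the two directed mean minimum distances between surface voxels, where a
  surface voxel has at least one 6-neighbour outside its mask and
  voxel-centre coordinates are scaled by the (possibly anisotropic) spacing.

Multi-rater ground truth uses the 50% consensus criterion: a voxel is
nodule when at least half of the raters marked it (exact halves included).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigError, GeometryError, UndefinedMetricError
from .volumes import NoduleMask


def _as_bool(mask: NoduleMask | np.ndarray) -> np.ndarray:
    arr = mask.labels if isinstance(mask, NoduleMask) else np.asarray(mask)
    return arr.astype(bool)


def _check_pair(gt, auto) -> tuple[np.ndarray, np.ndarray]:
    g, a = _as_bool(gt), _as_bool(auto)
    if g.shape != a.shape:
        raise GeometryError(f"mask shapes differ: {g.shape} vs {a.shape}")
    return g, a


def dice(gt, auto) -> float:
    """Dice similarity coefficient 2|Gt & Auto| / (|Gt| + |Auto|)."""
    g, a = _check_pair(gt, auto)
    denom = int(g.sum()) + int(a.sum())
    if denom == 0:
        raise UndefinedMetricError("dice undefined for two empty masks")
    return 2.0 * int((g & a).sum()) / denom


def jaccard_overlap(gt, auto) -> float:
    """Jaccard overlap |Gt & Auto| / |Gt | Auto|."""
    g, a = _check_pair(gt, auto)
    union = int((g | a).sum())
    if union == 0:
        raise UndefinedMetricError("overlap undefined for two empty masks")
    return int((g & a).sum()) / union


def sensitivity_ppv(gt, auto) -> tuple[float, float]:
    """(SEN, PPV) = (|Gt & Auto|/|Gt|, |Gt & Auto|/|Auto|)."""
    g, a = _check_pair(gt, auto)
    n_gt, n_auto = int(g.sum()), int(a.sum())
    if n_gt == 0:
        raise UndefinedMetricError("SEN undefined: ground truth is empty")
    if n_auto == 0:
        raise UndefinedMetricError("PPV undefined: automatic mask is empty")
    inter = int((g & a).sum())
    return inter / n_gt, inter / n_auto


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask 6-neighbour (borders count)."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return m & ~eroded


def asd(gt, auto, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average surface distance in millimetres."""
    g, a = _check_pair(gt, auto)
    if not g.any() or not a.any():
        raise UndefinedMetricError("ASD undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pts_g = np.argwhere(surface_voxels(g)) * spacing
    pts_a = np.argwhere(surface_voxels(a)) * spacing
    d_g_to_a = cKDTree(pts_a).query(pts_g)[0]
    d_a_to_g = cKDTree(pts_g).query(pts_a)[0]
    return 0.5 * (float(d_g_to_a.mean()) + float(d_a_to_g.mean()))


def consensus_mask(rater_masks: list[NoduleMask]) -> NoduleMask:
    """Voxels marked by at least 50% of raters (exact halves included)."""
    if len(rater_masks) == 0:
        raise ConfigError("need at least one rater mask")
    arrs = [_as_bool(m) for m in rater_masks]
    shape = arrs[0].shape
    for m in arrs[1:]:
        if m.shape != shape:
            raise GeometryError("rater masks must share one shape")
    votes = np.sum(arrs, axis=0)
    return NoduleMask((votes * 2 >= len(arrs)).astype(np.uint8))


def metrics_report(gt, auto, spacing=(1.0, 1.0, 1.0)) -> dict:
    """All five metrics for one case, as a plain dict."""
    g, a = _check_pair(gt, auto)
    return {
        "dsc": dice(g, a),
        "jaccard": jaccard_overlap(g, a),
        "sen": sensitivity_ppv(g, a)[0],
        "ppv": sensitivity_ppv(g, a)[1],
        "asd_mm": asd(g, a, spacing),
        "n_gt_voxels": int(g.sum()),
        "n_auto_voxels": int(a.sum()),
    }


def evaluate_cohort(results, gts, spacings) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case metric table plus a mean / sd (sample, n-1) summary.

    ``results`` may be SegmentationResult objects or plain masks.
    """
    if not (len(results) == len(gts) == len(spacings)):
        raise ConfigError("results, ground truths and spacings must align")
    if len(results) == 0:
        raise ConfigError("empty cohort")
    rows = []
    for i, (res, gt, spacing) in enumerate(zip(results, gts, spacings)):
        auto = getattr(res, "mask", res)
        rows.append({"case": i, **metrics_report(gt, auto, spacing)})
    table = pd.DataFrame(rows)
    metric_cols = ["dsc", "jaccard", "sen", "ppv", "asd_mm"]
    summary = pd.DataFrame(
        {"mean": table[metric_cols].mean(), "sd": table[metric_cols].std(ddof=1)}
    )
    return table, summary
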