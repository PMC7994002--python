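"""Label smoothing: Gaussian baseline, adaptive morphological opening, and
signed-distance interpolation of edited contours.

Atlases annotated plane-by-plane show jagged, high-frequency label borders in
the orthogonal viewing directions.  Two smoothers are provided:

* a Gaussian baseline that blurs each label's indicator and re-binarizes it —
  simple, but it drops sparsely populated or fragmented labels;
* an adaptive morphological opening that halves its structuring element for
  small labels (≤ 5000 voxels) and falls back to a closing when a label would
  vanish, guaranteeing zero label loss.

Labels are processed largest to smallest on a single working volume, so later
(smaller) labels overwrite earlier gap fills; vacated foreground voxels are
re-assigned to their nearest surviving label at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .morph import ball_closing, ball_dilation, ball_erosion, ball_opening
from .volumes import LabelVolume, nearest_label_fill

__all__ = [
    "SmoothParams",
    "SmoothRecord",
    "gaussian_label_smoothing",
    "adaptive_morph_smoothing",
    "smooth_labels",
    "interpolate_label_between_planes",
    "records_frame",
]


@dataclass
class SmoothParams:
    """Smoothing configuration.

    ``size`` is the structuring-element *radius* in voxels for the adaptive
    mode; ``sigma`` the Gaussian sigma in voxels.  ``rebinarize_threshold``
    is the support level at which the blurred indicator is re-binarized.  It
    is a low floor (0.0025) rather than 0.5: at the sub-voxel sigmas used for
    this baseline a 0.5 threshold degenerates to the exact identity (the
    discrete kernel is nearly a delta), whereas a support floor keeps every
    voxel the blur reaches with non-negligible mass.  Labels processed in
    sequence then fill their interior pinholes and absorb stray fragments
    embedded in them — the documented failure mode of the Gaussian baseline
    (sparse labels lost even at sigma 0.25, loss increasing with sigma) —
    while convex smooth shapes are barely moved at small sigma.
    """

    mode: str = "adaptive_opening"  # or "gaussian"
    sigma: float = 0.5
    size: int = 3
    small_label_px: int = 5000
    iterations: int = 2
    rebinarize_threshold: float = 0.0025

    def __post_init__(self):
        if self.sigma < 0 or self.size < 0 or self.small_label_px < 0:
            raise ValueError("sigma, size and small_label_px must be >= 0")
        if self.mode not in ("gaussian", "adaptive_opening"):
            raise ValueError(f"unknown smoothing mode {self.mode}")


@dataclass
class SmoothRecord:
    label_id: int
    filter_applied: str  # opening | opening_halved | closing | gaussian | none
    n_before: int
    n_after: int

    @property
    def lost(self) -> bool:
        return self.n_after == 0


def records_frame(records: list[SmoothRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(label_id=r.label_id, filter=r.filter_applied,
              n_before=r.n_before, n_after=r.n_after) for r in records]
    )


def _label_bbox(mask: np.ndarray, pad: int, shape) -> tuple[slice, ...]:
    obj = ndimage.find_objects(mask.astype(np.uint8))[0]
    return tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, n))
        for s, n in zip(obj, shape)
    )


def smooth_labels(
    labels: LabelVolume, params: SmoothParams
) -> tuple[LabelVolume, list[SmoothRecord]]:
    """Smooth every label in place on a working copy, largest to smallest.

    Each label is extracted within its bounding box padded by the filter
    radius + 1 (the minimum that prevents clipping of dilation), filtered,
    and written back: vacated voxels are cleared, gained voxels overwrite.
    After all labels are processed, foreground voxels left unlabeled are
    in-painted from their nearest surviving label.  Loss is recorded, and in
    adaptive mode prevented by the halving/closing fallbacks.
    """
    out = labels.data.copy()
    orig_fg = labels.data != 0
    ids, counts = np.unique(labels.data[orig_fg], return_counts=True)
    order = np.argsort(-counts)
    filters_applied: dict[int, str] = {}
    n_before: dict[int, int] = {}
    for i in order:
        lid = int(ids[i])
        mask_full = out == lid
        n0 = int(mask_full.sum())
        n_before[lid] = int(counts[i])
        if n0 == 0:
            filters_applied[lid] = "none"
            continue
        if params.mode == "gaussian":
            pad = int(np.ceil(4 * params.sigma * np.sqrt(max(params.iterations, 1)))) + 1
        else:
            pad = params.size + 1
        box = _label_bbox(mask_full, pad, out.shape)
        mask = mask_full[box]
        if params.mode == "gaussian":
            if params.sigma == 0:
                filters_applied[lid] = "none"
                continue
            blurred = mask.astype(float)
            for _ in range(max(params.iterations, 1)):
                blurred = ndimage.gaussian_filter(blurred, params.sigma)
            sm = blurred > params.rebinarize_threshold
            if not sm.any():
                sm = mask  # never let the floor itself erase a label outright
            filters_applied[lid] = "gaussian"
        else:
            size = params.size
            if size == 0:
                filters_applied[lid] = "none"
                continue
            name = "opening"
            if n0 <= params.small_label_px:
                size = max(size // 2, 1)
                name = "opening_halved"
            sm = ball_opening(mask, size)
            if not sm.any():
                sm = ball_closing(mask, size)
                name = "closing"
            filters_applied[lid] = name
        region = out[box]
        region[mask & ~sm] = 0
        region[sm] = lid
    # refill vacated foreground from nearest surviving labels
    gaps = orig_fg & (out == 0)
    if gaps.any() and (out != 0).any():
        out = nearest_label_fill(out, gaps, labels.spacing)
    records = []
    for i in np.argsort(ids):
        lid = int(ids[i])
        records.append(
            SmoothRecord(lid, filters_applied.get(lid, "none"),
                         n_before[lid], int((out == lid).sum()))
        )
    return replace(labels, data=out), records


def gaussian_label_smoothing(
    labels: LabelVolume, params: SmoothParams | None = None
) -> tuple[LabelVolume, list[SmoothRecord]]:
    params = params or SmoothParams(mode="gaussian")
    if params.mode != "gaussian":
        raise ValueError("params.mode must be 'gaussian'")
    return smooth_labels(labels, params)


def adaptive_morph_smoothing(
    labels: LabelVolume, params: SmoothParams | None = None
) -> tuple[LabelVolume, list[SmoothRecord]]:
    params = params or SmoothParams(mode="adaptive_opening")
    if params.mode != "adaptive_opening":
        raise ValueError("params.mode must be 'adaptive_opening'")
    return smooth_labels(labels, params)


def _signed_distance_2d(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside, in voxels."""
    if mask.all():
        return np.full(mask.shape, np.inf)
    if not mask.any():
        return np.full(mask.shape, -np.inf)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_label_between_planes(
    labels: LabelVolume, label_id: int, plane_a: int, plane_b: int
) -> LabelVolume:
    """Morph one label's contour smoothly between two edited planes.

    The signed distance fields of the label mask at the two end planes are
    linearly interpolated for every intervening plane and re-thresholded at
    zero, giving borders that vary smoothly in all three dimensions.  End
    planes are never modified.
    """
    if plane_a >= plane_b:
        raise ValueError("plane_a must be < plane_b")
    ma = labels.data[plane_a] == label_id
    mb = labels.data[plane_b] == label_id
    if not ma.any() or not mb.any():
        raise ValueError(f"label {label_id} absent in one of the end planes")
    out = labels.data.copy()
    sda, sdb = _signed_distance_2d(ma), _signed_distance_2d(mb)
    for p in range(plane_a + 1, plane_b):
        t = (p - plane_a) / (plane_b - plane_a)
        interp = (1 - t) * sda + t * sdb
        new_mask = interp > 0
        plane = out[p]
        plane[plane == label_id] = 0
        plane[new_mask] = label_id
    return replace(labels, data=out)
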