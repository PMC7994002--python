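"""Anatomical edge maps from intensity volumes and surface maps from labels.

Broad anatomical boundaries are modelled as the zero crossings of a
Laplacian-of-Gaussian response: a wide Gaussian (sigma 5 voxels by default)
keeps only well-demarcated tissue transitions such as the cortical surface and
basal ganglia, and the sign changes of the Laplacian locate them.  The
resulting binary map drives both the watershed-based label refinement and the
label-to-anatomy distance metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters
from skimage.morphology import ball

from .volumes import LabelVolume, Mask, Volume, threshold_foreground

__all__ = [
    "EdgeMapParams",
    "zero_crossings",
    "anatomical_edge_map",
    "label_surfaces",
    "foreground_mask",
]


@dataclass
class EdgeMapParams:
    """Parameters of the anatomical edge detector.

    gaussian_sigma is in voxels (not µm): the fixed sigma used across
    anisotropic atlases smooths in index space, so a coarse plane axis is
    smoothed over the same number of planes as a fine axis.
    """

    gaussian_sigma: float = 5.0
    laplacian_size: int = 3
    background_strategy: str = "labels_union_threshold"
    #: zero-crossing contrast gate: None flags every sign change; "otsu"
    #: thresholds the local response swing automatically; a float sets the
    #: minimum swing.  Homogeneous regions produce near-zero responses whose
    #: noise-driven sign flips would otherwise litter the map with false
    #: edges (the Marr-Hildreth slope test).
    zero_crossing_contrast: float | str | None = None

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.laplacian_size < 3 or self.laplacian_size % 2 == 0:
            raise ValueError("laplacian_size must be odd and >= 3")
        if self.background_strategy not in ("labels_union_threshold", "threshold_only"):
            raise ValueError(f"unknown background_strategy {self.background_strategy}")


def zero_crossings(
    signed: np.ndarray, min_contrast: float | str | None = None
) -> np.ndarray:
    """Flag voxels where a signed response changes sign in their neighborhood.

    A voxel is flagged iff the grey erosion (local min) is negative and the
    grey dilation (local max) is positive over a spherical radius-1
    neighborhood, i.e. both signs occur within one voxel of it.  With
    ``min_contrast`` set, the local swing ``max − min`` must additionally
    exceed it ("otsu" picks the threshold from the swing histogram), which
    suppresses the noise-driven sign flips of near-zero responses.
    """
    signed = np.asarray(signed, dtype=float)
    footprint = ball(1)
    mn = ndimage.grey_erosion(signed, footprint=footprint)
    mx = ndimage.grey_dilation(signed, footprint=footprint)
    out = (mn < 0) & (mx > 0)
    if min_contrast is not None:
        swing = mx - mn
        if min_contrast == "otsu":
            min_contrast = float(filters.threshold_otsu(swing))
        out &= swing > float(min_contrast)
    return out


def foreground_mask(
    vol: Volume,
    labels: LabelVolume | None,
    strategy: str = "labels_union_threshold",
) -> Mask:
    """Tissue foreground: Otsu threshold of the intensities, optionally unioned
    with the labels mask to fill holes the threshold misses."""
    fg = threshold_foreground(vol, method="otsu").data
    if strategy == "labels_union_threshold":
        if labels is None:
            raise ValueError("labels required for background_strategy='labels_union_threshold'")
        fg = fg | (labels.data != 0)
    fg = ndimage.binary_fill_holes(fg)
    return Mask(fg, vol.spacing, vol.origin)


def _cross_surface(mask: np.ndarray) -> np.ndarray:
    """Surface of a binary mask: mask minus its face-connected erosion."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=struct, border_value=0)


def anatomical_edge_map(
    vol: Volume,
    labels: LabelVolume | None = None,
    params: EdgeMapParams | None = None,
) -> Mask:
    """Binary map of broad anatomical boundaries in an intensity volume.

    Pipeline: Gaussian blur -> Laplacian -> zero crossings, masked to the
    tissue foreground, plus the outer surface of the foreground itself so the
    brain outline is always part of the map.
    """
    params = params or EdgeMapParams()
    smoothed = ndimage.gaussian_filter(vol.data.astype(float), params.gaussian_sigma)
    response = filters.laplace(smoothed, ksize=params.laplacian_size)
    edges = zero_crossings(response, params.zero_crossing_contrast)
    fg = foreground_mask(vol, labels, params.background_strategy).data
    edges &= fg
    if fg.any() and not fg.all():
        edges |= _cross_surface(fg)
    return Mask(edges, vol.spacing, vol.origin)


def label_surfaces(labels: LabelVolume) -> Mask:
    """Union over labels of each label's one-voxel-thick outer surface.

    Per label the surface is the label minus its erosion by the face-connected
    (cross-shaped) structuring element; equivalently, a nonzero voxel is
    surface iff any of its six face neighbors (or the image border) carries a
    different value.
    """
    data = labels.data
    surf = np.zeros(data.shape, bool)
    fg = data != 0
    for axis in range(3):
        for shift in (1, -1):
            neigh = np.roll(data, shift, axis=axis)
            # voxels rolled in from the opposite border count as background
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            differs = neigh != data
            differs[tuple(edge)] = True
            surf |= differs
    surf &= fg
    return Mask(surf, labels.spacing, labels.origin)
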