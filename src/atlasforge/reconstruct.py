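"""Completing partial atlases: lateral label extension, compressed-plane
expansion, midline rotation and mirroring, piecewise affine shears, and
stripping of non-CNS tissue.

The source atlases label only part of one hemisphere.  The missing lateral
planes are filled by recursively carrying the last labeled sagittal plane
outward — resizing it to the shrinking histology, re-fitting it to detected
anatomical edges with an erosion + compact-watershed step, and letting
central labels taper away — after which the completed hemisphere is mirrored
across the sagittal midline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation, transform

from .morph import ball_dilation, disk_dilation, disk_erosion
from .volumes import LabelVolume, Mask, Volume, nearest_label_fill

__all__ = [
    "ExtensionParams",
    "MirrorParams",
    "find_extension_start",
    "extend_labels_lateral",
    "expand_compressed_planes",
    "rotate_to_midline",
    "mirror_across_midline",
    "piecewise_affine_shear",
    "strip_non_cns",
]


@dataclass
class ExtensionParams:
    """Lateral extension settings.

    ``erosion_base`` is the per-atlas erosion radius used when re-fitting each
    carried plane; with ``taper_weighting`` on, each label's radius is scaled
    by its normalized median distance to the structure perimeter so central
    labels erode (and may taper away) first.
    """

    start_fraction: float | None = None
    plane_threshold: float = 10.0
    min_object_px: int = 200
    erosion_base: int = 3
    taper_weighting: bool = True
    watershed_compactness: float = 0.005
    direction: int = -1  # extension toward decreasing plane index ("lateral")
    min_contiguous: int = 3

    def __post_init__(self):
        if self.start_fraction is not None and not (0 <= self.start_fraction < 1):
            raise ValueError("start_fraction must be in [0, 1)")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass
class MirrorParams:
    mirror_fraction: float = 0.5
    rotations: list = field(default_factory=list)  # (axis, degrees) pairs
    negate_mirrored_ids: bool = False

    def __post_init__(self):
        if not (0 < self.mirror_fraction < 1):
            raise ValueError("mirror_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Extension start detection
# ---------------------------------------------------------------------------


def find_extension_start(
    labels: LabelVolume, override: int | None = None, params: ExtensionParams | None = None
) -> int:
    """Most lateral plane of the first contiguous labeled stretch.

    Scanning inward from the labeled-side edge (low indices when extension
    proceeds toward decreasing indices), isolated labeled planes are skipped:
    a stretch counts once at least ``min_contiguous`` consecutive planes are
    labeled.  ``override`` is returned verbatim when given.
    """
    if override is not None:
        return int(override)
    params = params or ExtensionParams()
    labeled = np.array([bool(np.any(p)) for p in labels.data])
    if not labeled.any():
        raise ValueError("no labeled plane in the volume")
    n = len(labeled)
    scan = range(n) if params.direction == -1 else range(n - 1, -1, -1)
    need = max(params.min_contiguous, 1)
    for i in scan:
        if labeled[i]:
            run = [i + k * (1 if params.direction == -1 else -1) for k in range(need)]
            if all(0 <= j < n and labeled[j] for j in run):
                return i
    # no long-enough run: fall back to the innermost labeled plane
    return int(np.flatnonzero(labeled)[0 if params.direction == -1 else -1])


# ---------------------------------------------------------------------------
# Lateral extension
# ---------------------------------------------------------------------------


def _plane_foreground(plane: np.ndarray, params: ExtensionParams) -> np.ndarray:
    fg = plane > params.plane_threshold
    if params.min_object_px > 0:
        # drop connected components below min_object_px pixels
        fg = morphology.remove_small_objects(
            fg, max_size=params.min_object_px - 1, connectivity=1
        )
    return fg


def _resize_labels_to_box(src: np.ndarray, box: tuple[slice, ...]) -> np.ndarray:
    shape = tuple(s.stop - s.start for s in box)
    return transform.resize(
        src, shape, order=0, preserve_range=True, anti_aliasing=False
    ).astype(src.dtype)


def _bbox(mask: np.ndarray) -> tuple[slice, ...] | None:
    objs = ndimage.find_objects(mask.astype(np.uint8))
    return objs[0] if objs else None


def _refit_plane(
    plane_labels: np.ndarray,
    structure_mask: np.ndarray,
    edge_dist_slice: np.ndarray,
    params: ExtensionParams,
) -> np.ndarray:
    """Erode labels (taper-weighted) and regrow them by compact watershed on
    the edge-distance landscape, within one structure of one plane."""
    ids = np.unique(plane_labels[structure_mask])
    ids = ids[ids != 0]
    if ids.size == 0:
        return plane_labels
    dist_in = ndimage.distance_transform_edt(structure_mask)
    max_dist = float(dist_in.max())
    seeds = np.zeros_like(plane_labels)
    for lid in ids:
        m = (plane_labels == lid) & structure_mask
        radius = float(params.erosion_base)
        if params.taper_weighting and max_dist > 0:
            med = float(np.median(dist_in[m]))
            radius *= med / max_dist
        eroded = disk_erosion(m, radius)
        seeds[eroded] = lid  # labels may erode completely (taper)
    if not seeds.any():
        return plane_labels
    grown = segmentation.watershed(
        -edge_dist_slice,
        markers=seeds,
        mask=structure_mask,
        compactness=params.watershed_compactness,
    )
    out = plane_labels.copy()
    out[structure_mask] = grown[structure_mask]
    return out


def extend_labels_lateral(
    vol: Volume,
    labels: LabelVolume,
    start: int,
    edge_map: Mask,
    params: ExtensionParams | None = None,
) -> LabelVolume:
    """Grow labels plane-by-plane into the unlabeled lateral planes.

    For each unlabeled plane moving outward from ``start``: per connected
    foreground structure, the previous plane's labels are resized (order 0)
    from their bounding box to the structure's bounding box, restricted to the
    largest connected component, in-painted against the thresholded
    foreground, then eroded per label (radius scaled by the label's normalized
    median distance to the structure perimeter) and regrown by a compact
    watershed over the anatomical edge-distance landscape.  Central labels may
    taper away entirely; every cleaned above-threshold voxel ends up labeled.
    """
    params = params or ExtensionParams()
    if vol.shape != labels.shape or vol.shape != edge_map.shape:
        raise ValueError("volume, labels and edge map must share shape")
    if not np.any(labels.data[start]):
        raise ValueError(f"start plane {start} has no labels")
    out = labels.data.copy()
    edge_dist = ndimage.distance_transform_edt(~np.asarray(edge_map.data, bool))
    n = out.shape[0]
    planes = (
        range(start - 1, -1, -1) if params.direction == -1 else range(start + 1, n)
    )
    for p in planes:
        prev = out[p - params.direction]
        cur_fg = _plane_foreground(vol.data[p], params)
        new_plane = np.zeros_like(prev)
        if not cur_fg.any():
            out[p] = new_plane
            continue
        comp, n_comp = ndimage.label(cur_fg)
        prev_fg = prev != 0
        for ci in range(1, n_comp + 1):
            cmask = comp == ci
            box = _bbox(cmask)
            # labels of the previous plane overlapping this structure's bbox
            prev_crop_mask = np.zeros_like(prev_fg)
            prev_crop_mask[box] = prev_fg[box]
            src_box = _bbox(prev_crop_mask)
            if src_box is None:
                warnings.warn(
                    f"plane {p}: structure {ci} has no matching labels, skipped"
                )
                continue
            resized = _resize_labels_to_box(prev[src_box], box)
            placed = np.zeros_like(prev)
            placed[box] = resized
            placed[~cmask] = 0
            if not placed.any():
                warnings.warn(
                    f"plane {p}: resized labels missed structure {ci}, skipped"
                )
                continue
            placed = nearest_label_fill(placed, cmask, labels.spacing[1:])
            placed = _refit_plane(placed, cmask, edge_dist[p], params)
            new_plane[cmask] = placed[cmask]
        out[p] = new_plane
    return replace(labels, data=out)


# ---------------------------------------------------------------------------
# Compressed-plane expansion
# ---------------------------------------------------------------------------


def expand_compressed_planes(
    vol: Volume,
    labels: LabelVolume,
    plane_range: tuple[int, int],
    params: ExtensionParams | None = None,
) -> LabelVolume:
    """Re-stretch per-plane label content to the histology bounding box.

    For each plane in ``plane_range`` (half-open), the labels' bounding box is
    resized (order 0) to the bounding box of the largest connected foreground
    component, correcting planes whose annotation was compressed along one
    axis.  Planes with empty foreground are left unchanged with a warning.
    """
    params = params or ExtensionParams()
    lo, hi = plane_range
    if not (0 <= lo < hi <= vol.shape[0]):
        raise ValueError(f"plane range {plane_range} out of bounds")
    out = labels.data.copy()
    for p in range(lo, hi):
        fg = _plane_foreground(vol.data[p], params)
        if not fg.any():
            warnings.warn(f"plane {p}: empty foreground, left unchanged")
            continue
        comp, n_comp = ndimage.label(fg)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n_comp + 1))
        largest = comp == (1 + int(np.argmax(sizes)))
        lab_box = _bbox(out[p] != 0)
        if lab_box is None:
            warnings.warn(f"plane {p}: no labels, left unchanged")
            continue
        tgt_box = _bbox(largest)
        resized = _resize_labels_to_box(out[p][lab_box], tgt_box)
        new_plane = np.zeros_like(out[p])
        new_plane[tgt_box] = resized
        out[p] = new_plane
    return replace(labels, data=out)


# ---------------------------------------------------------------------------
# Rotation, mirroring, shearing, stripping
# ---------------------------------------------------------------------------


def rotate_to_midline(vol: Volume | LabelVolume, rotations) -> Volume | LabelVolume:
    """Apply in-plane rotations slice-by-slice along the given axes.

    ``rotations`` is a list of ``(axis, degrees)``: every 2D slice orthogonal
    to ``axis`` is rotated by the same angle, keeping the shape and filling
    exposed corners with background.  Labels rotate order-0; right angles are
    applied exactly.
    """
    is_labels = isinstance(vol, LabelVolume)
    data = vol.data.copy()
    for axis, deg in rotations:
        deg = float(deg)
        if deg % 360 == 0:
            continue
        plane_axes = tuple(a for a in range(3) if a != axis)
        if deg % 90 == 0:
            k = int(deg // 90) % 4
            data = np.rot90(data, k=k, axes=plane_axes)
            continue
        order = 0 if is_labels else 1
        data = ndimage.rotate(
            data, deg, axes=plane_axes, reshape=False, order=order,
            mode="constant", cval=0, prefilter=False,
        )
        if is_labels:
            data = data.astype(vol.data.dtype)
    return replace(vol, data=data)


def mirror_plane_source(j: int, m: int) -> int:
    """Source plane for output plane ``j >= m`` when mirroring at plane m."""
    return max(2 * m - 1 - j, 0)


def mirror_across_midline(
    vol: Volume, labels: LabelVolume, params: MirrorParams
) -> tuple[Volume, LabelVolume]:
    """Replace planes beyond ``round(fraction·N)`` with reflections of the
    planes below it, for both intensity and labels."""
    n = vol.shape[0]
    m = int(round(params.mirror_fraction * n))
    if not (0 < m < n):
        raise ValueError(f"mirror plane {m} outside volume of {n} planes")
    vdata = vol.data.copy()
    ldata = labels.data.copy()
    for j in range(m, n):
        src = mirror_plane_source(j, m)
        vdata[j] = vdata[src]
        lsrc = ldata[src]
        ldata[j] = -lsrc if params.negate_mirrored_ids else lsrc
    return replace(vol, data=vdata), replace(labels, data=ldata)


def piecewise_affine_shear(
    vol: Volume | LabelVolume,
    roi: tuple[slice, slice, slice],
    shear_axis: int,
    shift_axis: int,
    max_shift: int,
    attach_axis: int | None = None,
) -> Volume | LabelVolume:
    """Shear a cuboid ROI plane-by-plane with an optional attachment face.

    Plane ``k`` along ``shear_axis`` shifts along ``shift_axis`` by a linear
    ramp from 0 to ``max_shift`` voxels.  With ``attach_axis`` set, the shift
    additionally ramps line-by-line from 0 at the attachment face, so the
    sheared block stays connected to its surroundings along two faces.
    Vacated voxels become background; content shifted past the ROI border is
    clipped.
    """
    axes = {shear_axis, shift_axis}
    if attach_axis is not None:
        axes.add(attach_axis)
    if len(axes) != (3 if attach_axis is not None else 2):
        raise ValueError("shear, shift and attach axes must be distinct")
    sub = vol.data[roi]
    n_shear = sub.shape[_roi_axis(shear_axis)]
    if abs(max_shift) >= sub.shape[_roi_axis(shift_axis)]:
        raise ValueError("max_shift exceeds the ROI extent along the shift axis")
    out_sub = np.zeros_like(sub)
    sa, fa = _roi_axis(shear_axis), _roi_axis(shift_axis)
    aa = _roi_axis(attach_axis) if attach_axis is not None else None
    for k in range(n_shear):
        plane = np.take(sub, k, axis=sa)
        shift_k = max_shift * (k / (n_shear - 1)) if n_shear > 1 else 0.0
        shifted = np.zeros_like(plane)
        if aa is None:
            _shift_into(shifted, plane, int(round(shift_k)), _plane_axis(fa, sa))
        else:
            line_axis = _plane_axis(aa, sa)
            move_axis = _plane_axis(fa, sa)
            n_lines = plane.shape[line_axis]
            del move_axis  # lines are 1D once the attach axis is taken out
            for j in range(n_lines):
                line = np.take(plane, j, axis=line_axis)
                s = int(round(shift_k * (j / (n_lines - 1)))) if n_lines > 1 else 0
                dst = np.zeros_like(line)
                _shift_into(dst, line, s, 0)
                _put_along(shifted, dst, j, line_axis)
        _put_along(out_sub, shifted, k, sa)
    out = vol.data.copy()
    out[roi] = out_sub
    return replace(vol, data=out)


def _roi_axis(axis: int) -> int:
    return axis


def _plane_axis(axis: int, dropped: int) -> int:
    return axis - 1 if axis > dropped else axis


def _shift_into(dst: np.ndarray, src: np.ndarray, shift: int, axis: int) -> None:
    n = src.shape[axis]
    if shift == 0:
        dst[...] = src
        return
    if abs(shift) >= n:
        return
    src_sl = [slice(None)] * src.ndim
    dst_sl = [slice(None)] * src.ndim
    if shift > 0:
        src_sl[axis] = slice(0, n - shift)
        dst_sl[axis] = slice(shift, n)
    else:
        src_sl[axis] = slice(-shift, n)
        dst_sl[axis] = slice(0, n + shift)
    dst[tuple(dst_sl)] = src[tuple(src_sl)]


def _put_along(arr: np.ndarray, values: np.ndarray, index: int, axis: int) -> None:
    sl = [slice(None)] * arr.ndim
    sl[axis] = index
    arr[tuple(sl)] = values


def strip_non_cns(
    vol: Volume,
    labels: LabelVolume,
    pad: int = 5,
    dilate: float = 2.0,
) -> tuple[Volume, LabelVolume]:
    """Crop to the labels' padded bounding box and zero intensities outside a
    slightly dilated labels mask, removing embryo tissue outside the CNS."""
    fg = labels.data != 0
    if not fg.any():
        raise ValueError("labels are empty; nothing to strip to")
    box = _bbox(fg)
    box = tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, n))
        for s, n in zip(box, labels.shape)
    )
    vdata = vol.data[box].copy()
    ldata = labels.data[box].copy()
    keep = ball_dilation(ldata != 0, dilate)
    vdata[~keep] = 0
    return replace(vol, data=vdata), replace(labels, data=ldata)
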