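"""Core volumetric containers, file I/O, thresholding, in-painting and downsampling.

A brain atlas here is a pair of co-registered 3D images: a scalar intensity
volume (histology or nuclear-stained microscopy) and an integer label volume
(the annotation), sharing shape and physical voxel spacing.  Axis order is
fixed throughout the package as ``(plane, row, col)`` where axis 0 is the
sagittal stacking axis, axis 1 runs dorsoventrally and axis 2 rostrocaudally.
All spacings are micrometres.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters

__all__ = [
    "Volume",
    "LabelVolume",
    "Mask",
    "load_volume",
    "save_volume",
    "load_ontology",
    "threshold_foreground",
    "in_paint_labels",
    "downsample",
]


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """3D scalar intensity image with per-axis physical spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    path: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume(Volume):
    """Integer annotation volume; 0 is background, nonzero values are label IDs.

    ``ontology`` optionally maps label IDs to names and hierarchy, as a
    DataFrame with columns ``id, name, parent_id, level``.
    """

    ontology: Optional[pd.DataFrame] = None

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {self.data.dtype}")

    def label_ids(self) -> np.ndarray:
        """Sorted nonzero label IDs present in the volume."""
        ids = np.unique(self.data)
        return ids[ids != 0]

    def foreground(self) -> "Mask":
        return Mask(self.data != 0, self.spacing, self.origin)

    def copy(self) -> "LabelVolume":
        return replace(self, data=self.data.copy())


@dataclass
class Mask:
    """Boolean volume sharing geometry with its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.data))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SITK_EXTS = {".mhd", ".mha", ".nii", ".nrrd"}
_TIFF_EXTS = {".tif", ".tiff"}


def _split_ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii"
    return path.suffix.lower()


def load_volume(
    path: Union[str, os.PathLike],
    spacing: Optional[Sequence[float]] = None,
    as_labels: bool = False,
    ontology: Optional[pd.DataFrame] = None,
) -> Union[Volume, LabelVolume]:
    """Load a volume from MetaImage, NIfTI-1, NRRD or multi-page TIFF.

    Spacing is taken from file metadata and returned in (plane, row, col)
    order; TIFF files carry no reliable spacing, so ``spacing`` must be given
    explicitly for them.  Label files are loaded without any interpolation of
    values; pass ``as_labels=True`` to get a :class:`LabelVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = _split_ext(path)
    if ext in _SITK_EXTS:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x) == (plane, row, col)
        if data.ndim != 3:
            raise ValueError(f"expected 3D image in {path}, got ndim={data.ndim}")
        file_spacing = tuple(reversed(img.GetSpacing()))
        file_origin = tuple(reversed(img.GetOrigin()))
        sp = _as_tuple3(spacing, "spacing") if spacing is not None else file_spacing
        origin = file_origin
    elif ext in _TIFF_EXTS:
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"expected 3D TIFF stack in {path}, got ndim={data.ndim}")
        if spacing is None:
            raise ValueError(
                f"TIFF file {path} carries no voxel spacing; pass spacing= explicitly"
            )
        sp = _as_tuple3(spacing, "spacing")
        origin = (0.0, 0.0, 0.0)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if as_labels:
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(
                f"label volume {path} has non-integer dtype {data.dtype}"
            )
        return LabelVolume(data, sp, origin, path=str(path), ontology=ontology)
    return Volume(data, sp, origin, path=str(path))


def save_volume(vol: Union[Volume, LabelVolume, Mask], path: Union[str, os.PathLike]) -> None:
    """Write a volume; format chosen from the extension.

    Integer data round-trips bit-exactly through every supported format.
    Masks are written as 8-bit 0/1 volumes.
    """
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    ext = _split_ext(path)
    if ext in _SITK_EXTS:
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(reversed([float(s) for s in vol.spacing])))
        img.SetOrigin(tuple(reversed([float(o) for o in vol.origin])))
        sitk.WriteImage(img, str(path))
    elif ext in _TIFF_EXTS:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path}")


def load_ontology(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read a label ontology table (columns: id, name, parent_id, level)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"id", "name"} - set(df.columns)
    if missing:
        raise ValueError(f"ontology table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def threshold_foreground(
    vol: Volume, method: str = "otsu", value: Optional[float] = None
) -> Mask:
    """Foreground mask: voxels with intensity strictly above a threshold.

    ``method`` is one of ``mean`` (threshold at the image mean), ``otsu``
    (Otsu's criterion), or ``fixed`` (caller-supplied ``value``).
    A constant image under ``otsu`` yields an empty mask with a warning.
    """
    data = vol.data
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires value=")
        thresh = float(value)
    elif method == "mean":
        thresh = float(data.mean())
    elif method == "otsu":
        mn, mx = data.min(), data.max()
        if mn == mx:
            warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
            return Mask(np.zeros(vol.shape, bool), vol.spacing, vol.origin)
        thresh = float(filters.threshold_otsu(data))
    else:
        raise ValueError(f"unknown threshold method: {method}")
    return Mask(data > thresh, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Nearest-label in-painting
# ---------------------------------------------------------------------------


def nearest_label_fill(
    labels_data: np.ndarray,
    fill_mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Assign each voxel in ``fill_mask`` the value of its nearest labeled voxel.

    Distances are Euclidean and spacing-aware.  Ties are broken by the lowest
    linear (C-order) index among the equidistant donors, which makes the
    operation deterministic and directly checkable against brute force.
    Works for arrays of any dimensionality.
    """
    fill_mask = np.asarray(fill_mask, bool) & (labels_data == 0)
    if not fill_mask.any():
        return labels_data.copy()
    donor_mask = labels_data != 0
    if not donor_mask.any():
        raise ValueError("no labeled voxels to in-paint from")
    sp = np.asarray(spacing, dtype=float)[-labels_data.ndim:]
    donor_idx = np.argwhere(donor_mask)
    donor_pts = donor_idx * sp
    tree = cKDTree(donor_pts)
    query_idx = np.argwhere(fill_mask)
    query_pts = query_idx * sp
    k = min(2, len(donor_pts))
    dists, nn = tree.query(query_pts, k=k)
    if k == 1:
        dists = dists[:, None]
        nn = nn[:, None]
    donor_lin = np.ravel_multi_index(donor_idx.T, labels_data.shape)
    chosen = nn[:, 0].copy()
    # resolve ties (nearest two donors at essentially equal distance) in favor
    # of the lowest linear index so results are platform-independent
    if k == 2:
        tied = np.isclose(dists[:, 0], dists[:, 1], rtol=0.0, atol=1e-9)
        for i in np.flatnonzero(tied):
            cands = tree.query_ball_point(query_pts[i], r=dists[i, 0] + 1e-9)
            chosen[i] = min(cands, key=lambda c: donor_lin[c])
    out = labels_data.copy()
    vals = labels_data.ravel()[donor_lin]
    out[tuple(query_idx.T)] = vals[chosen]
    return out


def in_paint_labels(labels: LabelVolume, target: Mask) -> LabelVolume:
    """Fill every unlabeled voxel of ``target`` with its nearest label.

    Previously labeled voxels are never changed, so the output label ID set is
    a subset of the input's.
    """
    if labels.shape != target.shape:
        raise ValueError("labels and target must share shape")
    filled = nearest_label_fill(labels.data, target.data, labels.spacing)
    return replace(labels, data=filled)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def _resample_coords(n_in: int, n_out: int) -> np.ndarray:
    # half-pixel-centre alignment, as in standard image resizing
    scale = n_in / n_out
    c = (np.arange(n_out) + 0.5) * scale - 0.5
    return np.clip(c, 0, n_in - 1)


def downsample(
    vol: Union[Volume, LabelVolume],
    target_shape: Sequence[int],
    chunked: bool = False,
    chunk_len: int = 32,
) -> Union[Volume, LabelVolume]:
    """Resample a volume to ``target_shape`` (works for up- or downsampling).

    Intensity volumes are interpolated linearly; label volumes use order-0
    (nearest) sampling so no new label values appear.  The chunked path slices
    the output grid into blocks, fetches exactly the input slab each block
    needs and evaluates the same global sample coordinates, so chunked and
    unchunked outputs are elementwise identical.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n <= 0 for n in target_shape):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    is_labels = isinstance(vol, LabelVolume)
    order = 0 if is_labels else 1
    coords = [_resample_coords(vol.shape[a], target_shape[a]) for a in range(3)]

    def _sample(block_coords):
        grid = np.meshgrid(*block_coords, indexing="ij")
        pts = np.stack([g.ravel() for g in grid])
        out = ndimage.map_coordinates(
            vol.data.astype(float) if not is_labels else vol.data,
            pts,
            order=order,
            mode="nearest",
        )
        return out.reshape([len(c) for c in block_coords])

    if not chunked:
        new = _sample(coords)
    else:
        new = np.empty(target_shape, dtype=vol.data.dtype if is_labels else float)
        for z0 in range(0, target_shape[0], chunk_len):
            for y0 in range(0, target_shape[1], chunk_len):
                for x0 in range(0, target_shape[2], chunk_len):
                    sl = tuple(
                        slice(o, min(o + chunk_len, target_shape[a]))
                        for a, o in enumerate((z0, y0, x0))
                    )
                    new[sl] = _sample([coords[a][sl[a]] for a in range(3)])
    if is_labels:
        new = new.astype(vol.data.dtype)
    new_spacing = tuple(
        s * vol.shape[a] / target_shape[a] for a, s in enumerate(vol.spacing)
    )
    return replace(vol, data=new, spacing=new_spacing)
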