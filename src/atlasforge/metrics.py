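"""Atlas quality metrics: compactness, smoothing quality, Dice, edge distances
and per-label intensity variability.

The central shape statistic is the classical 3D compactness ``SA³ / Vol²``, a
scale-free irregularity measure minimized by the sphere (36π ≈ 113.1).
Smoothing is scored per label by *compaction* (fractional compactness gain),
penalized by *displacement* (fraction of the smoothed label outside the
original), their difference being the *smoothing quality*; the atlas-wide
score is the volume-weighted mean over labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .edges import label_surfaces
from .volumes import LabelVolume, Mask, Volume

__all__ = [
    "LabelShapeStats",
    "SmoothingReport",
    "EdgeDistanceStats",
    "LabelIntensityStats",
    "compactness",
    "smoothing_report",
    "dice",
    "edge_distance_stats",
    "intensity_cv",
]

SPHERE_COMPACTNESS = 36.0 * math.pi


@dataclass
class LabelShapeStats:
    label_id: int
    surface_area: float  # µm²
    volume: float  # µm³
    compactness: float  # dimensionless, SA³/Vol²


@dataclass
class SmoothingReport:
    per_label: pd.DataFrame  # columns: label_id, compaction, displacement, quality, vol_orig
    atlas_wide_quality: float
    labels_lost: int

    def lost_label_ids(self) -> list[int]:
        return list(self.per_label.loc[self.per_label["lost"], "label_id"])


@dataclass
class EdgeDistanceStats:
    per_label: pd.DataFrame  # columns: label_id, n_surface, dist_sum, dist_mean (µm)
    total: float  # µm


@dataclass
class LabelIntensityStats:
    per_label: pd.DataFrame  # columns: label_id, mean, std, cv, volume_vox
    weighted_mean_cv: float
    weighted_median_cv: float


def compactness(
    mask: Mask, spacing=None, label_id: int = 0, mesh_smoothing_sigma: float = 0.6
) -> LabelShapeStats:
    """Shape statistics of a binary mask from a marching-cubes isosurface.

    The mask is zero-padded so the surface is guaranteed closed, the
    indicator is smoothed by a sub-voxel Gaussian (sigma 0.6 voxels) before
    the level-0.5 isosurface is extracted, and volume is voxel count times
    voxel volume.  The sub-voxel smoothing corrects most of the staircase
    overestimate of curved surface areas (a raw binary mesh of a ball
    overestimates its area by ~29%) while keeping flat faces within a few
    percent; masks too small to reach the iso-level after smoothing fall
    back to the raw binary mesh.  Smoothing acts in voxel space and the mesh
    in physical space, so ``SA³/Vol²`` stays exactly invariant to uniform
    spacing rescaling.
    """
    data = np.asarray(mask.data, bool)
    if not data.any():
        raise ValueError("compactness of an empty mask is undefined")
    sp = tuple(float(s) for s in (spacing if spacing is not None else mask.spacing))
    pad = 1 + int(np.ceil(3 * mesh_smoothing_sigma))
    field_ = np.pad(data, pad).astype(float)
    if mesh_smoothing_sigma > 0:
        sm = ndimage.gaussian_filter(field_, mesh_smoothing_sigma)
        if sm.max() > 0.5:
            field_ = sm
    verts, faces, _, _ = measure.marching_cubes(field_, level=0.5, spacing=sp)
    sa = float(measure.mesh_surface_area(verts, faces))
    vol = float(data.sum()) * float(np.prod(sp))
    return LabelShapeStats(label_id, sa, vol, sa**3 / vol**2)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 when both are empty."""
    da, db = np.asarray(a.data, bool), np.asarray(b.data, bool)
    if da.shape != db.shape:
        raise ValueError("masks must share shape")
    na, nb = int(da.sum()), int(db.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / (na + nb)


def smoothing_report(orig: LabelVolume, smoothed: LabelVolume) -> SmoothingReport:
    """Score a smoothing run label by label.

    For each label present in the original: compaction ``(C_orig − C_smooth) /
    C_orig``, displacement ``|smoothed ∖ orig| / |smoothed|``, quality =
    compaction − displacement.  Labels that vanished are counted as lost and
    excluded from the atlas-wide volume-weighted mean (their quality is
    undefined), which is reported alongside the loss count.
    """
    if orig.shape != smoothed.shape:
        raise ValueError("volumes must share shape")
    rows = []
    for lid in orig.label_ids():
        m_orig = orig.data == lid
        m_sm = smoothed.data == lid
        n_orig, n_sm = int(m_orig.sum()), int(m_sm.sum())
        if n_sm == 0:
            rows.append(
                dict(label_id=int(lid), compaction=np.nan, displacement=np.nan,
                     quality=np.nan, vol_orig=n_orig, lost=True)
            )
            continue
        c_orig = compactness(Mask(m_orig, orig.spacing), label_id=int(lid)).compactness
        c_sm = compactness(Mask(m_sm, smoothed.spacing), label_id=int(lid)).compactness
        compaction = (c_orig - c_sm) / c_orig
        displacement = int((m_sm & ~m_orig).sum()) / n_sm
        rows.append(
            dict(label_id=int(lid), compaction=compaction, displacement=displacement,
                 quality=compaction - displacement, vol_orig=n_orig, lost=False)
        )
    df = pd.DataFrame(rows)
    kept = df[~df["lost"]]
    if len(kept) and kept["vol_orig"].sum() > 0:
        atlas_wide = float(
            (kept["quality"] * kept["vol_orig"]).sum() / kept["vol_orig"].sum()
        )
    else:
        atlas_wide = float("nan")
    return SmoothingReport(df, atlas_wide, int(df["lost"].sum()))


def edge_distance_stats(
    labels: LabelVolume, edge_map: Mask, spacing=None
) -> EdgeDistanceStats:
    """Distances from label surfaces to the nearest anatomical edge.

    The spacing-aware Euclidean distance transform of the edge map is sampled
    at every label-surface voxel; sums are reported per label and in total,
    in µm.
    """
    if not np.any(edge_map.data):
        raise ValueError("edge map is empty")
    sp = tuple(float(s) for s in (spacing if spacing is not None else labels.spacing))
    dist = ndimage.distance_transform_edt(~np.asarray(edge_map.data, bool), sampling=sp)
    surf = label_surfaces(labels).data
    rows = []
    for lid in labels.label_ids():
        sel = surf & (labels.data == lid)
        d = dist[sel]
        rows.append(
            dict(label_id=int(lid), n_surface=int(sel.sum()),
                 dist_sum=float(d.sum()), dist_mean=float(d.mean()) if d.size else 0.0)
        )
    df = pd.DataFrame(rows)
    return EdgeDistanceStats(df, float(df["dist_sum"].sum()) if len(df) else 0.0)


def intensity_cv(vol: Volume, labels: LabelVolume) -> LabelIntensityStats:
    """Per-label coefficient of variation σ/µ of the intensities.

    σ is the population standard deviation.  Labels with zero mean have an
    undefined CV; they are flagged (NaN) and excluded, with a warning, from
    the volume-weighted aggregates.  Both the weighted mean and the weighted
    median of the per-label CVs are reported.
    """
    if vol.shape != labels.shape:
        raise ValueError("volumes must share shape")
    rows = []
    for lid in labels.label_ids():
        sel = labels.data == lid
        vals = vol.data[sel].astype(float)
        mu = float(vals.mean())
        sd = float(vals.std())
        cv = sd / mu if mu != 0 else np.nan
        if mu == 0:
            warnings.warn(f"label {lid} has zero mean intensity; CV undefined")
        rows.append(dict(label_id=int(lid), mean=mu, std=sd, cv=cv, volume_vox=int(sel.sum())))
    df = pd.DataFrame(rows)
    ok = df[df["cv"].notna()]
    if len(ok) and ok["volume_vox"].sum() > 0:
        w = ok["volume_vox"].to_numpy(float)
        cvs = ok["cv"].to_numpy(float)
        wmean = float((cvs * w).sum() / w.sum())
        order = np.argsort(cvs)
        cum = np.cumsum(w[order])
        wmedian = float(cvs[order][np.searchsorted(cum, cum[-1] / 2.0)])
    else:
        wmean = wmedian = float("nan")
    return LabelIntensityStats(df, wmean, wmedian)
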