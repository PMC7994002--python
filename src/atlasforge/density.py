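"""Nuclei-level atlas measurements: per-voxel heat maps, per-label counts,
volumes and densities, and DBSCAN-based label-quality scoring.

A poorly aligned label boundary captures nuclei from a neighboring region as
isolated pockets; density-based clustering flags those as noise, so the total
DBSCAN noise count over labels works as a label-misalignment indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .volumes import LabelVolume

__all__ = [
    "HeatMap",
    "ClusterParams",
    "dbscan_min_samples",
    "nuclei_heatmap",
    "per_label_stats",
    "cluster_label_nuclei",
    "knn_elbow_distances",
]


def dbscan_min_samples(ndim: int = 3) -> int:
    """Rule-of-thumb minimum samples for DBSCAN: 2·ndim (6 for 3D points)."""
    return 2 * ndim


@dataclass
class HeatMap:
    counts: np.ndarray  # 3D integer array
    scale: tuple[float, float, float]
    n_out_of_bounds: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClusterParams:
    eps: float = 20.0  # µm
    min_samples: int = dbscan_min_samples(3)

    def __post_init__(self):
        if self.eps <= 0 or self.min_samples < 1:
            raise ValueError("need eps > 0 and min_samples >= 1")


def nuclei_heatmap(blobs: np.ndarray, scale, shape) -> HeatMap:
    """Count nuclei per voxel of a (typically downsampled) grid.

    Blob centers are multiplied by per-axis ``scale``, rounded to the nearest
    voxel and accumulated; out-of-bounds blobs are dropped and counted.
    """
    scale = np.broadcast_to(np.asarray(scale, float), (3,))
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    shape = tuple(int(n) for n in shape)
    counts = np.zeros(shape, dtype=np.int64)
    n_oob = 0
    if len(blobs):
        coords = np.rint(np.atleast_2d(blobs)[:, :3] * scale).astype(int)
        inb = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
        n_oob = int((~inb).sum())
        np.add.at(counts, tuple(coords[inb].T), 1)
    return HeatMap(counts, tuple(scale), n_oob)


def per_label_stats(
    heatmap: HeatMap, labels: LabelVolume, spacing=None
) -> pd.DataFrame:
    """Per-label nuclei count, physical volume, density and within-label CV.

    Volume is voxel count × voxel volume converted to mm³ (spacing in µm);
    density is nuclei/mm³; the CV is the population σ/µ of the per-voxel
    counts inside the label.  Ontology names are joined when available.
    """
    if heatmap.counts.shape != labels.shape:
        raise ValueError("heat map and labels must share shape")
    sp = tuple(float(s) for s in (spacing if spacing is not None else labels.spacing))
    vox_mm3 = float(np.prod(sp)) * 1e-9
    rows = []
    for lid in labels.label_ids():
        sel = labels.data == lid
        vals = heatmap.counts[sel].astype(float)
        n = float(vals.sum())
        vol = float(sel.sum()) * vox_mm3
        mu = float(vals.mean())
        cv = float(vals.std() / mu) if mu > 0 else np.nan
        rows.append(
            dict(label_id=int(lid), count=int(n), volume_mm3=vol,
                 density_per_mm3=n / vol if vol > 0 else np.nan, density_cv=cv)
        )
    df = pd.DataFrame(rows)
    if labels.ontology is not None and len(df):
        names = labels.ontology.set_index("id")["name"]
        df.insert(1, "name", df["label_id"].map(names))
    return df


def blob_labels(blobs: np.ndarray, labels: LabelVolume) -> np.ndarray:
    """Label ID at each blob's rounded voxel (0 outside every label/bounds).

    The same rounded-voxel rule is used for counting and clustering so the
    two always agree on boundary blobs.
    """
    if len(blobs) == 0:
        return np.zeros(0, dtype=labels.data.dtype)
    coords = np.rint(np.atleast_2d(blobs)[:, :3]).astype(int)
    out = np.zeros(len(coords), dtype=labels.data.dtype)
    inb = np.all((coords >= 0) & (coords < np.array(labels.shape)), axis=1)
    out[inb] = labels.data[tuple(coords[inb].T)]
    return out


def cluster_label_nuclei(
    blobs: np.ndarray,
    labels: LabelVolume,
    spacing=None,
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Per-label DBSCAN clustering of nuclei coordinates.

    Blob centers (given in the label volume's voxel frame) are converted to
    µm, grouped by enclosing label, and clustered independently per label —
    a cluster never spans labels.  Returns cluster and noise counts per label;
    labels without nuclei report (0, 0).
    """
    params = params or ClusterParams()
    sp = np.asarray(spacing if spacing is not None else labels.spacing, float)
    lab_of_blob = blob_labels(blobs, labels)
    rows = []
    for lid in labels.label_ids():
        pts = np.atleast_2d(blobs)[lab_of_blob == lid][:, :3] * sp \
            if len(blobs) else np.empty((0, 3))
        if len(pts) == 0:
            rows.append(dict(label_id=int(lid), n_nuclei=0, n_clusters=0, n_noise=0))
            continue
        fit = DBSCAN(eps=params.eps, min_samples=params.min_samples).fit(pts)
        lab = fit.labels_
        rows.append(
            dict(label_id=int(lid), n_nuclei=len(pts),
                 n_clusters=int(len(set(lab[lab >= 0]))),
                 n_noise=int((lab == -1).sum()))
        )
    return pd.DataFrame(rows)


def knn_elbow_distances(
    points: np.ndarray,
    k: int = dbscan_min_samples(3) - 1,
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Sorted k-th nearest-neighbor distances (µm) for eps elbow inspection.

    The conventional k is ``2·ndim − 1`` (5 for 3D); the elbow of the sorted
    curve suggests the DBSCAN eps.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) <= k:
        raise ValueError(f"need more than k={k} points, got {len(points)}")
    pts = points[:, :3] * np.asarray(spacing, float)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)  # first neighbor is the point itself
    return np.sort(dists[:, k])
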