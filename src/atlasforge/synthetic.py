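"""Synthetic atlas and nuclei phantoms with exact ground truth.

The atlas phantom emulates the defect classes of plane-wise-annotated
volumetric atlases: per-plane boundary jitter (jagged edges in orthogonal
views), a run of unlabeled lateral planes, and one fully unlabeled
hemisphere.  Regions are nested ellipsoid shells, split dorsoventrally so
every label has its own mean intensity and therefore a detectable anatomical
edge; the layout is symmetric about the mid-sagittal plane so mirroring and
extension have meaningful ground truth.  The nuclei phantom scatters
quasi-spherical Gaussian-profile blobs of known centers and radii on a noisy
background.

All generators are pure functions of their parameters (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morph import disk_dilation, disk_erosion
from .volumes import LabelVolume, Volume, nearest_label_fill

__all__ = [
    "AtlasFixtureParams",
    "NucleiFixtureParams",
    "make_synthetic_atlas",
    "make_synthetic_nuclei_volume",
]


@dataclass
class AtlasFixtureParams:
    """Atlas phantom settings.

    Defaults give the standard jagged fixture: 128³ voxels, 12 labels
    (11 shell halves plus one sparse fragmented label), boundary jitter of up
    to 4 voxels per plane — chosen so the degraded-vs-true per-label Dice sits
    near 0.76, a typical disagreement level between plane-wise annotations
    and their anatomy-refined counterparts.  ``unlabeled_fraction`` clears
    that fraction of lateral (low-index) planes; ``drop_hemisphere`` clears
    planes past the midline.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    n_regions: int = 12
    intensity_range: tuple[float, float] = (60.0, 230.0)
    background_intensity: float = 5.0
    noise_sd: float = 2.0
    jitter: int = 4
    unlabeled_fraction: float = 0.0
    drop_hemisphere: bool = False
    fragmented_label: bool = True
    n_fragments: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if not (0 <= self.unlabeled_fraction < 0.5):
            raise ValueError("unlabeled_fraction must be in [0, 0.5)")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")


@dataclass
class NucleiFixtureParams:
    """Nuclei phantom settings.

    A blob of nominal radius r has a Gaussian intensity profile with
    σ = r/√3, the scale at which a LoG detector responds maximally.  SNR is
    peak blob amplitude over background noise σ.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nuclei: int = 200
    radius_mean: float = 3.0
    radius_sd: float = 0.3
    min_separation: float = 8.0
    edge_margin: float = 6.0
    snr: float = 5.0
    amplitude: float = 1.0
    #: "poisson": shot-noise-limited fluorescence — Poisson noise on the
    #: signal with peak SNR = snr, plus additive camera read noise (dark
    #: background, as in cleared-tissue lightsheet imaging).  "gaussian":
    #: additive white noise of sd amplitude/snr everywhere.
    noise_model: str = "poisson"
    read_noise: float = 0.01
    seed: int = 0
    max_attempts: int = 200_000

    def __post_init__(self):
        if self.min_separation < 0 or self.snr <= 0:
            raise ValueError("need min_separation >= 0 and snr > 0")


def _shell_labels(shape, n_regions: int) -> np.ndarray:
    """Nested ellipsoid shells, outer shells split into dorsal/ventral halves.

    Produces ``n_regions - 1`` regular labels: an innermost core plus split
    shells (the last region ID is reserved for the fragmented label).
    """
    n_regular = n_regions - 1
    n_shells = n_regular // 2 + 1  # core + split shells
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.45 * n for n in shape]
    r2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    # shell boundaries: equal radial steps from core to outer surface
    radii = np.linspace(0.25, 1.0, n_shells)
    labels = np.zeros(shape, dtype=np.int32)
    dorsal = yy < center[1]
    next_id = 1
    core = r2 <= radii[0] ** 2
    labels[core] = next_id
    next_id += 1
    for i in range(1, n_shells):
        shell = (r2 > radii[i - 1] ** 2) & (r2 <= radii[i] ** 2)
        labels[shell & dorsal] = next_id
        second = next_id + 1 if next_id + 1 <= n_regular else next_id
        labels[shell & ~dorsal] = second
        next_id += 2
    return labels


def make_synthetic_atlas(
    params: AtlasFixtureParams | None = None,
) -> tuple[Volume, LabelVolume, LabelVolume]:
    """Build (intensity volume, true labels, degraded labels).

    Degradation: per plane, each region's 2D mask is independently dilated or
    eroded by a random radius up to ``jitter`` and repainted (larger regions
    first), then unlabeled gaps inside the true foreground are re-assigned to
    their nearest label so the degraded labels remain a partition of the true
    foreground with jagged boundaries.  Optionally, lateral planes are cleared
    and one hemisphere dropped.  Same seed, same output, bit for bit.
    """
    params = params or AtlasFixtureParams()
    rng = np.random.default_rng(params.seed)
    true = _shell_labels(params.shape, params.n_regions)

    frag_id = 0
    if params.fragmented_label:
        frag_id = params.n_regions
        # scatter strictly interior to the core, deeper than the maximum
        # per-plane boundary recession, so every fragment voxel stays
        # embedded in the core label even after degradation; small volumes
        # fall back to shallower embedding rather than dropping the label
        depth = params.jitter + 1
        while depth > 0:
            interior = ndimage.binary_erosion(true == 1, iterations=depth)
            if interior.any():
                break
            depth -= 1
        else:
            interior = true == 1
        core_vox = np.argwhere(interior)
        picks = core_vox[
            rng.choice(len(core_vox), size=min(params.n_fragments, len(core_vox)),
                       replace=False)
        ]
        true[tuple(picks.T)] = frag_id

    ids = np.unique(true)
    ids = ids[ids != 0]
    lo, hi = params.intensity_range
    means = {int(l): m for l, m in zip(ids, np.linspace(lo, hi, len(ids)))}
    intensity = np.full(params.shape, params.background_intensity, dtype=float)
    for lid, m in means.items():
        intensity[true == lid] = m
    intensity += rng.normal(0.0, params.noise_sd, params.shape)
    intensity = np.clip(intensity, 0, None)

    degraded = np.zeros_like(true)
    sizes = {int(l): int((true == l).sum()) for l in ids}
    paint_order = sorted(sizes, key=sizes.get, reverse=True)
    fg3d = true != 0
    for p in range(params.shape[0]):
        plane_true = true[p]
        plane_fg = fg3d[p]
        if not plane_fg.any():
            continue
        plane = np.zeros_like(plane_true)
        for lid in paint_order:
            m = plane_true == lid
            if not m.any():
                continue
            if lid != frag_id and params.jitter > 0:
                r = int(rng.integers(-params.jitter, params.jitter + 1))
                if r > 0:
                    m = disk_dilation(m, r)
                elif r < 0:
                    m = disk_erosion(m, -r)
                if not m.any():
                    m = plane_true == lid  # never lose a region outright
            plane[m] = lid
        plane[~plane_fg] = 0
        # fragment voxels must stay isolated single-voxel sites: they do not
        # donate to gap in-painting and are repainted afterwards
        frag_sites = plane_true == frag_id if frag_id else None
        if frag_id:
            plane[frag_sites] = 0
        gaps = plane_fg & (plane == 0)
        if gaps.any() and (plane != 0).any():
            plane = nearest_label_fill(plane, gaps)
        if frag_id:
            plane[frag_sites] = frag_id
        degraded[p] = plane

    n = params.shape[0]
    n_unlabeled = int(round(params.unlabeled_fraction * n))
    if n_unlabeled:
        degraded[:n_unlabeled] = 0
    if params.drop_hemisphere:
        degraded[n // 2:] = 0

    spacing = (1.0, 1.0, 1.0)
    vol = Volume(intensity, spacing)
    return (
        vol,
        LabelVolume(true, spacing),
        LabelVolume(degraded, spacing),
    )


def make_synthetic_nuclei_volume(
    params: NucleiFixtureParams | None = None,
) -> tuple[Volume, np.ndarray]:
    """Build (noisy intensity volume, truth blobs as an (n, 4) z,y,x,r array).

    Centers are rejection-sampled to honor ``min_separation`` (and an edge
    margin so no truth nucleus is clipped by the volume border); raises if the
    requested density cannot be placed within a bounded number of attempts.
    """
    params = params or NucleiFixtureParams()
    rng = np.random.default_rng(params.seed)
    shape = np.array(params.shape, float)
    lo = params.edge_margin
    hi = shape - params.edge_margin
    centers: list[np.ndarray] = []
    placed = np.empty((0, 3))
    attempts = 0
    while len(centers) < params.n_nuclei:
        if attempts >= params.max_attempts:
            raise RuntimeError(
                f"placed only {len(centers)}/{params.n_nuclei} nuclei after "
                f"{attempts} attempts; density incompatible with min_separation"
            )
        attempts += 1
        c = rng.uniform(lo, hi)
        if len(placed) == 0 or np.min(
            np.linalg.norm(placed - c, axis=1)
        ) >= params.min_separation:
            centers.append(c)
            placed = np.vstack([placed, c])
    radii = np.clip(
        rng.normal(params.radius_mean, params.radius_sd, params.n_nuclei),
        0.5 * params.radius_mean,
        1.5 * params.radius_mean,
    )
    data = np.zeros(params.shape, dtype=float)
    for c, r in zip(centers, radii):
        sigma = r / np.sqrt(3.0)
        ext = int(np.ceil(3 * sigma)) + 1
        lo_i = np.maximum(np.floor(c - ext).astype(int), 0)
        hi_i = np.minimum(np.ceil(c + ext).astype(int) + 1, np.array(params.shape))
        sl = tuple(slice(a, b) for a, b in zip(lo_i, hi_i))
        grid = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo_i, hi_i)), indexing="ij")
        d2 = sum((g - cc) ** 2 for g, cc in zip(grid, c))
        data[sl] += params.amplitude * np.exp(-d2 / (2 * sigma**2))
    if params.noise_model == "poisson":
        gain = params.snr**2 / params.amplitude  # counts per intensity unit
        data = rng.poisson(data * gain).astype(float) / gain
        data += rng.normal(0.0, params.read_noise * params.amplitude, params.shape)
    elif params.noise_model == "gaussian":
        data += rng.normal(0.0, params.amplitude / params.snr, params.shape)
    else:
        raise ValueError(f"unknown noise model {params.noise_model}")
    data = np.clip(data, 0, None)
    truth = np.column_stack([np.array(centers), radii])
    return Volume(data, params.spacing), truth
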