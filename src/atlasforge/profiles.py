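"""Per-atlas parameter profiles and pipeline orchestration.

Each source atlas needs its own bundle of settings (extension start, rotation
angles, mirror fraction, filter radii, optional affine shears and non-CNS
stripping); profiles are plain YAML so a run is fully described by one file.
The repository ships profiles for the eight developing-mouse atlases with the
published rotation/mirroring values.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .density import ClusterParams
from .detection import DetectParams
from .edges import EdgeMapParams
from .metrics import dice, edge_distance_stats, intensity_cv, smoothing_report
from .reconstruct import (
    ExtensionParams,
    MirrorParams,
    expand_compressed_planes,
    extend_labels_lateral,
    find_extension_start,
    mirror_across_midline,
    piecewise_affine_shear,
    rotate_to_midline,
    strip_non_cns,
)
from .refine import RefineParams, refine_atlas
from .smoothing import SmoothParams, records_frame
from .edges import anatomical_edge_map
from .volumes import LabelVolume, Mask, Volume

__all__ = [
    "Profile",
    "load_profile",
    "builtin_profile_names",
    "run_atlas_pipeline",
    "run_detection_pipeline",
]


@dataclass
class Profile:
    """Named bundle of per-stage parameters for one atlas or dataset."""

    name: str = "default"
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    mirror: MirrorParams = field(default_factory=MirrorParams)
    refine: RefineParams = field(default_factory=RefineParams)
    smooth: SmoothParams = field(default_factory=SmoothParams)
    edge_map: EdgeMapParams = field(default_factory=EdgeMapParams)
    detect: DetectParams = field(default_factory=DetectParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    expand_planes: tuple[int, int] | None = None
    affines: list = field(default_factory=list)  # piecewise_affine_shear kwargs
    do_extension: bool = True
    do_mirror: bool = True
    do_refine: bool = True
    do_smooth: bool = True
    strip_non_cns: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "Profile":
        kwargs = {}
        sub = dict(
            extension=ExtensionParams, mirror=MirrorParams, refine=RefineParams,
            smooth=SmoothParams, edge_map=EdgeMapParams, detect=DetectParams,
            cluster=ClusterParams,
        )
        for key, val in d.items():
            if key in sub:
                if key == "detect" and "chunk_shape" in val:
                    val = dict(val, chunk_shape=tuple(val["chunk_shape"]))
                if key == "mirror" and "rotations" in val:
                    val = dict(val, rotations=[tuple(r) for r in val["rotations"]])
                if key == "refine" and isinstance(val.get("post_smooth"), dict):
                    val = dict(val, post_smooth=SmoothParams(**val["post_smooth"]))
                kwargs[key] = sub[key](**val)
            elif key == "expand_planes" and val is not None:
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_profile(source: str | Path) -> Profile:
    """Load a profile from a YAML path or a built-in profile name."""
    path = Path(source)
    if not path.exists():
        res = importlib.resources.files("atlasforge") / "profiles" / f"{source}.yaml"
        if not res.is_file():
            raise FileNotFoundError(f"no profile file or built-in named {source!r}")
        text = res.read_text()
    else:
        text = path.read_text()
    return Profile.from_dict(yaml.safe_load(text))


def builtin_profile_names() -> list[str]:
    root = importlib.resources.files("atlasforge") / "profiles"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def run_atlas_pipeline(
    vol: Volume,
    labels: LabelVolume,
    profile: Profile | None = None,
) -> tuple[Volume, LabelVolume, dict]:
    """Reconstruct and refine an atlas pair end to end.

    Stage order: optional compressed-plane expansion → lateral extension →
    rotation → optional piecewise affine shears → mirroring → optional
    non-CNS stripping → edge-aware 3D refinement → adaptive smoothing (the
    refinement's own post-smoothing).  Returns the processed pair and a
    report dict of per-stage metrics.
    """
    profile = profile or Profile()
    report: dict = {"stages": []}
    cur_vol, cur_labels = vol, labels

    def stage(name):
        report["stages"].append(name)

    if profile.expand_planes is not None:
        stage("expand_compressed_planes")
        cur_labels = expand_compressed_planes(
            cur_vol, cur_labels, profile.expand_planes, profile.extension
        )
    if profile.do_extension:
        stage("extend_labels_lateral")
        n = cur_labels.shape[0]
        override = (
            int(round(profile.extension.start_fraction * n))
            if profile.extension.start_fraction is not None
            else None
        )
        start = find_extension_start(cur_labels, override, profile.extension)
        edge_map = anatomical_edge_map(cur_vol, cur_labels, profile.edge_map)
        cur_labels = extend_labels_lateral(
            cur_vol, cur_labels, start, edge_map, profile.extension
        )
        report["extension_start"] = start
    if profile.mirror.rotations:
        stage("rotate_to_midline")
        cur_vol = rotate_to_midline(cur_vol, profile.mirror.rotations)
        cur_labels = rotate_to_midline(cur_labels, profile.mirror.rotations)
    for aff in profile.affines:
        stage("piecewise_affine_shear")
        kw = dict(aff)
        kw["roi"] = tuple(slice(*ab) for ab in kw["roi"])
        cur_vol = piecewise_affine_shear(cur_vol, **kw)
        cur_labels = piecewise_affine_shear(cur_labels, **kw)
    if profile.do_mirror:
        stage("mirror_across_midline")
        cur_vol, cur_labels = mirror_across_midline(cur_vol, cur_labels, profile.mirror)
    if profile.strip_non_cns:
        stage("strip_non_cns")
        cur_vol, cur_labels = strip_non_cns(cur_vol, cur_labels)
    if profile.do_refine:
        stage("refine_atlas")
        pre_refine = cur_labels
        cur_labels, refine_report = refine_atlas(
            cur_vol, cur_labels, profile.refine, profile.edge_map
        )
        report["refine"] = refine_report
        report["smoothing"] = smoothing_report(pre_refine, cur_labels)
    return cur_vol, cur_labels, report


def run_detection_pipeline(
    vol: Volume,
    profile: Profile | None = None,
    truth: np.ndarray | None = None,
    labels: LabelVolume | None = None,
    match_tol: float = 5.0,
) -> dict:
    """Whole-volume nuclei detection plus optional evaluation and density stats."""
    from .density import cluster_label_nuclei, nuclei_heatmap, per_label_stats
    from .detection import detect_whole_volume, evaluate_detections

    profile = profile or Profile()
    blobs = detect_whole_volume(vol, profile.detect)
    out: dict = {"blobs": blobs, "n_blobs": len(blobs)}
    if truth is not None:
        res = evaluate_detections(blobs, truth, match_tol, vol.spacing)
        out["match"] = res
        out["recall"] = res.recall
        out["precision"] = res.precision
    if labels is not None:
        scale = tuple(ls / vs for ls, vs in zip(labels.shape, vol.shape))
        hm = nuclei_heatmap(blobs, scale, labels.shape)
        out["heatmap"] = hm
        out["label_stats"] = per_label_stats(hm, labels)
        scaled = blobs.copy()
        if len(scaled):
            scaled[:, :3] *= scale
        out["clusters"] = cluster_label_nuclei(scaled, labels, params=profile.cluster)
    return out
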