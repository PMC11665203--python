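"""Configuration schema and the end-to-end per-subject / study pipelines."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from pamvasc import binarize, imgio, morphometry, plaque, stats, vesselness
from pamvasc.bins import DEFAULT_BINS_UM, bin_label

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    equalize: bool = True
    clahe: bool = False
    background_method: str = "median"
    background_roi: Optional[List[int]] = None  # [r0, r1, c0, c1]


@dataclass
class ScaleConfig:
    kernel_px: int = 3
    beta: float = 0.5
    c_mode: str = "adaptive"
    c_value: Optional[float] = None

    def to_params(self) -> vesselness.VesselnessParams:
        return vesselness.VesselnessParams(
            kernel_px=self.kernel_px,
            beta=self.beta,
            c_mode=self.c_mode,
            c_value=self.c_value,
        )


@dataclass
class VesselnessConfig:
    small: ScaleConfig = field(default_factory=lambda: ScaleConfig(kernel_px=3))
    large: ScaleConfig = field(default_factory=lambda: ScaleConfig(kernel_px=30))


@dataclass
class ThresholdConfig:
    factor: float = 1.1
    map2_method: str = "otsu"  # paper-gap: Frangi binarization unstated
    map2_level: Optional[float] = None
    map3_method: str = "otsu"  # paper-gap
    map3_level: Optional[float] = None
    min_object_px: int = 0  # paper-gap: no cleanup by default


@dataclass
class MorphometryConfig:
    prune_len_px: float = 10.0  # paper-gap
    tip_correction: bool = False
    bins_um: List[float] = field(default_factory=lambda: list(DEFAULT_BINS_UM))


@dataclass
class PlaqueConfig:
    spot_fwhm_um: float = 15.0  # paper-gap: plaque size unstated
    min_sep_um: float = 30.0
    rel_threshold: float = 0.3


@dataclass
class StatsConfig:
    welch: bool = False


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration; defaults follow the published workflow
    (threshold factor 1.1, kernel scales 3 and 30 px, 2 x 2 mm / 512 x 512
    geometry), with paper-gap defaults marked in the shipped example config."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vesselness: VesselnessConfig = field(default_factory=VesselnessConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    plaque: PlaqueConfig = field(default_factory=PlaqueConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    pixel_pitch_um: float = 2000.0 / 512.0
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build(cls, data: Any, path: str):
    if not dataclasses.is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path or '<root>'}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        sub = f.type if dataclasses.is_dataclass(f.type) else None
        # dataclass-typed fields carry a default_factory producing a dataclass
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default):
            kwargs[key] = _build(type(default), value, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: Union[str, Path, None] = None) -> PipelineConfig:
    """Load and schema-validate a YAML config; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _build(PipelineConfig, data, "")
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    cfg.vesselness.small.to_params()
    cfg.vesselness.large.to_params()
    binarize.ThresholdParams(factor=cfg.threshold.factor)
    if cfg.pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be > 0")
    if cfg.morphometry.prune_len_px < 0:
        raise ValueError("prune_len_px must be >= 0")


def compute_maps(
    image: imgio.IntensityImage, cfg: PipelineConfig
) -> Dict[str, binarize.BinaryVesselMask]:
    """Preprocess + the three candidate maps + their combination."""
    work = image
    if cfg.preprocess.equalize:
        work = imgio.equalize(image, clahe=cfg.preprocess.clahe)
    roi = cfg.preprocess.background_roi
    if roi is not None:
        bg = imgio.estimate_background(work, (slice(roi[0], roi[1]), slice(roi[2], roi[3])))
    else:
        bg = imgio.estimate_background(work, method=cfg.preprocess.background_method)
    m1 = binarize.map1_global(work, bg, binarize.ThresholdParams(factor=cfg.threshold.factor))
    v_small = vesselness.frangi(work, cfg.vesselness.small.to_params())
    v_large = vesselness.frangi(work, cfg.vesselness.large.to_params())
    m2 = binarize.map_from_vesselness(
        v_small,
        method=cfg.threshold.map2_method,
        level=cfg.threshold.map2_level,
        source="MAP2",
        min_object_px=cfg.threshold.min_object_px,
    )
    m3 = binarize.map_from_vesselness(
        v_large,
        method=cfg.threshold.map3_method,
        level=cfg.threshold.map3_level,
        source="MAP3",
    )
    mult = binarize.combine_maps(m1, m2, m3)
    return {"MAP1": m1, "MAP2": m2, "MAP3": m3, "MAPult": mult}


def analyze_image(
    image: imgio.IntensityImage, cfg: PipelineConfig
) -> Tuple[Dict[str, binarize.BinaryVesselMask], morphometry.VesselGraph, morphometry.VLDProfile]:
    """Binarization maps, vessel graph and VLD profile for one angiogram."""
    maps = compute_maps(image, cfg)
    skel = morphometry.skeletonize_mask(maps["MAPult"])
    graph = morphometry.build_graph(
        skel,
        maps["MAPult"],
        image.pixel_pitch_um,
        prune_len_px=cfg.morphometry.prune_len_px,
        tip_correction=cfg.morphometry.tip_correction,
    )
    profile = morphometry.vld_profile(graph, cfg.morphometry.bins_um)
    return maps, graph, profile


def _write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint8) * 255)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_subject(
    pam: Union[imgio.IntensityImage, str, Path],
    cfg: PipelineConfig,
    out_dir: Union[str, Path],
    cfm: Union[imgio.IntensityImage, str, Path, None] = None,
    name: str = "subject",
) -> Dict[str, Any]:
    """Run the full single-subject pipeline and write all artifacts.

    Writes MAP1/2/3/MAPult and the skeleton as TIFF, segment and VLD tables
    as CSV, the plaque result (when a CFM frame is given) as CSV, and a JSON
    manifest with the config digest and artifact checksums. Deterministic:
    re-running with identical inputs and config reproduces the outputs.
    """
    if isinstance(pam, (str, Path)):
        pam = imgio.load_image(pam, cfg.pixel_pitch_um, modality="PAM")
    if isinstance(cfm, (str, Path)):
        cfm = imgio.load_image(cfm, cfg.pixel_pitch_um, modality="CFM")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    maps, graph, profile = analyze_image(pam, cfg)
    artifacts: Dict[str, str] = {}
    for key, m in maps.items():
        p = out / f"{name}_{key}.tif"
        _write_mask(p, m.mask)
        artifacts[key] = p.name
    skel = morphometry.skeletonize_mask(maps["MAPult"])
    _write_mask(out / f"{name}_skeleton.tif", skel)
    artifacts["skeleton"] = f"{name}_skeleton.tif"

    seg_rows = [
        {
            "segment_id": i,
            "length_um": s.length_um,
            "mean_diameter_um": s.mean_diameter_um,
            "bin": bin_label(
                morphometry.assign_bin(s.mean_diameter_um, cfg.morphometry.bins_um)
            ),
        }
        for i, s in enumerate(graph.segments)
    ]
    pd.DataFrame(
        seg_rows, columns=["segment_id", "length_um", "mean_diameter_um", "bin"]
    ).to_csv(out / f"{name}_segments.csv", index=False)
    artifacts["segments"] = f"{name}_segments.csv"

    vld_rows = [
        {"bin": bin_label(b), "vld_mm_per_mm2": v} for b, v in profile.vld_per_bin.items()
    ]
    vld_rows.append({"bin": "total", "vld_mm_per_mm2": profile.total_vld})
    pd.DataFrame(vld_rows).to_csv(out / f"{name}_vld.csv", index=False)
    artifacts["vld"] = f"{name}_vld.csv"

    plaque_result = None
    if cfm is not None:
        plaque_result = plaque.detect_plaques(
            cfm,
            min_sep_um=cfg.plaque.min_sep_um,
            spot_fwhm_um=cfg.plaque.spot_fwhm_um,
            rel_threshold=cfg.plaque.rel_threshold,
        )
        pd.DataFrame(
            plaque_result.coordinates, columns=["x_um", "y_um"]
        ).to_csv(out / f"{name}_plaques.csv", index=False)
        artifacts["plaques"] = f"{name}_plaques.csv"

    manifest = {
        "name": name,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "pixel_pitch_um": pam.pixel_pitch_um,
        "artifacts": {k: {"file": v, "sha256": _sha256(out / v)} for k, v in artifacts.items()},
        "total_vld_mm_per_mm2": profile.total_vld,
        "n_segments": len(graph.segments),
        "plaque_count": plaque_result.count if plaque_result else None,
    }
    (out / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "maps": maps,
        "graph": graph,
        "vld": profile,
        "plaque": plaque_result,
        "manifest": manifest,
    }


def run_study(
    study_dir: Union[str, Path],
    cfg: PipelineConfig,
    out_dir: Union[str, Path],
) -> pd.DataFrame:
    """Run every subject under ``study_dir/<group>/*.tif`` and compare groups.

    A ``<stem>.json`` sidecar may override the pixel pitch per subject; all
    subjects must share one pitch (offenders are named otherwise). Each group
    needs at least two subjects.
    """
    study_dir = Path(study_dir)
    out = Path(out_dir)
    groups = sorted(d for d in study_dir.iterdir() if d.is_dir())
    if not groups:
        raise ValueError(f"{study_dir}: no group subdirectories found")
    pitches: Dict[str, float] = {}
    subjects: List[Tuple[str, Path, float]] = []
    for gdir in groups:
        tifs = sorted(gdir.glob("*.tif"))
        if len(tifs) < 2:
            raise ValueError(f"group {gdir.name!r} has {len(tifs)} subjects; need >= 2")
        for t in tifs:
            sidecar = t.with_suffix(".json")
            pitch = cfg.pixel_pitch_um
            if sidecar.exists():
                pitch = float(json.loads(sidecar.read_text())["pixel_pitch_um"])
            pitches[f"{gdir.name}/{t.name}"] = pitch
            subjects.append((gdir.name, t, pitch))
    if len(set(pitches.values())) > 1:
        values = list(pitches.values())
        modal = max(set(values), key=values.count)
        offenders = [k for k, v in pitches.items() if v != modal]
        raise ValueError(f"mixed pixel pitches across subjects: {offenders}")

    results: List[stats.SubjectResult] = []
    for group, tif, pitch in subjects:
        image = imgio.load_image(tif, pitch, modality="PAM")
        res = run_subject(image, cfg, out / group, name=tif.stem)
        cfm_path = tif.with_name(tif.stem + "_cfm.tif")
        plaque_result = None
        if cfm_path.exists():
            cfm = imgio.load_image(cfm_path, pitch, modality="CFM")
            plaque_result = plaque.detect_plaques(
                cfm,
                min_sep_um=cfg.plaque.min_sep_um,
                spot_fwhm_um=cfg.plaque.spot_fwhm_um,
                rel_threshold=cfg.plaque.rel_threshold,
            )
        results.append(stats.SubjectResult(group, res["vld"], plaque_result))

    comparisons = stats.compare_cohort(results, welch=cfg.stats.welch)
    report = stats.comparisons_to_frame(comparisons)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "study_report.csv", index=False)
    return report
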