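"""Volume/annotation/result I/O and the end-to-end pipeline driver.

Volumes are stored in a documented HDF5 layout (version attribute
``mfoct_layout``): two complex ``(z, x, y, t)`` datasets ``S_V`` and ``S_H``
and the required root attributes ``pixel_size_axial_um``,
``pixel_size_lateral_um`` and ``bscan_period_s``.  Annotations are JSON
(``onh``, ``lesions``, ``deposits``); per-acquisition results go to a CSV
with one row per :class:`StudyRecord`; en-face maps export to 32-bit float
TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import evaluation, octa, preprocess, projections, pscontrast, segmentation
from .core import DualChannelVolume, EnFaceMap, FormatError, SurfaceSet
from .evaluation import AnnulusSpec, SeedAnnotations

LAYOUT_VERSION = "1.0"
_REQUIRED_ATTRS = ("pixel_size_axial_um", "pixel_size_lateral_um", "bscan_period_s")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class StudyRecord:
    """One longitudinal study observation (one acquisition of one eye)."""

    mouse: str
    eye: str                              # "left" / "right"
    postnatal_day: int
    acquisition_id: str = ""
    metrics: dict = field(default_factory=dict)
    quality: str = "accepted"             # "accepted" / "rejected"

    def __post_init__(self) -> None:
        if self.postnatal_day <= 0:
            raise ValueError("postnatal day must be positive")
        if self.quality not in ("accepted", "rejected"):
            raise ValueError(f"unknown quality flag {self.quality!r}")
        if self.quality == "rejected" and self.metrics:
            raise ValueError("a rejected measurement must carry no metrics")


def records_to_frame(records: list[StudyRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "mouse": rec.mouse, "eye": rec.eye,
            "postnatal_day": rec.postnatal_day,
            "acquisition_id": rec.acquisition_id, "quality": rec.quality,
        }
        row.update(rec.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def write_volume(path, volume: DualChannelVolume) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["mfoct_layout"] = LAYOUT_VERSION
        f.attrs["pixel_size_axial_um"] = volume.pixel_size_axial_um
        f.attrs["pixel_size_lateral_um"] = volume.pixel_size_lateral_um
        f.attrs["bscan_period_s"] = volume.bscan_period_s
        f.create_dataset("S_V", data=volume.sv.astype(np.complex64))
        f.create_dataset("S_H", data=volume.sh.astype(np.complex64))


def read_volume(path) -> DualChannelVolume:
    """Read a dual-channel complex tomogram from the documented HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("S_V", "S_H"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r}")
        sv = f["S_V"][()]
        sh = f["S_H"][()]
        if not np.iscomplexobj(sv) or not np.iscomplexobj(sh):
            raise TypeError(f"{path}: channel datasets must be complex")
        volume = DualChannelVolume(
            sv=sv, sh=sh,
            pixel_size_axial_um=float(f.attrs["pixel_size_axial_um"]),
            pixel_size_lateral_um=float(f.attrs["pixel_size_lateral_um"]),
            bscan_period_s=float(f.attrs["bscan_period_s"]),
            meta={"path": str(path)},
        )
    if not volume.angiography_available:
        volume.meta["angiography_unavailable"] = True
    return volume


def write_annotations(path, ann: SeedAnnotations) -> None:
    payload = {
        "onh": list(ann.onh),
        "lesions": [list(p) for p in ann.lesions],
        "deposits": [list(p) for p in ann.deposits],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path) -> SeedAnnotations:
    payload = json.loads(Path(path).read_text())
    for key in ("onh", "lesions", "deposits"):
        if key not in payload:
            raise FormatError(f"{path}: missing annotation field {key!r}")
    return SeedAnnotations(
        onh=tuple(payload["onh"]),
        lesions=[tuple(p) for p in payload["lesions"]],
        deposits=[tuple(p) for p in payload["deposits"]],
    )


def write_enface_tiff(path, enface: EnFaceMap) -> None:
    tifffile.imwrite(path, enface.values.astype(np.float32))


@dataclass
class PipelineConfig:
    """Processing parameters; defaults follow the study protocol."""

    dopu_window: tuple[int, int, int] = (3, 9, 5)
    variance_slab_px: int = 50
    annulus_inner_px: float = 125.0
    annulus_outer_px: float = 225.0
    annulus_coverage: float = 0.75
    depth_bins: int = 20
    background_margin_px: int = 20
    rpe_margin_px: int = 5
    max_step_px: int = 3
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "dopu_window" in payload:
            payload["dopu_window"] = tuple(payload["dopu_window"])
        return cls(**payload)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle produced by one end-to-end run."""

    record: StudyRecord
    surfaces: SurfaceSet | None
    maps: dict[str, EnFaceMap]
    dopu: pscontrast.DopuVolume | None
    angio: octa.AngioVolume | None
    averaged: preprocess.ReflectivityVolume | None
    meta: dict = field(default_factory=dict)


def run_full_pipeline(
    volume: DualChannelVolume,
    annotations: SeedAnnotations,
    config: PipelineConfig | None = None,
    mouse: str = "unknown",
    eye: str = "left",
    postnatal_day: int = 1,
    acquisition_id: str = "",
) -> PipelineResult:
    """Execute every stage in order on one acquisition.

    Pre-processing (motion compensation, flattening), multi-functional
    contrast (DOPU, angiography), repeat averaging, layer segmentation with
    3D refinement and reference fit, en-face projections and the
    quantitative evaluation.  A failed segmentation sanity check marks the
    record rejected instead of raising, mirroring manual quality rejection.
    """
    config = config or PipelineConfig()
    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "input_path": volume.meta.get("path", "<memory>"),
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError(name, exc) from exc

    refl = stage("reflectivity", lambda: preprocess.compute_reflectivity(volume))
    motion = stage("motion_estimation", lambda: preprocess.build_motion_model(refl))
    flat = stage("motion_compensation",
                 lambda: preprocess.compensate_and_flatten(volume, motion))
    refl_flat = stage("reflectivity_flattened",
                      lambda: preprocess.compute_reflectivity(flat))

    ilm_provisional = np.full(refl_flat.shape[1:3], float(motion.target_depth))
    background = stage(
        "background",
        lambda: pscontrast.estimate_background(
            refl_flat, ilm_provisional, margin=config.background_margin_px
        ),
    )
    stokes = stage("stokes", lambda: pscontrast.compute_stokes(flat))
    wz, wx, wt = config.dopu_window
    window = (wz, wx, min(wt, volume.n_repeats))   # t-window spans all repeats
    dopu = stage(
        "dopu",
        lambda: pscontrast.compute_dopu(stokes, background, window=window),
    )
    angio = None
    if volume.angiography_available:
        angio = stage("angiography", lambda: octa.compute_angio_volume(flat))
    averaged = stage(
        "repeat_averaging",
        lambda: preprocess.average_repeats(refl_flat, exclude=motion.severe),
    )
    surfaces = stage(
        "segmentation",
        lambda: segmentation.segment_all_layers(
            averaged.intensity, max_step=config.max_step_px
        ),
    )
    surfaces = stage("refinement", lambda: segmentation.refine_3d(surfaces))
    reference = stage(
        "reference_fit",
        lambda: segmentation.fit_reference_surface(surfaces["rpe"], surfaces["ch"]),
    )
    surfaces.surfaces["ref"] = reference
    surfaces.valid["ref"] = np.isfinite(reference)

    # segmentation sanity: ordering must hold almost everywhere
    ok_fraction = 1.0 - surfaces.ordering_violations().mean()
    rejected = ok_fraction < 0.95

    ax_um = volume.pixel_size_axial_um
    lat_um = volume.pixel_size_lateral_um
    maps = {}
    maps["variance"] = stage(
        "variance_map",
        lambda: projections.outer_retina_variance_map(
            averaged.intensity, reference, slab_px=config.variance_slab_px,
            pixel_size_um=lat_um,
        ),
    )
    for which in ("TR", "IR", "OR"):
        maps[f"thickness_{which.lower()}"] = stage(
            "thickness_map",
            lambda which=which: projections.thickness_map(
                surfaces, which, pixel_size_axial_um=ax_um,
                pixel_size_lateral_um=lat_um,
            ),
        )
    maps["min_dopu"] = stage(
        "min_dopu_map",
        lambda: projections.min_dopu_map(
            dopu, surfaces, rpe_margin=config.rpe_margin_px, pixel_size_um=lat_um
        ),
    )
    if angio is not None:
        maps["angio_depth"] = stage(
            "depth_coded_angio",
            lambda: projections.depth_coded_angio_map(
                angio, surfaces, pixel_size_um=lat_um
            ),
        )

    metrics: dict = {}
    if not rejected:
        annulus = AnnulusSpec(
            center=annotations.onh,
            inner_radius_px=config.annulus_inner_px,
            outer_radius_px=config.annulus_outer_px,
            min_coverage=config.annulus_coverage,
            pixel_size_um=lat_um,
        )
        for which in ("tr", "ir", "or"):
            value, reason = evaluation.annulus_mean_thickness(
                maps[f"thickness_{which}"], annulus
            )
            metrics[f"thickness_{which}_um"] = (
                value if value is not None else np.nan
            )
            if value is None:
                meta[f"thickness_{which}_reason"] = reason
        metrics["lesion_count"] = len(annotations.lesions)
        metrics["deposit_count"] = len(annotations.deposits)
        if len(annotations.lesions) >= 2:
            pairwise, nn = evaluation.lesion_spacing_stats(
                [(x, y) for (_, x, y) in annotations.lesions], pixel_size_um=lat_um
            )
            metrics["lesion_mean_pairwise_um"] = pairwise
            metrics["lesion_mean_nn_um"] = nn

    record = StudyRecord(
        mouse=mouse, eye=eye, postnatal_day=postnatal_day,
        acquisition_id=acquisition_id,
        metrics=metrics if not rejected else {},
        quality="rejected" if rejected else "accepted",
    )
    meta["ordering_ok_fraction"] = float(ok_fraction)
    return PipelineResult(
        record=record, surfaces=surfaces, maps=maps, dopu=dopu, angio=angio,
        averaged=averaged, meta=meta,
    )
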