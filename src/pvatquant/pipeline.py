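"""End-to-end orchestration: simulate -> segment -> profile -> classify ->
summarize -> regress, with a machine-readable log of every derived quantity.

Two input modes share the same downstream path:

* manifest mode — a CSV manifest of on-disk wall/fat image pairs plus
  external wall masks (the clinical layout);
* phantom mode — a ``CohortSpec`` is simulated in memory; either the truth
  masks are profiled directly (``render="masks"``, fast, exercises the
  geometry stages) or images are rendered and segmented (``render="images"``,
  the full path).

Each run writes the long-format cohort CSV, thresholds with derivation
provenance, the angular summary, the mixed-model fits, and a log recording
seeds, thresholds and counts (slices, cords, segments = slices x 72).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import angular, hierarchical, io, thresholds as thr
from .core import N_CORDS, SlicePair, ThresholdSet
from .geometry import profile_slice
from .phantom import CohortSpec, PhantomSpec, generate_slice, render_masks
from .segmentation import load_wall_mask, segment_pvat
from .core import SegmentationMask

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level configuration; see docs/methods.md for the YAML schema."""

    out_dir: str = "results"
    manifest: Optional[str] = None            # CSV of image pairs (manifest mode)
    cohort_spec: Optional[CohortSpec] = None  # phantom mode
    render: str = "masks"                     # "masks" | "images" (phantom mode)
    spacing_deg: float = 5.0
    subsample_step_deg: float = 20.0
    subsample_offset_deg: float = 0.0
    extent_overrides: dict = field(default_factory=dict)
    normal_patient_ids: Optional[list[str]] = None  # normal subsample for the cut
    run_stats: bool = True
    run_regression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(360.0 % self.spacing_deg, 0.0):
            raise ValueError("spacing_deg must divide 360")
        if not np.isclose(self.subsample_step_deg % self.spacing_deg, 0.0):
            raise ValueError("subsample step must be a multiple of spacing_deg")
        if self.manifest is None and self.cohort_spec is None:
            raise ValueError("config needs a manifest or a cohort_spec")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and offending slice id."""

    def __init__(self, stage: str, slice_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on slice {slice_id!r}: {cause}")
        self.stage = stage
        self.slice_id = slice_id


def _profile_pair(pair: SlicePair, wall_mask, pvat_mask, tset: ThresholdSet,
                  spacing_deg: float) -> pd.DataFrame:
    wall_p, pvat_p, center, _frame = profile_slice(
        pair, wall_mask, pvat_mask, tset, spacing_deg=spacing_deg)
    return pd.DataFrame({
        "patient_id": pair.patient_id,
        "vessel_class": pair.vessel_class,
        "slice_index": pair.slice_index,
        "angle_deg": wall_p.angles_deg,
        "wall_mm": wall_p.values_mm,
        "pvat_mm": pvat_p.values_mm,
        "normal_flag": True,
        "flags": wall_p.flags | pvat_p.flags,
    })


def _phantom_slices(spec: CohortSpec, render: str):
    """Yield (pair, wall_mask, pvat_mask) per simulated slice.

    ``masks`` mode rasterizes the sampled per-angle truth profiles directly;
    ``images`` mode renders noisy images and runs the 2-SD fat segmentation.
    """
    from .phantom import generate_cohort

    if render == "images":
        pairs, truths, _ = generate_cohort(spec, render=True)
        for pair, truth in zip(pairs, truths):
            pvat = segment_pvat(pair.fat_image, exclusion=None)
            yield pair, truth.wall_mask, pvat
        return

    _, _, cohort = generate_cohort(spec, render=False)
    for (pid, j), grp in cohort.groupby(["patient_id", "slice_index"], sort=True):
        grp = grp.sort_values("angle_deg")
        sl = replace(spec.slice_spec, vessel_class=spec.vessel_class,
                     patient_id=pid, slice_index=int(j), noise_sd=0.0)
        wall_region, fat_region = render_masks(
            sl, grp["wall_mm"].to_numpy(), grp["pvat_mm"].to_numpy())
        pair, _ = generate_slice(sl)
        yield (pair,
               SegmentationMask(wall_region, exclusion="phantom truth"),
               SegmentationMask(fat_region, exclusion="phantom truth"))


def _manifest_slices(manifest_path: str):
    man = pd.read_csv(manifest_path)
    if man.empty:
        raise ValueError(f"{manifest_path}: empty manifest")
    required = {"patient_id", "vessel_class", "slice_index", "wall_image",
                "fat_image", "wall_mask", "pixel_spacing_mm"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    for _, row in man.iterrows():
        sp = float(row["pixel_spacing_mm"])
        wall_img, sp_w = io.read_image(row["wall_image"], pixel_spacing_mm=sp)
        fat_img, _ = io.read_image(row["fat_image"], pixel_spacing_mm=sp)
        vert = None
        if row["vessel_class"] == "aorta":
            vert = (float(row["vertebral_x_px"]), float(row["vertebral_y_px"]))
        pair = SlicePair(
            wall_image=wall_img, fat_image=fat_img, pixel_spacing_mm=sp_w,
            vessel_class=row["vessel_class"], patient_id=str(row["patient_id"]),
            slice_index=int(row["slice_index"]), vertebral_point_px=vert,
        )
        wall_mask = load_wall_mask(
            io.read_mask(row["wall_mask"], pixel_spacing_mm=sp),
            reference_shape=wall_img.shape)
        exclusion = None
        if "exclusion_mask" in man.columns and isinstance(row.get("exclusion_mask"), str):
            exclusion = io.read_mask(row["exclusion_mask"], pixel_spacing_mm=sp)
        pvat_mask = segment_pvat(fat_img, exclusion=exclusion)
        yield pair, wall_mask, pvat_mask


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the artifact bundle as a dict.

    Any stage failure raises :class:`PipelineError` naming the stage and
    slice; nothing is written in that case.
    """
    out_dir = Path(config.out_dir)

    tset = ThresholdSet()
    tset.extent_mm.update(config.extent_overrides)

    if config.cohort_spec is not None:
        slice_iter = _phantom_slices(config.cohort_spec, config.render)
    else:
        slice_iter = _manifest_slices(config.manifest)

    records = []
    n_slices = 0
    for item in slice_iter:
        pair, wall_mask, pvat_mask = item
        sid = f"{pair.patient_id}/{pair.slice_index}"
        try:
            records.append(_profile_pair(pair, wall_mask, pvat_mask, tset,
                                         config.spacing_deg))
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise PipelineError("profile", sid, exc) from exc
        n_slices += 1
    if not records:
        raise ValueError("no slices profiled (empty input)")
    cohort = pd.concat(records, ignore_index=True)

    n_cords = int(round(360.0 / config.spacing_deg))
    n_segments = n_slices * n_cords

    # classification: abnormal cut from the designated normal subsample
    cut_mm = None
    if config.normal_patient_ids:
        normal = cohort[cohort["patient_id"].isin(config.normal_patient_ids)]
        if normal.empty:
            raise ValueError("normal subsample matched no profiled slices")
        maxima = normal.groupby(["patient_id", "vessel_class", "slice_index"])[
            "wall_mm"].max()
        cut_mm = thr.derive_abnormal_cut(maxima.to_numpy())
        tset = ThresholdSet(extent_mm=tset.extent_mm, abnormal_cut_mm=cut_mm,
                            derivation={**tset.derivation,
                                        "abnormal_cut_n": int(maxima.size)})
        cohort = thr.classify_cohort(cohort, cut_mm)

    bundle: dict = {
        "cohort": cohort,
        "thresholds": tset,
        "log": {
            "seed": config.seed,
            "n_slices": n_slices,
            "n_cords_per_slice": n_cords,
            "n_segments": n_segments,
            "extent_mm": dict(tset.extent_mm),
            "abnormal_cut_mm": cut_mm,
            "subsample_step_deg": config.subsample_step_deg,
            "subsample_offset_deg": config.subsample_offset_deg,
        },
    }

    if config.run_stats:
        bundle["summary"] = {
            tissue: angular.summarize(cohort, tissue) for tissue in ("wall", "pvat")
        }
        bundle["mean_lag1_acf_5deg"] = angular.mean_lag_acf(cohort, "pvat", 1)

    sub = angular.subsample(cohort, config.subsample_step_deg,
                            config.subsample_offset_deg)
    bundle["cohort_subsampled"] = sub

    if config.run_regression:
        strata = ["all"]
        if cut_mm is not None:
            strata = ["normal", "abnormal", "all"]
        fits = {}
        for stratum in strata:
            fits[stratum] = hierarchical.fit(
                sub, stratum=stratum,
                subsample_step_deg=config.subsample_step_deg)
        bundle["fits"] = fits

    _write_bundle(out_dir, bundle)
    return bundle


def _write_bundle(out_dir: Path, bundle: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_cohort(out_dir / "cohort.csv", bundle["cohort"])
    io.write_json(out_dir / "pipeline_log.json", bundle["log"])
    tset: ThresholdSet = bundle["thresholds"]
    io.write_yaml(out_dir / "thresholds.yaml", {
        "extent_mm": dict(tset.extent_mm),
        "abnormal_cut_mm": tset.abnormal_cut_mm,
        "derivation": tset.derivation,
    })
    if "summary" in bundle:
        summary_json = {}
        for tissue, s in bundle["summary"].items():
            summary_json[tissue] = {
                "per_angle_mean_mm": {str(k): float(v)
                                      for k, v in s.per_angle_mean.items()},
                "iqr_mm": list(s.iqr_mm),
                "cv": s.cv,
                "peak_angles_deg": s.peak_angles_deg[:4],
                "n_measurements": s.n_measurements,
            }
        io.write_json(out_dir / "summary.json", summary_json)
    if "fits" in bundle:
        io.write_json(out_dir / "fits.json",
                      {k: f.to_dict() for k, f in bundle["fits"].items()})
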