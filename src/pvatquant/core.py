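"""Shared data containers for the radial PVAT/wall quantification pipeline.

Conventions used throughout the package:

* Images are 2-D ``numpy`` arrays indexed ``[row, col]``.
* Physical coordinates are ``(x, y)`` in mm with ``x`` along columns and
  ``y`` along rows; the centre of pixel ``(row, col)`` sits at
  ``((col + 0.5) * spacing, (row + 0.5) * spacing)``.
* Angles are measured clockwise (as displayed, y pointing down) from the
  frame's zero direction, in degrees on the 5 deg grid {0, 5, ..., 355}.
* All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Angular grid of the 72 measurement cords (degrees).
ANGLES_DEG = np.arange(0.0, 360.0, 5.0)

#: Number of cords per slice at the default 5 deg spacing.
N_CORDS = 72

#: Default PVAT search extents beyond the wall's outer boundary (mm),
#: derived in the source study from n = 15 sample images.
DEFAULT_EXTENT_MM = {"aorta": 20.0, "carotid": 9.0}

_CAROTID_CLASSES = {
    "carotid",
    "left_common_carotid", "right_common_carotid",
    "left_internal_carotid", "right_internal_carotid",
    "left_external_carotid", "right_external_carotid",
}


def extent_class(vessel_class: str) -> str:
    """Map a vessel label to the extent-threshold family (``aorta``/``carotid``)."""
    if vessel_class == "aorta":
        return "aorta"
    if vessel_class in _CAROTID_CLASSES:
        return "carotid"
    raise ValueError(f"unknown vessel class: {vessel_class!r}")


@dataclass
class SlicePair:
    """One co-registered wall-weighted / fat-saturated image pair.

    ``vertebral_point_px`` is the vertebral-body reference point in ``(x, y)``
    pixel coordinates; it is mandatory for aortic slices because it defines
    the zero-angle direction there.
    """

    wall_image: np.ndarray
    fat_image: np.ndarray
    pixel_spacing_mm: float
    vessel_class: str
    patient_id: str
    slice_index: int
    vertebral_point_px: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.wall_image = np.asarray(self.wall_image, dtype=float)
        self.fat_image = np.asarray(self.fat_image, dtype=float)
        if self.wall_image.ndim != 2:
            raise ValueError("images must be 2-D")
        if self.wall_image.shape != self.fat_image.shape:
            raise ValueError(
                f"wall/fat image shapes differ: {self.wall_image.shape} vs "
                f"{self.fat_image.shape}"
            )
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        fam = extent_class(self.vessel_class)
        if fam == "aorta" and self.vertebral_point_px is None:
            raise ValueError("aortic slices require vertebral_point_px")


@dataclass
class SegmentationMask:
    """Binary mask aligned with its source image, with derivation provenance."""

    mask: np.ndarray
    threshold: Optional[float] = None
    exclusion: str = "none"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VesselCenter:
    """Least-squares circle centre of the wall's outer boundary (mm)."""

    center_mm: tuple[float, float]
    radius_mm: float
    fit_rms_mm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.center_mm).all() and self.fit_rms_mm >= 0):
            raise ValueError("invalid circle fit")


@dataclass(frozen=True)
class AngleFrame:
    """Zero-angle direction and (fixed) clockwise orientation.

    ``zero_direction`` is a unit vector in ``(x, y)`` mm coordinates with y
    pointing down the image rows; anatomical anterior ("up") is ``(0, -1)``.
    """

    zero_direction: tuple[float, float]
    orientation: str = "clockwise"

    def __post_init__(self) -> None:
        n = float(np.hypot(*self.zero_direction))
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("zero_direction must be a unit vector")
        if self.orientation != "clockwise":
            raise ValueError("orientation is fixed to clockwise")


@dataclass
class RadialProfile:
    """72 thickness values (mm) at 5 deg spacing for one tissue on one slice."""

    tissue: str  # "wall" | "pvat"
    values_mm: np.ndarray
    frame: AngleFrame
    extent_mm: Optional[float] = None  # PVAT search extent actually applied
    flags: Optional[np.ndarray] = None  # per-cord warning flags

    def __post_init__(self) -> None:
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        if self.values_mm.shape != (N_CORDS,):
            raise ValueError(f"profile needs exactly {N_CORDS} values")
        if (self.values_mm < 0).any():
            raise ValueError("thicknesses must be nonnegative")
        if self.tissue not in ("wall", "pvat"):
            raise ValueError("tissue must be 'wall' or 'pvat'")

    @property
    def angles_deg(self) -> np.ndarray:
        return ANGLES_DEG.copy()


@dataclass
class ThresholdSet:
    """PVAT extent thresholds per vessel family plus the abnormal-wall cut."""

    extent_mm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTENT_MM)
    )
    abnormal_cut_mm: Optional[float] = None
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.extent_mm.items():
            if not v > 0:
                raise ValueError(f"extent for {k} must be positive")
        if self.abnormal_cut_mm is not None and not self.abnormal_cut_mm > 0:
            raise ValueError("abnormal_cut_mm must be positive")

    def extent_for(self, vessel_class: str) -> float:
        return self.extent_mm[extent_class(vessel_class)]


@dataclass
class HierarchicalFit:
    """Mixed-model association between wall and PVAT thickness.

    ``beta_pvat`` is the raw regression coefficient in mm wall per mm PVAT;
    variance components are in mm^2.
    """

    beta_pvat: float
    ci_low: float
    ci_high: float
    p_value: float
    var_person: float
    var_angle: float
    var_slice: float
    var_resid: float
    n_obs: int
    n_patients: int
    stratum: str = "all"
    converged: bool = True
    diagnostic: str = ""
    beta_std: Optional[float] = None  # standardized coefficient, if requested
    opt_params: object = None  # packed REML parameters (warm starts); not serialized

    def __post_init__(self) -> None:
        if np.isfinite(self.beta_pvat):
            if not (self.ci_low <= self.beta_pvat <= self.ci_high):
                raise ValueError("CI must bracket the coefficient")
        for v in (self.var_person, self.var_angle, self.var_slice, self.var_resid):
            if np.isfinite(v) and v < -1e-12:
                raise ValueError("variance components must be nonnegative")

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.beta_pvat)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "beta_pvat": self.beta_pvat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "var_person": self.var_person,
            "var_angle": self.var_angle,
            "var_slice": self.var_slice,
            "var_resid": self.var_resid,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "converged": self.converged,
            "diagnostic": self.diagnostic,
            "beta_std": self.beta_std,
        }
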