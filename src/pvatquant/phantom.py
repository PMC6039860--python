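"""Synthetic cross-sectional vessel phantoms with analytic ground truth.

The generator emulates what the measurement pipeline needs from a paired
wall-weighted / fat-saturated MR acquisition: a bright annular vessel wall
with optional focal (plaque-like) thickening, a surrounding perivascular fat
band with a configurable angular thickness profile (including the two-peak
aortic pattern at 120 deg / 220 deg), an optional very bright subcutaneous
rim at the image border, and additive Gaussian noise.  Wall and fat are
rendered as disjoint regions at contrast 1.0 over background 0.0, which makes
the behaviour of the mean + 2 SD segmentation threshold analytically
tractable.

``generate_cohort`` additionally simulates the hierarchical variance
structure the statistics stages assume: per-person, per-angle (shared across
people), per-slice and residual random effects on wall thickness, a
person-level offset on PVAT thickness, and a tunable linear coupling
``beta_true`` (mm wall per mm PVAT) between the two tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ANGLES_DEG,
    DEFAULT_EXTENT_MM,
    AngleFrame,
    SegmentationMask,
    SlicePair,
    extent_class,
)

#: Minimum physical thickness (mm); draws below it are clipped, not rejected.
THICKNESS_FLOOR_MM = 0.05

#: Width of the bright subcutaneous rim rendered at the image border (mm).
RIM_WIDTH_MM = 1.5

#: Intensity of the subcutaneous rim (fat and wall tissue render at 1.0).
RIM_INTENSITY = 2.0


def circular_distance_deg(theta: np.ndarray, center: float) -> np.ndarray:
    """Shortest angular distance |theta - center| on the circle, in degrees."""
    d = np.abs(np.asarray(theta, dtype=float) - center) % 360.0
    return np.minimum(d, 360.0 - d)


def gaussian_bump(theta_deg, center_deg: float, width_deg: float) -> np.ndarray:
    """Periodic Gaussian bump exp(-d^2 / 2w^2), d = circular distance."""
    d = circular_distance_deg(theta_deg, center_deg)
    return np.exp(-(d ** 2) / (2.0 * width_deg ** 2))


@dataclass(frozen=True)
class PvatProfile:
    """Named angular PVAT-thickness function pi(theta), in mm.

    kind ``constant``: pi = base_mm.
    kind ``single_bump``: pi = base_mm + amp_mm * bump(peak1_deg, width_deg).
    kind ``double_peak``: two bumps at peak1_deg and peak2_deg (the aortic
    'M' pattern uses 120 and 220).
    """

    kind: str = "constant"
    base_mm: float = 0.8
    amp_mm: float = 0.0
    peak1_deg: float = 120.0
    peak2_deg: float = 220.0
    width_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "single_bump", "double_peak"):
            raise ValueError(f"unknown pvat profile kind: {self.kind!r}")
        if self.base_mm <= 0 and self.kind == "constant":
            raise ValueError("constant profile needs base_mm > 0")
        if self.width_deg <= 0:
            raise ValueError("width_deg must be positive")

    def __call__(self, theta_deg) -> np.ndarray:
        theta = np.asarray(theta_deg, dtype=float)
        out = np.full_like(theta, self.base_mm)
        if self.kind in ("single_bump", "double_peak"):
            out = out + self.amp_mm * gaussian_bump(theta, self.peak1_deg, self.width_deg)
        if self.kind == "double_peak":
            out = out + self.amp_mm * gaussian_bump(theta, self.peak2_deg, self.width_deg)
        return out

    @property
    def mean_mm(self) -> float:
        """Mean thickness over the 72-angle grid (used as the coupling reference)."""
        return float(np.mean(self(ANGLES_DEG)))


#: Aorta-like double-peak profile reproducing the reported posterior 'M' shape.
AORTIC_DOUBLE_PEAK = PvatProfile(
    kind="double_peak", base_mm=1.8, amp_mm=2.6,
    peak1_deg=120.0, peak2_deg=220.0, width_deg=30.0,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic slice."""

    image_size_px: tuple[int, int] = (96, 96)          # (rows, cols)
    pixel_spacing_mm: float = 0.39                     # carotid-like in-plane resolution
    lumen_radius_mm: float = 3.0
    wall_base_mm: float = 1.4
    plaque_amp_mm: float = 0.0
    plaque_center_deg: float = 90.0
    plaque_width_deg: float = 25.0
    pvat_profile: PvatProfile = field(default_factory=PvatProfile)
    rim_present: bool = False
    noise_sd: float = 0.0
    vessel_class: str = "carotid"
    vertebral_offset_mm: Optional[tuple[float, float]] = None  # aorta only
    center_offset_px: tuple[float, float] = (0.0, 0.0)  # (x, y) sub-pixel shift
    patient_id: str = "phantom"
    slice_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be positive")
        if self.wall_base_mm <= 0:
            raise ValueError("wall thickness must be positive at all angles")
        if self.plaque_amp_mm < 0 or self.noise_sd < 0:
            raise ValueError("plaque_amp_mm and noise_sd must be nonnegative")
        if not 0 <= self.plaque_center_deg < 360:
            raise ValueError("plaque_center_deg must lie in [0, 360)")
        if self.plaque_width_deg <= 0:
            raise ValueError("plaque_width_deg must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        extent_class(self.vessel_class)  # validates the label
        if self.vessel_class == "aorta" and self.vertebral_offset_mm is None:
            object.__setattr__(self, "vertebral_offset_mm", (0.0, 20.0))

    def wall_thickness_mm(self, theta_deg) -> np.ndarray:
        """Analytic wall thickness tau(theta) = base + plaque bump."""
        theta = np.asarray(theta_deg, dtype=float)
        return self.wall_base_mm + self.plaque_amp_mm * gaussian_bump(
            theta, self.plaque_center_deg, self.plaque_width_deg
        )

    @property
    def center_mm(self) -> tuple[float, float]:
        ny, nx = self.image_size_px
        sp = self.pixel_spacing_mm
        ox, oy = self.center_offset_px
        return (nx / 2.0 * sp + ox * sp, ny / 2.0 * sp + oy * sp)

    @property
    def zero_direction(self) -> tuple[float, float]:
        if self.vessel_class == "aorta":
            vx, vy = self.vertebral_offset_mm
            n = float(np.hypot(vx, vy))
            if n == 0:
                raise ValueError("vertebral point coincides with the aorta centre")
            # zero direction points from the vertebral body toward the centre
            return (-vx / n, -vy / n)
        return (0.0, -1.0)  # anatomical anterior = image "up"


@dataclass(frozen=True)
class AnalyticAnnulus:
    """Exact region between two angular radius functions around a centre.

    Membership is evaluated in continuous mm coordinates — the phantom's
    rasterization-free oracle for the ray sampler.
    """

    center_mm: tuple[float, float]
    zero_direction: tuple[float, float]
    inner_fn: object  # callable theta_deg -> inner radius (mm)
    outer_fn: object  # callable theta_deg -> outer radius (mm)

    def contains(self, x_mm, y_mm):
        dx = np.asarray(x_mm, dtype=float) - self.center_mm[0]
        dy = np.asarray(y_mm, dtype=float) - self.center_mm[1]
        r = np.hypot(dx, dy)
        theta = _clockwise_angle_deg(dx, dy, self.zero_direction)
        return (r >= self.inner_fn(theta)) & (r < self.outer_fn(theta))


@dataclass
class SliceTruth:
    """Analytic ground truth for one generated slice (oracle for recovery tests)."""

    wall_mm: np.ndarray           # tau at the 72 cord angles
    pvat_mm: np.ndarray           # pi at the 72 cord angles
    center_mm: tuple[float, float]
    zero_direction: tuple[float, float]
    abnormal: bool
    wall_mask: SegmentationMask
    fat_mask: SegmentationMask
    wall_region: Optional[AnalyticAnnulus] = None
    fat_region: Optional[AnalyticAnnulus] = None

    def table(self, patient_id: str = "phantom", slice_index: int = 0,
              vessel_class: str = "carotid") -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": patient_id,
            "vessel_class": vessel_class,
            "slice_index": slice_index,
            "angle_deg": ANGLES_DEG,
            "wall_mm": self.wall_mm,
            "pvat_mm": self.pvat_mm,
            "normal_flag": not self.abnormal,
        })


def _pixel_grid(image_size_px, pixel_spacing_mm):
    ny, nx = image_size_px
    sp = pixel_spacing_mm
    x = (np.arange(nx) + 0.5) * sp
    y = (np.arange(ny) + 0.5) * sp
    return np.meshgrid(x, y)


def _clockwise_angle_deg(dx, dy, zero_direction):
    """Clockwise angle (displayed, y down) of (dx, dy) from zero_direction."""
    ux, uy = zero_direction
    theta = np.degrees(np.arctan2(ux * dy - uy * dx, ux * dx + uy * dy))
    return np.mod(theta, 360.0)


def render_masks(spec: PhantomSpec,
                 wall_mm_72: Optional[np.ndarray] = None,
                 pvat_mm_72: Optional[np.ndarray] = None):
    """Rasterize wall and fat regions as boolean masks.

    By default uses the spec's analytic profiles; alternatively accepts
    per-angle thickness arrays on the 72-angle grid (interpolated circularly),
    which is how cohort slices with per-angle random effects are rendered.
    """
    X, Y = _pixel_grid(spec.image_size_px, spec.pixel_spacing_mm)
    cx, cy = spec.center_mm
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    theta = _clockwise_angle_deg(dx, dy, spec.zero_direction)

    if wall_mm_72 is None:
        tau = spec.wall_thickness_mm(theta)
    else:
        tau = _circular_interp(theta, wall_mm_72)
    if pvat_mm_72 is None:
        pi = spec.pvat_profile(theta)
    else:
        pi = _circular_interp(theta, pvat_mm_72)

    _check_fits(spec, float(np.max(tau)), float(np.max(pi)))

    lr = spec.lumen_radius_mm
    wall = (r >= lr) & (r < lr + tau)
    fat = (r >= lr + tau) & (r < lr + tau + pi)
    return wall, fat


def _circular_interp(theta_deg: np.ndarray, values_72: np.ndarray) -> np.ndarray:
    grid = np.concatenate([ANGLES_DEG, [360.0]])
    vals = np.concatenate([values_72, [values_72[0]]])
    return np.interp(np.mod(theta_deg, 360.0), grid, vals)


def _check_fits(spec: PhantomSpec, tau_max: float, pi_max: float) -> None:
    """Vessel + PVAT search extent (+rim margin) must fit inside the frame."""
    extent = DEFAULT_EXTENT_MM[extent_class(spec.vessel_class)]
    needed = spec.lumen_radius_mm + tau_max + max(pi_max, extent)
    if spec.rim_present:
        needed += RIM_WIDTH_MM
    cx, cy = spec.center_mm
    ny, nx = spec.image_size_px
    sp = spec.pixel_spacing_mm
    room = min(cx, cy, nx * sp - cx, ny * sp - cy)
    if needed > room:
        raise ValueError(
            f"phantom geometry does not fit: vessel + extent needs {needed:.1f} mm "
            f"but only {room:.1f} mm is available from the centre to the image edge; "
            f"enlarge image_size_px or shrink the vessel"
        )


def generate_slice(spec: PhantomSpec) -> tuple[SlicePair, SliceTruth]:
    """Render one paired wall/fat slice plus its analytic ground truth.

    Deterministic for a fixed spec (the seed drives the only randomness,
    the additive noise).
    """
    rng = np.random.default_rng(spec.seed)
    wall_region, fat_region = render_masks(spec)

    wall_img = wall_region.astype(float)
    fat_img = fat_region.astype(float)

    if spec.rim_present:
        ny, nx = spec.image_size_px
        sp = spec.pixel_spacing_mm
        b = max(1, int(round(RIM_WIDTH_MM / sp)))
        rim = np.zeros((ny, nx), dtype=bool)
        rim[:b, :] = rim[-b:, :] = True
        rim[:, :b] = rim[:, -b:] = True
        fat_img[rim] = RIM_INTENSITY

    if spec.noise_sd > 0:
        wall_img = wall_img + rng.normal(0.0, spec.noise_sd, wall_img.shape)
        fat_img = fat_img + rng.normal(0.0, spec.noise_sd, fat_img.shape)

    vert_px = None
    if spec.vessel_class == "aorta":
        cx, cy = spec.center_mm
        vx, vy = spec.vertebral_offset_mm
        sp = spec.pixel_spacing_mm
        vert_px = ((cx + vx) / sp - 0.5, (cy + vy) / sp - 0.5)

    pair = SlicePair(
        wall_image=wall_img,
        fat_image=fat_img,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        vessel_class=spec.vessel_class,
        patient_id=spec.patient_id,
        slice_index=spec.slice_index,
        vertebral_point_px=vert_px,
    )
    lr = spec.lumen_radius_mm
    wall_outer = lambda th: lr + spec.wall_thickness_mm(th)  # noqa: E731
    fat_outer = lambda th: lr + spec.wall_thickness_mm(th) + spec.pvat_profile(th)  # noqa: E731
    truth = SliceTruth(
        wall_mm=spec.wall_thickness_mm(ANGLES_DEG),
        pvat_mm=spec.pvat_profile(ANGLES_DEG),
        center_mm=spec.center_mm,
        zero_direction=spec.zero_direction,
        abnormal=spec.plaque_amp_mm > 0,
        wall_mask=SegmentationMask(wall_region, exclusion="phantom truth"),
        fat_mask=SegmentationMask(fat_region, exclusion="phantom truth"),
        wall_region=AnalyticAnnulus(spec.center_mm, spec.zero_direction,
                                    lambda th: np.full_like(np.asarray(th, dtype=float), lr),
                                    wall_outer),
        fat_region=AnalyticAnnulus(spec.center_mm, spec.zero_direction,
                                   wall_outer, fat_outer),
    )
    return pair, truth


@dataclass(frozen=True)
class CohortSpec:
    """Simulated cohort with person / angle / slice / residual variance structure."""

    n_patients: int = 20
    slices_per_patient: int = 10
    beta_true: float = 0.04            # mm wall per mm PVAT (carotid-normal scale)
    sd_person: float = 0.30            # between-person wall SD (mm)
    sd_angle: float = 0.10             # shared per-angle wall SD (mm)
    sd_slice: float = 0.15             # per-slice wall SD (mm)
    sd_resid: float = 0.25             # residual wall SD (mm)
    sd_pvat_person: float = 0.30       # person-level PVAT offset SD (mm)
    sd_pvat_resid: float = 0.40        # per-measurement PVAT SD (mm)
    wall_base_mm: float = 1.4
    pvat_profile: PvatProfile = field(default_factory=PvatProfile)
    vessel_class: str = "carotid"
    slice_spec: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be at least 1")
        for name in ("sd_person", "sd_angle", "sd_slice", "sd_resid",
                     "sd_pvat_person", "sd_pvat_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.wall_base_mm <= 0:
            raise ValueError("wall_base_mm must be positive")


def generate_cohort(spec: CohortSpec, render: bool = False):
    """Simulate a cohort table and (optionally) rendered slice pairs.

    Returns ``(pairs, truths, cohort)`` where ``cohort`` is the long-format
    table with one row per (patient, slice, angle) — the statistics stages'
    input — carrying the generating random-effect draws in ``b``/``a``/``s``/
    ``e`` columns so variance accounting is directly checkable.  ``pairs`` and
    ``truths`` are empty lists unless ``render=True``, in which case each
    cohort slice is rasterized (noise per ``slice_spec.noise_sd``) so the full
    imaging pipeline, not just the statistics, can be exercised.
    """
    rng = np.random.default_rng(spec.seed)
    n_ang = ANGLES_DEG.size

    tau_base = np.full(n_ang, spec.wall_base_mm)
    pi_base = spec.pvat_profile(ANGLES_DEG)
    pvat_ref = spec.pvat_profile.mean_mm

    a_k = rng.normal(0.0, spec.sd_angle, n_ang) if spec.sd_angle > 0 else np.zeros(n_ang)

    rows = []
    pairs: list[SlicePair] = []
    truths: list[SliceTruth] = []
    n_clipped = 0
    n_total = 0

    for i in range(spec.n_patients):
        pid = f"P{i:03d}"
        b_i = rng.normal(0.0, spec.sd_person) if spec.sd_person > 0 else 0.0
        p_i = rng.normal(0.0, spec.sd_pvat_person) if spec.sd_pvat_person > 0 else 0.0
        for j in range(spec.slices_per_patient):
            s_ij = rng.normal(0.0, spec.sd_slice) if spec.sd_slice > 0 else 0.0
            u = (rng.normal(0.0, spec.sd_pvat_resid, n_ang)
                 if spec.sd_pvat_resid > 0 else np.zeros(n_ang))
            e = (rng.normal(0.0, spec.sd_resid, n_ang)
                 if spec.sd_resid > 0 else np.zeros(n_ang))

            pvat_raw = pi_base + p_i + u
            pvat = np.maximum(pvat_raw, THICKNESS_FLOOR_MM)
            wall_raw = (tau_base + b_i + a_k + s_ij
                        + spec.beta_true * (pvat - pvat_ref) + e)
            wall = np.maximum(wall_raw, THICKNESS_FLOOR_MM)
            n_clipped += int((pvat_raw < THICKNESS_FLOOR_MM).sum()
                             + (wall_raw < THICKNESS_FLOOR_MM).sum())
            n_total += 2 * n_ang

            rows.append(pd.DataFrame({
                "patient_id": pid,
                "vessel_class": spec.vessel_class,
                "slice_index": j,
                "angle_deg": ANGLES_DEG,
                "wall_mm": wall,
                "pvat_mm": pvat,
                "normal_flag": True,
                "b": b_i, "a": a_k, "s": s_ij, "e": e,
            }))

            if render:
                sl = replace(
                    spec.slice_spec,
                    vessel_class=spec.vessel_class,
                    patient_id=pid,
                    slice_index=j,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                wall_region, fat_region = render_masks(sl, wall, pvat)
                pair, _ = generate_slice(sl)  # frame/vertebral metadata
                srng = np.random.default_rng(sl.seed)
                wall_img = wall_region.astype(float)
                fat_img = fat_region.astype(float)
                if sl.noise_sd > 0:
                    wall_img += srng.normal(0.0, sl.noise_sd, wall_img.shape)
                    fat_img += srng.normal(0.0, sl.noise_sd, fat_img.shape)
                pair.wall_image = wall_img
                pair.fat_image = fat_img
                pairs.append(pair)
                truths.append(SliceTruth(
                    wall_mm=wall, pvat_mm=pvat,
                    center_mm=sl.center_mm,
                    zero_direction=sl.zero_direction,
                    abnormal=False,
                    wall_mask=SegmentationMask(wall_region, exclusion="phantom truth"),
                    fat_mask=SegmentationMask(fat_region, exclusion="phantom truth"),
                ))

    cohort = pd.concat(rows, ignore_index=True)
    trunc_rate = n_clipped / n_total if n_total else 0.0
    if trunc_rate > 0.10:
        warnings.warn(
            f"{trunc_rate:.1%} of simulated thicknesses hit the "
            f"{THICKNESS_FLOOR_MM} mm floor; effect sizes are distorted",
            stacklevel=2,
        )
    return pairs, truths, cohort
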