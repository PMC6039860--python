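"""Circle fit, angle frame, cords and radial thickness measurement."""

import numpy as np
import pytest

from pvatquant.core import ANGLES_DEG, SegmentationMask, ThresholdSet, VesselCenter
from pvatquant.geometry import (
    fit_center,
    make_cords,
    make_frame,
    measure_profiles,
    profile_slice,
    thickness_along_ray,
)
from pvatquant.phantom import PhantomSpec, PvatProfile, generate_slice


def _annulus_mask(shape, center_px, r_in, r_out):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r = np.hypot(xx + 0.5 - center_px[0], yy + 0.5 - center_px[1])
    return SegmentationMask((r >= r_in) & (r < r_out))


# ---------------------------------------------------------------- fit_center

def test_center_of_perfect_annulus_within_tenth_pixel():
    mask = _annulus_mask((64, 64), (32.3, 31.6), 8.0, 12.0)
    c = fit_center(mask, 1.0)
    assert np.hypot(c.center_mm[0] - 32.3, c.center_mm[1] - 31.6) < 0.1


def test_ellipse_center_matches_brute_force_oracle():
    """Axis-aligned ellipse with a = 2b: Kåsa centre vs exhaustive grid
    search minimizing the radial variance."""
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    pts = np.column_stack([20.0 + 8.0 * np.cos(t), 20.0 + 4.0 * np.sin(t)])

    def radial_var(c):
        r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return np.sum((r - r.mean()) ** 2)

    grid = np.arange(19.0, 21.0, 0.01)
    best = min(((gx, gy) for gx in grid for gy in grid), key=radial_var)

    # run the Kåsa normal equations on the same point set
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    a, b, c0 = np.linalg.lstsq(A, x ** 2 + y ** 2, rcond=None)[0]
    assert abs(a - best[0]) <= 0.02 and abs(b - best[1]) <= 0.02


def test_occluded_annulus_center_within_half_pixel():
    """Annulus with a 30 deg arc deleted still centres within 0.5 px."""
    shape, ctr = (64, 64), (32.0, 32.0)
    mask = _annulus_mask(shape, ctr, 8.0, 12.0).mask
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    theta = np.degrees(np.arctan2(yy + 0.5 - ctr[1], xx + 0.5 - ctr[0])) % 360
    mask &= ~((theta >= 40) & (theta < 70))
    c = fit_center(SegmentationMask(mask), 1.0)
    assert np.hypot(c.center_mm[0] - ctr[0], c.center_mm[1] - ctr[1]) < 0.5


def test_center_errors_on_degenerate_masks():
    with pytest.raises(ValueError, match="empty"):
        fit_center(SegmentationMask(np.zeros((8, 8), dtype=bool)), 1.0)
    few = np.zeros((8, 8), dtype=bool)
    few[4, 4] = True
    with pytest.raises(ValueError, match="boundary points"):
        fit_center(SegmentationMask(few), 1.0)


# ---------------------------------------------------------------- frames/cords

def test_carotid_zero_is_anterior_up():
    frame = make_frame("carotid")
    assert frame.zero_direction == (0.0, -1.0)
    assert frame.orientation == "clockwise"


def test_aorta_zero_from_vertebral_line():
    # vertebral point directly below (larger y) the aorta centre -> zero is up
    frame = make_frame("aorta", aorta_center_mm=(10.0, 10.0),
                       vertebral_point_mm=(10.0, 30.0))
    assert frame.zero_direction == pytest.approx((0.0, -1.0))
    with pytest.raises(ValueError, match="coincides"):
        make_frame("aorta", aorta_center_mm=(5.0, 5.0),
                   vertebral_point_mm=(5.0, 5.0))
    with pytest.raises(ValueError, match="requires"):
        make_frame("aorta")


@pytest.mark.parametrize("spacing,count", [(5.0, 72), (10.0, 36), (20.0, 18)])
def test_cord_counts(spacing, count):
    angles, dirs = make_cords(make_frame("carotid"), spacing)
    assert angles.size == count and dirs.shape == (count, 2)
    assert np.allclose(np.hypot(dirs[:, 0], dirs[:, 1]), 1.0)


def test_cords_rotate_clockwise_from_anterior():
    _, dirs = make_cords(make_frame("carotid"), 90.0)
    # up, right, down, left in image coordinates (y down)
    assert np.allclose(dirs, [[0, -1], [1, 0], [0, 1], [-1, 0]], atol=1e-12)


def test_bad_spacing_rejected():
    with pytest.raises(ValueError, match="divide"):
        make_cords(make_frame("carotid"), 7.0)


# ---------------------------------------------------------------- ray thickness

def test_constant_annulus_thickness_recovered():
    mask = _annulus_mask((80, 80), (40.0, 40.0), 10.0, 12.0)  # 2 px thick
    for ang in (0.0, 30.0, 117.0, 245.0):
        th = np.radians(ang)
        t = thickness_along_ray(mask, 1.0, (40.0, 40.0),
                                (np.sin(th), -np.cos(th)), 0.0, 20.0)
        assert t == pytest.approx(2.0, abs=0.45)  # rasterized boundary


def test_disjoint_runs_are_summed():
    """Two separated in-ray runs of 1.0 mm and 0.5 mm total 1.5 mm."""
    mask = np.zeros((1, 40), dtype=bool)
    mask[0, 5:15] = True    # 10 px = 1.0 mm at 0.1 mm spacing
    mask[0, 20:25] = True   # 5 px = 0.5 mm
    t = thickness_along_ray(SegmentationMask(mask), 0.1, (0.0, 0.05),
                            (1.0, 0.0), 0.0, 3.5)
    assert t == pytest.approx(1.5, abs=0.02)


def test_empty_mask_measures_zero():
    mask = SegmentationMask(np.zeros((10, 10), dtype=bool))
    assert thickness_along_ray(mask, 1.0, (5.0, 5.0), (1.0, 0.0), 0.0, 4.0) == 0.0


def test_ray_leaving_image_warns_and_truncates(caplog):
    mask = SegmentationMask(np.ones((10, 10), dtype=bool))
    with caplog.at_level("WARNING"):
        t = thickness_along_ray(mask, 1.0, (5.0, 5.0), (1.0, 0.0), 0.0, 50.0)
    assert t == pytest.approx(5.0, abs=0.2)
    assert any("left the image" in r.message for r in caplog.records)


def test_polygon_oracle_equivalence():
    """Ray totals on a polygonal (rectangle) mask match exact ray-polygon
    intersection lengths within two step lengths."""
    mask = np.zeros((60, 60), dtype=bool)
    mask[20:30, 10:50] = True  # rectangle y in [20,30), x in [10,50)
    sm = SegmentationMask(mask)
    center = (30.0, 25.0)
    for ang, exact in [(90.0, 20.0), (270.0, 20.0), (0.0, 5.0), (180.0, 5.0)]:
        th = np.radians(ang)
        d = (np.sin(th), -np.cos(th))
        t = thickness_along_ray(sm, 1.0, center, d, 0.0, 28.0)
        assert t == pytest.approx(exact, abs=0.2)


# ---------------------------------------------------------------- profile_slice

def test_constant_phantom_profiles_recovered_within_pixel(constant_carotid):
    _, pair, truth = constant_carotid
    sp = pair.pixel_spacing_mm
    w, p, center, _ = profile_slice(pair, truth.wall_mask, truth.fat_mask,
                                    ThresholdSet())
    assert np.abs(w.values_mm - 2.0).max() < sp
    assert np.abs(p.values_mm - 3.0).max() < sp
    assert np.hypot(center.center_mm[0] - truth.center_mm[0],
                    center.center_mm[1] - truth.center_mm[1]) < 0.1 * sp


def test_analytic_oracle_recovery_within_one_step(constant_aorta):
    """Sampling the exact phantom regions recovers the reported-mean
    geometry (wall 2.38 mm, PVAT 3.34 mm) within one ray step at all 72
    angles."""
    spec, pair, truth = constant_aorta
    step = 0.1 * spec.pixel_spacing_mm
    w, p, _, _ = profile_slice(pair, truth.wall_region, truth.fat_region,
                               ThresholdSet())
    assert np.abs(w.values_mm - 2.38).max() <= step
    assert np.abs(p.values_mm - 3.34).max() <= step


def test_pvat_clipped_at_carotid_extent():
    """A fat band deeper than the 9 mm carotid extent measures 9 mm."""
    spec = PhantomSpec(image_size_px=(160, 160), noise_sd=0.0,
                       pvat_profile=PvatProfile("constant", base_mm=12.0))
    pair, truth = generate_slice(spec)
    _, p, _, _ = profile_slice(pair, truth.wall_region, truth.fat_region,
                               ThresholdSet())
    assert np.allclose(p.values_mm, 9.0, atol=0.1 * spec.pixel_spacing_mm)
    assert p.extent_mm == 9.0


def test_plaque_slice_argmax_at_plaque_center():
    spec = PhantomSpec(noise_sd=0.0, plaque_amp_mm=3.0, plaque_center_deg=90.0)
    pair, truth = generate_slice(spec)
    w, _, _, _ = profile_slice(pair, truth.wall_region, truth.fat_region,
                               ThresholdSet())
    assert ANGLES_DEG[np.argmax(w.values_mm)] == 90.0


def test_rotational_equivariance_of_profiles():
    """Rotating the plaque by 90 deg cyclically shifts the wall profile."""
    base = PhantomSpec(noise_sd=0.0, plaque_amp_mm=2.0, plaque_center_deg=45.0)
    rot = PhantomSpec(noise_sd=0.0, plaque_amp_mm=2.0, plaque_center_deg=135.0)
    w1 = profile_slice(*_slice_args(base))[0].values_mm
    w2 = profile_slice(*_slice_args(rot))[0].values_mm
    assert np.allclose(np.roll(w1, 18), w2, atol=1e-9)


def _slice_args(spec):
    pair, truth = generate_slice(spec)
    return pair, truth.wall_region, truth.fat_region, ThresholdSet()


def test_wall_plus_pvat_never_exceed_window(constant_carotid):
    _, pair, truth = constant_carotid
    w, p, center, _ = profile_slice(pair, truth.wall_mask, truth.fat_mask,
                                    ThresholdSet())
    assert w.values_mm.shape == (72,) and p.values_mm.shape == (72,)
    # PVAT never exceeds its search extent; wall never exceeds the stop radius
    assert (p.values_mm <= p.extent_mm + 1e-9).all()


def test_misaligned_masks_rejected(constant_carotid):
    _, pair, truth = constant_carotid
    bad = SegmentationMask(np.ones((10, 10), dtype=bool))
    with pytest.raises(ValueError, match="aligned"):
        profile_slice(pair, bad, truth.fat_mask, ThresholdSet())
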