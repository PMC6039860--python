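"""Phantom generator: determinism, truth tables, variance structure."""

import numpy as np
import pandas as pd
import pytest

from pvatquant.core import ANGLES_DEG
from pvatquant.phantom import (
    AORTIC_DOUBLE_PEAK,
    CohortSpec,
    PhantomSpec,
    PvatProfile,
    circular_distance_deg,
    generate_cohort,
    generate_slice,
)


def test_identical_seed_gives_bit_identical_output():
    spec = PhantomSpec(noise_sd=0.08, seed=7)
    pair1, truth1 = generate_slice(spec)
    pair2, truth2 = generate_slice(spec)
    assert np.array_equal(pair1.wall_image, pair2.wall_image)
    assert np.array_equal(pair1.fat_image, pair2.fat_image)
    assert np.array_equal(truth1.wall_mm, truth2.wall_mm)

    cspec = CohortSpec(n_patients=3, slices_per_patient=2, seed=5)
    _, _, c1 = generate_cohort(cspec)
    _, _, c2 = generate_cohort(cspec)
    pd.testing.assert_frame_equal(c1, c2)


def test_noiseless_constant_truth(constant_carotid):
    _, _, truth = constant_carotid
    assert np.allclose(truth.wall_mm, 2.0)
    assert np.allclose(truth.pvat_mm, 3.0)
    assert truth.wall_mm.size == 72


def test_double_peak_truth_maxima_at_120_and_220(double_peak_aorta):
    _, _, truth = double_peak_aorta
    top2 = set(ANGLES_DEG[np.argsort(truth.pvat_mm)[-2:]])
    assert top2 == {120.0, 220.0}


def test_plaque_bump_peaks_at_its_center():
    spec = PhantomSpec(noise_sd=0.0, plaque_amp_mm=3.0, plaque_center_deg=90.0)
    _, truth = generate_slice(spec)
    assert ANGLES_DEG[np.argmax(truth.wall_mm)] == 90.0
    assert truth.wall_mm.max() == pytest.approx(spec.wall_base_mm + 3.0)
    assert truth.abnormal


def test_wall_and_fat_regions_are_disjoint(double_peak_aorta):
    _, _, truth = double_peak_aorta
    assert not (truth.wall_mask.mask & truth.fat_mask.mask).any()


def test_rim_renders_brighter_than_fat():
    spec = PhantomSpec(noise_sd=0.0, rim_present=True)
    pair, _ = generate_slice(spec)
    assert pair.fat_image[0, 0] == 2.0
    assert pair.fat_image.max() == 2.0


def test_geometry_exceeding_frame_is_rejected():
    with pytest.raises(ValueError, match="does not fit"):
        generate_slice(PhantomSpec(image_size_px=(40, 40), lumen_radius_mm=6.0))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(lumen_radius_mm=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(wall_base_mm=0.0)
    with pytest.raises(ValueError):
        PvatProfile(kind="spiral")
    with pytest.raises(ValueError):
        CohortSpec(sd_person=-0.1)


def test_circular_distance_wraps():
    assert circular_distance_deg(350.0, 10.0) == 20.0
    assert circular_distance_deg(10.0, 350.0) == 20.0


def test_zero_coupling_gives_zero_correlation():
    # person-level effects off: rows are independent and the MC error of the
    # pooled correlation is ~1/sqrt(n_rows); with them on, the error is
    # governed by n_patients instead, so the bound loosens accordingly
    spec = CohortSpec(n_patients=20, slices_per_patient=6, beta_true=0.0,
                      sd_person=0.0, sd_pvat_person=0.0, sd_slice=0.0, seed=3)
    _, _, cohort = generate_cohort(spec)
    r = np.corrcoef(cohort["wall_mm"], cohort["pvat_mm"])[0, 1]
    assert abs(r) < 4.0 / np.sqrt(len(cohort))

    full = CohortSpec(n_patients=40, slices_per_patient=6, beta_true=0.0, seed=3)
    _, _, cohort2 = generate_cohort(full)
    r2 = np.corrcoef(cohort2["wall_mm"], cohort2["pvat_mm"])[0, 1]
    assert abs(r2) < 4.0 / np.sqrt(full.n_patients)


def test_noise_free_cohort_is_exact_affine():
    spec = CohortSpec(n_patients=4, slices_per_patient=3, beta_true=0.5,
                      sd_person=0.0, sd_angle=0.0, sd_slice=0.0, sd_resid=0.0,
                      seed=1)
    _, _, cohort = generate_cohort(spec)
    ref = spec.pvat_profile.mean_mm
    expected = spec.wall_base_mm + 0.5 * (cohort["pvat_mm"] - ref)
    assert np.allclose(cohort["wall_mm"], np.maximum(expected, 0.05))


def test_variance_components_match_generating_sds():
    """Empirical person/angle/slice/residual variances track the spec SDs."""
    spec = CohortSpec(n_patients=50, slices_per_patient=10, beta_true=0.0, seed=9)
    _, _, c = generate_cohort(spec)
    sd_person = c.groupby("patient_id")["b"].first().std(ddof=1)
    sd_angle = c.groupby("angle_deg")["a"].first().std(ddof=1)
    sd_slice = c.groupby(["patient_id", "slice_index"])["s"].first().std(ddof=1)
    sd_resid = c["e"].std(ddof=1)
    assert sd_person == pytest.approx(spec.sd_person, rel=0.15)
    assert sd_angle == pytest.approx(spec.sd_angle, rel=0.15)
    assert sd_slice == pytest.approx(spec.sd_slice, rel=0.15)
    assert sd_resid == pytest.approx(spec.sd_resid, rel=0.15)


def test_high_truncation_rate_warns():
    spec = CohortSpec(n_patients=5, slices_per_patient=4, seed=2,
                      pvat_profile=PvatProfile("constant", base_mm=0.2),
                      sd_pvat_resid=0.6)
    with pytest.warns(UserWarning, match="floor"):
        generate_cohort(spec)


def test_cohort_table_shape_and_grid(small_cohort):
    spec, cohort = small_cohort
    assert len(cohort) == spec.n_patients * spec.slices_per_patient * 72
    assert set(np.unique(cohort["angle_deg"])) == set(ANGLES_DEG)
    # one record per (patient, slice, angle)
    assert not cohort.duplicated(["patient_id", "slice_index", "angle_deg"]).any()
    assert (cohort[["wall_mm", "pvat_mm"]] >= 0.05).all().all()


def test_aortic_profile_mean_matches_reported_scale():
    # double-peak default sits near the reported 3.34 mm aortic PVAT mean
    assert AORTIC_DOUBLE_PEAK.mean_mm == pytest.approx(3.34, abs=0.6)
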