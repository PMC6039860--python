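"""Angular summaries, CV comparison, peak detection, ACF and subsampling."""

import numpy as np
import pandas as pd
import pytest

from pvatquant.angular import (
    autocorr,
    compare_cv,
    cv,
    mean_lag_acf,
    peak_angles,
    subsample,
    summarize,
)
from pvatquant.core import ANGLES_DEG
from pvatquant.phantom import AORTIC_DOUBLE_PEAK, CohortSpec, generate_cohort


def _toy_cohort(values_by_slice):
    rows = []
    for i, vals in enumerate(values_by_slice):
        rows.append(pd.DataFrame({
            "patient_id": f"P{i}", "vessel_class": "carotid", "slice_index": 0,
            "angle_deg": ANGLES_DEG, "wall_mm": vals, "pvat_mm": vals,
            "normal_flag": True,
        }))
    return pd.concat(rows, ignore_index=True)


def test_constant_cohort_summary_is_degenerate():
    c = _toy_cohort([np.full(72, 2.5), np.full(72, 2.5)])
    s = summarize(c, "wall")
    assert np.allclose(s.per_angle_mean, 2.5)
    assert s.iqr_mm[0] == s.iqr_mm[1]
    assert s.cv == 0.0
    assert s.peak_angles_deg == []


def test_cv_hand_value_on_two_element_sample():
    # {2, 4}: mean 3, sample SD sqrt(2) -> CV = 1.4142/3 = 0.471
    assert cv([2.0, 4.0]) == pytest.approx(0.4714, abs=5e-4)
    assert cv([5.0, 5.0, 5.0]) == 0.0


def test_cv_scale_invariant_not_translation_invariant():
    rng = np.random.default_rng(1)
    x = rng.lognormal(0, 0.4, 200)
    assert cv(3.7 * x) == pytest.approx(cv(x))
    assert cv(x + 5.0) != pytest.approx(cv(x))


def test_identical_samples_compare_equal():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    cv_a, cv_b, p = compare_cv(x, x.copy())
    assert cv_a == cv_b
    assert p == pytest.approx(1.0)


def test_reported_cv_contrast_is_highly_significant():
    """Samples simulated at the reported dispersion contrast (CV 0.90 vs
    0.32) reject equality at far below 0.1%."""
    rng = np.random.default_rng(7)
    pvat_like = rng.gamma(shape=1 / 0.81, scale=3.34 * 0.81, size=2000)  # CV 0.9
    wall_like = rng.gamma(shape=1 / 0.1024, scale=2.38 * 0.1024, size=2000)  # CV 0.32
    cv_a, cv_b, p = compare_cv(pvat_like, wall_like)
    assert cv_a == pytest.approx(0.90, abs=0.06)
    assert cv_b == pytest.approx(0.32, abs=0.03)
    assert p < 0.001


def test_bootstrap_agrees_with_asymptotic_decision():
    rng = np.random.default_rng(3)
    a = rng.gamma(2.0, 1.0, 400)      # CV ~0.71
    b = rng.gamma(25.0, 1.0, 400)     # CV ~0.2
    _, _, p_asym = compare_cv(a, b)
    _, _, p_boot = compare_cv(a, b, n_boot=500, seed=0)
    assert (p_asym < 0.05) == (p_boot < 0.05)
    same = rng.gamma(4.0, 1.0, 300)
    _, _, p1 = compare_cv(same[:150], same[150:])
    _, _, p2 = compare_cv(same[:150], same[150:], n_boot=500, seed=0)
    assert (p1 < 0.05) == (p2 < 0.05)


def test_cv_comparison_rejects_nonpositive_mean():
    with pytest.raises(ValueError, match="mean"):
        compare_cv([-1.0, -2.0, -3.0], [1.0, 2.0])


def test_double_peak_profile_peaks_found_exactly():
    prof = AORTIC_DOUBLE_PEAK(ANGLES_DEG)
    top2 = set(peak_angles(prof)[:2])
    assert top2 == {120.0, 220.0}


def test_single_bump_at_zero_wraps():
    prof = 1.0 + np.exp(-np.minimum(ANGLES_DEG, 360 - ANGLES_DEG) ** 2 / (2 * 30 ** 2))
    assert peak_angles(prof) == [0.0]


def test_flat_profile_has_no_peaks():
    assert peak_angles(np.full(72, 1.3)) == []


def test_peak_detection_is_rotation_equivariant():
    prof = AORTIC_DOUBLE_PEAK(ANGLES_DEG)
    shifted = np.roll(prof, 5)  # rotate by 25 deg
    p0 = sorted(peak_angles(prof)[:2])
    p1 = sorted(peak_angles(shifted)[:2])
    assert p1 == [(a + 25.0) % 360 for a in p0]


def test_autocorr_white_noise_near_zero():
    rng = np.random.default_rng(0)
    acf = np.mean([autocorr(rng.normal(size=72), 1)[1] for _ in range(200)])
    assert abs(acf) < 0.05


def test_subsample_keeps_18_angles_at_20_deg():
    spec = CohortSpec(n_patients=2, slices_per_patient=2, seed=0)
    _, _, cohort = generate_cohort(spec)
    sub = subsample(cohort, 20.0)
    per_slice = sub.groupby(["patient_id", "slice_index"])["angle_deg"].nunique()
    assert (per_slice == 18).all()
    assert set(np.unique(sub["angle_deg"])) == set(np.arange(0.0, 360.0, 20.0))
    off = subsample(cohort, 20.0, offset_deg=5.0)
    assert set(np.unique(off["angle_deg"])) == set(np.arange(5.0, 360.0, 20.0))


def test_subsample_grid_validation():
    spec = CohortSpec(n_patients=1, slices_per_patient=1, seed=0)
    _, _, cohort = generate_cohort(spec)
    with pytest.raises(ValueError):
        subsample(cohort, 17.0)
    with pytest.raises(ValueError):
        subsample(cohort, 20.0, offset_deg=2.0)


def test_subsampling_commutes_with_summarizing():
    spec = CohortSpec(n_patients=6, slices_per_patient=3, seed=11)
    _, _, cohort = generate_cohort(spec)
    s_full = summarize(cohort, "pvat")
    s_sub = summarize(subsample(cohort, 20.0), "pvat")
    kept = s_sub.per_angle_mean.index
    assert np.allclose(s_full.per_angle_mean.loc[kept], s_sub.per_angle_mean)


def test_subsampling_reduces_smooth_profile_autocorrelation():
    """Smooth angular profiles: lag-1 ACF at 5 deg spacing exceeds lag-1 ACF
    of the 20-deg subsample."""
    spec = CohortSpec(n_patients=10, slices_per_patient=4, seed=21,
                      pvat_profile=AORTIC_DOUBLE_PEAK, vessel_class="aorta",
                      sd_pvat_resid=0.3)
    _, _, cohort = generate_cohort(spec)
    acf_full = mean_lag_acf(cohort, "pvat", 1)
    acf_sub = mean_lag_acf(subsample(cohort, 20.0), "pvat", 1)
    assert acf_full > acf_sub
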