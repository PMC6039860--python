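#!/usr/bin/env python
"""Angular distribution of PVAT vs wall thickness on the aortic cohort.

Summarizes per-angle means and IQRs, locates the characteristic double-peak
('M') PVAT pattern, contrasts the dispersion of the two tissues
(coefficients of variation, Feltz-Miller test), and quantifies the angular
autocorrelation that motivates the 20-deg subsample.
"""

import json
from pathlib import Path

from pvatquant import io
from pvatquant.angular import compare_cv, mean_lag_acf, subsample, summarize

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = io.read_cohort(OUT / "aorta_truth.csv")

    s_pvat = summarize(cohort, "pvat")
    s_wall = summarize(cohort, "wall")
    print(f"aortic PVAT per-angle mean IQR: "
          f"{s_pvat.iqr_mm[0]:.2f}-{s_pvat.iqr_mm[1]:.2f} mm; "
          f"wall IQR: {s_wall.iqr_mm[0]:.2f}-{s_wall.iqr_mm[1]:.2f} mm")
    print(f"PVAT peak angles (top 2): "
          f"{sorted(s_pvat.peak_angles_deg[:2])} deg (double-peak pattern)")

    cv_p, cv_w, p = compare_cv(cohort["pvat_mm"], cohort["wall_mm"])
    print(f"dispersion: CV(PVAT) {cv_p:.2f} vs CV(wall) {cv_w:.2f}, "
          f"Feltz-Miller p = {p:.2e}")

    acf5 = mean_lag_acf(cohort, "pvat", 1)
    acf20 = mean_lag_acf(subsample(cohort, 20.0), "pvat", 1)
    print(f"mean lag-1 angular ACF: {acf5:.2f} at 5 deg spacing -> "
          f"{acf20:.2f} after 20 deg subsampling")

    with open(OUT / "angular_summary.json", "w") as fh:
        json.dump({
            "pvat": {"iqr_mm": s_pvat.iqr_mm, "cv": s_pvat.cv,
                     "peaks_deg": s_pvat.peak_angles_deg[:2]},
            "wall": {"iqr_mm": s_wall.iqr_mm, "cv": s_wall.cv},
            "cv_comparison_p": p,
            "lag1_acf": {"full_5deg": acf5, "subsampled_20deg": acf20},
        }, fh, indent=2)
    print(f"wrote {OUT/'angular_summary.json'}")


if __name__ == "__main__":
    main()
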