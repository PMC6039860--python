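#!/usr/bin/env python
"""Simulate the study-sized phantom cohort used by the downstream analyses.

Generates a carotid-like cohort (20 patients x 59 slices = 1,180 slices,
matching the study's combined slice count) plus a smaller aortic cohort with
the double-peak PVAT pattern, and writes their ground-truth tables under
results/.  Everything downstream (02-05) reads these tables.
"""

from pathlib import Path

from pvatquant import io
from pvatquant.phantom import AORTIC_DOUBLE_PEAK, CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

def main() -> None:
    OUT.mkdir(exist_ok=True)

    carotid = CohortSpec(n_patients=20, slices_per_patient=59, seed=SEED)
    _, _, carotid_cohort = generate_cohort(carotid)
    io.write_cohort(OUT / "carotid_truth.csv", carotid_cohort)

    aorta = CohortSpec(n_patients=28, slices_per_patient=11, vessel_class="aorta",
                       wall_base_mm=2.38, pvat_profile=AORTIC_DOUBLE_PEAK,
                       seed=SEED + 1)
    _, _, aorta_cohort = generate_cohort(aorta)
    io.write_cohort(OUT / "aorta_truth.csv", aorta_cohort)

    print(f"carotid cohort: {carotid.n_patients} patients, "
          f"{len(carotid_cohort)} records -> {OUT/'carotid_truth.csv'}")
    print(f"aortic cohort:  {aorta.n_patients} patients, "
          f"{len(aorta_cohort)} records -> {OUT/'aorta_truth.csv'}")


if __name__ == "__main__":
    main()
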