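# pvatquant

Circumferential quantification of perivascular adipose tissue (PVAT) and
vessel-wall thickness in cross-sectional vascular MR images.

Whether PVAT promotes atherosclerosis through local (paracrine) signalling
is contested. A spatial test of that hypothesis needs more than total fat
volume: it needs the *angular* distribution of fat around the vessel,
measured against the adjacent wall. This package implements that
measurement for paired fat-suppressed (wall) and water-suppressed (fat) MR
slices of the carotid arteries and aorta, and the statistics that relate
the two tissues:

* **PVAT segmentation** — threshold at μ + 2σ of the whole fat image, with
  exclusion masks for background and the bright subcutaneous rim;
* **radial profiling** — a best-fit circle centres the vessel; 72 cords at
  5° spacing (clockwise from anterior for carotids, from the
  vertebral-body→aorta line for the aorta) measure t_wall(θ) and t_pvat(θ),
  the PVAT window limited to a per-vessel extent (defaults 20 mm aorta,
  9 mm carotid, each derived as mean + 2·SD from sample measurements);
* **wall classification** — a slice is abnormal when max_θ t_wall(θ)
  exceeds mean + 3·SD of maxima in a visually normal subsample;
* **angular statistics** — per-angle means, IQRs, coefficients of
  variation (Feltz–Miller equality test), peak angles of the mean profile,
  circular autocorrelation, and the 20°-spaced angular subsample (18 of 72
  cords) that removes it;
* **hierarchical regression** — REML mixed model
  `wall ~ β·pvat + angle + slice` (fixed) with crossed random intercepts
  for person, angle and slice, reporting β (mm wall per mm PVAT) with Wald
  95% CI.

Because the original patient scans are not public, the package ships a
phantom generator that renders paired slices with analytic ground truth
(annular wall, configurable angular fat profile including the aortic
120°/220° double-peak pattern, bright rim, noise) and simulates cohorts
with the person/angle/slice variance structure the model assumes. Every
stage is tested against it. See `docs/methods.md` for the full model.

## Worked example

```python
from pvatquant.core import ThresholdSet
from pvatquant.phantom import PhantomSpec, PvatProfile, generate_slice
from pvatquant.geometry import profile_slice
from pvatquant.segmentation import segment_pvat

spec = PhantomSpec(image_size_px=(176, 176), vessel_class="aorta",
                   lumen_radius_mm=8.0, wall_base_mm=2.38,
                   pvat_profile=PvatProfile("constant", base_mm=3.34),
                   noise_sd=0.05, seed=1)
pair, truth = generate_slice(spec)

pvat_mask = segment_pvat(pair.fat_image)          # mean + 2 SD threshold
wall, pvat, center, frame = profile_slice(pair, truth.wall_mask, pvat_mask,
                                          ThresholdSet())
print(f"wall  {wall.values_mm.mean():.2f} mm over 72 cords")
print(f"pvat  {pvat.values_mm.mean():.2f} mm within {pvat.extent_mm:.0f} mm extent")
print(f"center residual {center.fit_rms_mm:.3f} mm")
```

prints

```
wall  2.35 mm over 72 cords
pvat  3.40 mm within 20 mm extent
center residual 0.115 mm
```

i.e. the measured mean wall and PVAT thickness recover the generating
geometry (2.38 / 3.34 mm) to within the rasterization error of a 0.39 mm
pixel grid, and the circle fit's RMS residual is at sub-pixel level.

The numbered scripts under `analysis/` run the same stages as a narrative
study: `01_simulate_cohort.py` (1,180-slice cohort), `02_measure_profiles.py`
(full imaging chain, error accounting), `03_thresholds_and_classification.py`
(data-driven cut-offs), `04_angular_distribution.py` (double-peak pattern,
CV contrast, autocorrelation) and `05_hierarchical_regression.py`
(β ≈ 0.042 [0.021, 0.064] on a cohort generated with β_true = 0.04). They
write their tables under `results/`.

A `pvatquant` CLI wraps the stages
(`simulate | segment | profile | classify | stats | regress | run`);
`pvatquant --help` lists the options, and YAML configs drive `simulate`/`run`.

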