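# ezquant

Quantification of **ellipsoid-zone (EZ) defects** in the macular central
subfield from SD-OCT volumes, and their longitudinal association with
visual acuity — built for researchers studying photoreceptor integrity as
a structural biomarker in macular edema secondary to retinal vein
occlusion (and similar settings), and validated end-to-end on synthetic,
ground-truthed data.

The EZ (formerly the IS/OS junction) is the second outer hyperreflective
band on SD-OCT; its disruption marks photoreceptor damage and correlates
with visual acuity letter score (VALS). The package implements the full
measurement chain:

1. **Synthetic phantoms** (`ezquant.oct_synth`) — volumes with
   Gaussian-ridge outer-retinal bands (ELM, EZ, RPE), EZ-defect lesions of
   known area, and hemorrhage/fluid-style shadows, plus longitudinal
   cohorts whose VALS trajectories depend on defect area with AR(1)
   within-participant noise. Ground truth is exact by construction.
2. **Boundary segmentation** (`ezquant.layer_seg`) — the EZ inner border
   and RPE inner border per A-scan, by deterministic ridge tracking with
   half-prominence inner-edge refinement; columns without a qualifying EZ
   ridge are flagged as candidate defects. A per-column signal-quality
   index captures outer-retinal signal blockage.
3. **En face mapping** (`ezquant.enface`) — EZ–RPE thickness per
   (B-scan, A-scan) cell, `t = (z_RPE − z_EZ) · s_axial`, with the 1 mm
   ETDRS central-subfield (CSF) disc mask (area π·0.25 ≈ 0.785 mm²).
4. **Pixel classification** (`ezquant.defect_detect`) — a trainable
   bagged-decision-tree classifier over a multi-scale feature bank labels
   each CSF pixel defect vs intact (defects are the dark map regions).
5. **Quantification and grading** (`ezquant.quantify_grade`) — defect
   area with reading-center rules (floor 0.004 mm², cap 0.78 mm²), the
   binary presence variable (area > 0.004 mm²), gradability from the
   blocked-column fraction, and the three-step qualitative grade
   (normal / patchy / absent / cannot-grade).
6. **Cohort statistics** (`ezquant.cohort_stats`) — visit summaries with
   one-decimal percentages, Welch t-tests, one-way ANOVA of area by
   grade, point-biserial correlations, Bonferroni flags (α = 0.002), and
   the longitudinal mixed model

   `ΔVALS_iv = β_v + γ_v · area_iv + ε_iv`,  `Cov(ε_iv, ε_iw) = σ² ρ^|v−w|`

   fit by maximum likelihood with ρ profiled out via per-participant GLS
   (missing visits handled by covariance subsetting).

`ezquant.pipeline` orchestrates the whole chain with a single seeded
config and a checksum manifest; `ez-pipeline` is the CLI.

## Worked example

Simulate an eye with a 0.2 mm-radius EZ defect at the fovea, then measure
it blind to the ground truth:

```python
from ezquant import make_geometry
from ezquant.oct_synth import LesionSpec, simulate_volume
from ezquant.layer_seg import segment_volume, volume_signal_quality
from ezquant.enface import csf_mask, thickness_map
from ezquant.pipeline import train_default_classifier
from ezquant.defect_detect import classify
from ezquant.quantify_grade import assess_gradability, measure_defect, qualitative_grade

geom = make_geometry("cirrus6mm")          # 512 x 128 over 6 mm x 6 mm
lesion = LesionSpec("ez_defect", center_mm=(3.0, 3.0), radius_mm=0.2)
volume, truth = simulate_volume(geom, [lesion], noise_sd=0.1, seed=42)

model = train_default_classifier(geom, n_train=8, seed=0, noise_sd=0.1)
boundaries = segment_volume(volume)
emap = thickness_map(boundaries, geom)
csf = csf_mask(geom)
gradability = assess_gradability(volume_signal_quality(boundaries), csf)
mask = classify(emap, model, csf)
measure = measure_defect(mask.mask, geom)
grade = qualitative_grade(measure, gradability)

print(f"true defect area : {truth.true_defect_area_mm2:.4f} mm^2")
print(f"reported area    : {measure.reported_area_mm2:.4f} mm^2")
print(f"defect present   : {measure.present}")
print(f"gradable         : {gradability.gradable}")
print(f"qualitative grade: {grade.value}")
```

Output:

```
true defect area : 0.1252 mm^2
reported area    : 0.1241 mm^2
defect present   : True
gradable         : True
qualitative grade: patchy
```

The true area is the rasterized lesion footprint inside the CSF
(≈ π·0.2² = 0.126 mm²); the reported area recovers it to ~1%. A lesion
covering 10–50% of the disc grades as *patchy*; shadowed scans grade as
*cannot_grade* instead.

A complete demo run (cohort + imaging + statistics for 12 synthetic eyes
over 4 visits):

```bash
ez-pipeline run --seed 1 --out demo_run
```

which writes `cohort.csv`, `results.csv`, `visit_summary.csv`,
`table1.csv`, `stats.json` and a checksum `manifest.json`; rerunning the
same config reproduces identical tables.

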