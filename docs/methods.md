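# Methods

`ezquant` quantifies ellipsoid-zone (EZ) integrity in the macular central
subfield (CSF) from SD-OCT volumes and links it to visual acuity letter
score (VALS) longitudinally. Because no clinical images ship with the
package, a first-class synthetic-data module generates ground-truthed
volumes and cohorts with the statistical structure the analysis assumes;
everything downstream is validated against that ground truth.

## Scan geometry

Two acquisition dialects are modeled: a 6 × 6 mm macular cube of 512
A-scans × 128 B-scans (Cirrus-style) and a 20° × 20° field of 512 × 97
(Spectralis-style). The en face pixel area is the product of the A-scan
pitch and B-scan spacing (0.000549 mm² for the 6 mm cube). The Spectralis
field's physical extent is not fixed by the acquisition protocol — it
depends on the eye — so the degree→mm factor is a configurable parameter
defaulting to 0.291 mm/degree (emmetropic schematic eye); physical areas
are then comparable across dialects. Axial sampling defaults to 496 pixels
at 3.9 µm/pixel; only *relative* band depths matter downstream, so these
are config defaults rather than claims about any device.

## Synthetic volumes

Outer-retinal anatomy is modeled as Gaussian-profile hyperreflective
ridges in depth (inner surface, ELM-like band, EZ, RPE) whose positions
vary smoothly across the field by a low-order polynomial (random tilt up
to ±6 px and a bowl term up to 5 px, seeded). A band's nominal position is
its *inner border*, operationalized everywhere in the package as the
shallowest depth at which the band profile exceeds half its prominence;
the Gaussian ridge center is therefore placed `sigma*sqrt(2 ln 2)` below
the stated border so construction and measurement agree by definition.

EZ-defect lesions are elliptical en face footprints inside which the EZ
band amplitude is attenuated by the lesion severity (a severity ≥ 0.5
footprint counts as true EZ loss); shadow lesions attenuate *all* bands,
emulating signal blockage by hemorrhage or fluid. Ground truth —
boundary depth maps, defect mask, rasterized defect area within the CSF,
and a gradability flag (true blocked fraction of CSF pixels ≤ 0.25) — is
exact by construction. The phantom deliberately omits speckle statistics,
motion artifacts, vessel shadows and real pathology other than EZ loss
and shadowing; passing tests therefore demonstrate correctness of the
measurement chain, not clinical segmentation performance on real scans.

## Boundary segmentation

The tracker is automatic and deterministic: per column, the profile is
depth-smoothed (σ = 1 px); the vitreoretinal surface is the first crossing
of a relative rising threshold; the RPE is the brightest ridge at least
40 px below the surface; the EZ is the deepest local maximum 8–55 px above
the RPE whose prominence reaches 55% of the RPE prominence. Columns
without a qualifying EZ ridge are *undefined* — candidate defects.
Both ridges are refined to their half-prominence inner borders and
median-smoothed across columns (width 5). All decision rules are ratios
of intensity differences, so outputs are invariant to global affine
intensity rescaling. A scan in which the RPE is undetectable (prominence
below 20% of the scan median) in more than half the columns raises the
scan-level failure signal. Confidence per column is the EZ/RPE prominence
ratio clipped to [0, 1]. The 55% prominence threshold is the package's
convention for "EZ absent vs ambiguous": on the phantom the intact-EZ
ratio is ≈ 0.8 and the strongest confounder (the ELM-like band) sits near
0.4, so the midpoint separates them with margin at realistic noise.

## En face mapping and the central subfield

EZ thickness per en face cell is `(RPE inner − EZ inner) × axial µm/px`,
0 where the EZ is undefined (defects appear dark). The CSF is the central
1 mm diameter disc of the ETDRS grid — the diameter is forced by the
area cap of 0.78 mm² ≈ π·(0.5 mm)² — centered on the fovea, which
defaults to the scan center (the acquisition protocol is fovea-centered)
and is overridable. Membership is by pixel-center test with no partial
pixels, so areas are exact pixel counts times pixel area and the
brute-force counting oracle is exact. At the 6 mm cube's 46.9 µm B-scan
pitch the rasterized disc area is 0.789 mm² (1436 pixels); it converges
to π/4 under grid refinement, which the tests check at 4× resolution.

## Defect classification

En face maps are classified pixel-wise into defect vs intact EZ by a
bagged ensemble of decision trees (60 trees, depth ≤ 12, single-threaded
for determinism) over a fixed feature bank: raw thickness, Gaussian
smoothing at σ ∈ {1, 2, 4} px, gradient magnitude (σ = 1), local variance
and local min/max over 5 × 5 neighborhoods. Training pixels are
subsampled to ≤ 200 000; out-of-bag accuracy is the reported held-out
estimate. The probability threshold is 0.5 and no morphological
post-processing is applied — the endpoint is total area, not lesion
shape. Models embed a hash of the feature configuration and refuse to
predict under a mismatched config. The default training set is 8 phantom
maps whose lesion areas span 0–0.4 mm², one quarter of them defect-free.

## Quantification and grading

Raw defect area is the classified pixel count times pixel area within the
CSF. Reporting rules: values below the measurability floor of 0.004 mm²
are zero; the report is capped at 0.78 mm² (the CSF itself). Presence is
strict: reported > 0.004 mm². A raw value of exactly 0.004 mm² is thus
reported as measurable but counted as defect-absent — both printed rules
are honored and the boundary case has measure zero. Gradability: a column
is blocked when its signal index (RPE prominence normalized to the scan
median, clipped to [0, 1]) falls below 0.3; the scan is ungradable when
more than 25% of CSF columns are blocked. The three-step qualitative
grade uses the defect fraction of the exact disc area π·0.25 mm² (so
thresholds are resolution-independent): normal below 0.02, absent at or
above 0.50, patchy between, with `cannot_grade` taking precedence on
ungradable scans. Human graders carry no numeric thresholds; these two
cutoffs are explicit package conventions, config-exposed, and an optional
grader-noise mode flips adjacent categories with a configured probability
to emulate intergrader variability.

## Synthetic cohort

Each participant carries an integer baseline VALS uniform on [19, 73]
(the eligibility window) depressed by −75 letters/mm² of the
participant's latent defect burden and clipped back to the window:
photoreceptor damage costs acuity before treatment, and at the cohort's
mean positive burden (~0.13 mm²) this reproduces the ~10-letter gap in
VALS *levels* between defect and no-defect eyes, which the ~1-letter
contemporaneous effect alone cannot. VALS change from baseline at
follow-up visit v
is `visit_effect[v] + area_slope × area_v + ε_v`, with ε a stationary
AR(1) process over the ordered visits M01, M06, M12, M24 (default
ρ = 0.5, marginal SD σ = 8 letters) and `area_slope = −20` letters/mm²
(one letter lost per 0.05 mm² of defect). Visit effects default to
{15.4, 20.8, 22.5, 19.8} letters — the zero-area intercepts, chosen as
the normal-EZ stratum means so that the negative slope then reproduces
the worse trajectories of the patchy/absent strata. Stored VALS are
rounded and clipped to the 0–100 letter scale. Defect areas are
zero-inflated log-normal: 48.7% structural zeros, positive areas
log-normal(µ = −2.572, σ = 1.078) jittered per visit (log-SD 0.35) and
capped at 0.78 mm², giving cohort moments ≈ 0.07 ± 0.14 mm² at M01 —
the only distribution shape consistent with mean ≪ SD plus a large
zero mass. Per-visit missingness (attrition) and ungradability rates
default to the reference cohort's observed rates (77% ungradable at
baseline, improving under treatment). Visits are treated as equally
spaced indices for the AR(1) structure, matching the categorical-visit
model.

## Statistics

Percentages round half-up to one decimal. The t-test is Welch by default
(pooling unspecified in the source analyses); one-way ANOVA and the
point-biserial correlation use the standard F and t reference
distributions. The longitudinal model regresses VALS change on
categorical visit, the EZ predictor (continuous area or categorical
grade) and their interaction in a saturated cell-means parameterization,
so each coefficient reads directly as a per-visit effect. Estimation is
maximum likelihood with the AR(1) correlation ρ profiled out: at each ρ,
GLS via per-participant Cholesky whitening of the observed-visit
submatrix of `ρ^|i−j|` (valid for intermittently missing visits because
AR(1) marginals of a visit subset are just the corresponding entries —
no imputation), then bounded 1-D search of the profile likelihood over
ρ ∈ (−0.95, 0.95). Standard errors are the ML Wald ones,
`σ²(XᵀV⁻¹X)⁻¹`. With ρ fixed at 0 the fit reduces to OLS exactly, which
is tested to 1e-8. ML (not REML) is used; the simulate-and-refit study
(100 replicates, n = 300) shows the slope recovered within Monte-Carlo
error and ~95% Wald coverage, which is the package's calibration
evidence for this choice. The family-wise significance threshold after
Bonferroni correction is the fixed constant α = 0.002 (strict
inequality); the implied comparison count is not derived.

## Validation studies and problem sizes

Built-in studies (`ezquant.studies`) recompute all agreement numbers
from fresh simulations: end-to-end area recovery over 50 phantom eyes
with lesion areas spanning 0.01–0.26 mm² at intensity noise SD 0.1
(ICC(1,1) and mean bias between reported and rasterized-truth areas);
segmentation Dice between EZ-undefined columns and true footprints on
noiseless phantoms plus mean boundary error in axial pixels; and the
AR(1) recovery study above. The demo pipeline default is 12 eyes × 4
visits, a size chosen so a complete worked example (including classifier
training) finishes in a few minutes on one CPU; all sizes are
config-exposed.

## Numerical and degenerate-input conventions

Depth index 0 is the innermost (vitreous) row; grids are 0-based with
half-open intervals. An all-zero or contrast-free scan yields the
segmentation failure signal rather than boundaries. Ties in the EZ
candidate search resolve to the deeper (RPE-adjacent) ridge. The
background estimate is the 20th intensity percentile of the column.
Percentage denominators are visit-specific non-missing counts. The
pipeline fans a single global seed out to per-stage child seeds by
hashing stage names, so adding a stage does not shift earlier random
streams; identical configs reproduce byte-identical tabular outputs.

## Known limitations

The phantom's separability makes classifier accuracy near-ceiling;
reported ICC/bias characterize the measurement chain, not clinical
performance. Fovea localization is assumed (scan center) rather than
detected. Only the central subfield is modeled, not the full 9-subfield
grid. The grade thresholds and the EZ-prominence convention are
package conventions where the underlying clinical protocol relies on
human judgment. Intergrader agreement modeling is limited to the
adjacent-category flip mode. Treatment-arm comparisons and
injection-count analyses are out of scope.
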