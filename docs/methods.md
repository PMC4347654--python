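# Methods and modelling notes

## The quantification problem

On late gadolinium enhancement (LGE) images acquired after acute infarction,
necrotic myocardium retains contrast and appears bright; on T2-weighted STIR
images the oedematous area-at-risk appears bright. Given manually drawn
endocardial and epicardial contours, each quantification method reduces to a
rule for picking a signal-intensity threshold and a pair of corrections an
analyst would apply afterwards. The package implements those rules exactly
as stated below, and everything downstream (masses, percentages, agreement
statistics) follows deterministically.

Conventions held fixed throughout:

- **Enhancement is strict**: a voxel is enhanced iff SI > T. The methods
  are described in the field with "above"/"exceeds"; we pin the strict form
  and keep it consistent across methods so exactness tests are meaningful.
- **kSD uses the sample SD** (n−1) of the remote ROI. At the default ROI
  size (2 cm² ≈ 89 voxels at 1.5 mm pixels) the difference from the
  population SD is negligible, but the choice must be pinned for
  machine-precision threshold tests.
- **Per-slice Otsu** builds a 256-bin histogram over that slice's
  myocardial min–max range; candidate thresholds are the interior bin
  edges; class statistics are computed exactly over the voxel values on
  each side of the candidate; ties break toward the lowest threshold. A
  brute-force search over the same candidates is the test oracle, and the
  two agree exactly on random slices. A constant-intensity slice has no
  two-class structure and yields no enhancement (with a warning). A
  threshold is computed on every quantifiable slice regardless of infarct
  presence — this is deliberate, because it is the method's documented
  overestimation mechanism.
- **FWHM auto-core** is the brightest myocardial voxel on quantifiable
  slices. The manual procedure (draw candidate core ROIs, keep the one with
  the highest maximum) reduces to exactly this, and it is what makes the
  method insensitive to ROI size.
- **%LVM denominator**: the most apical contoured slice is excluded from
  both the numerator and the denominator (the ratio is taken over the same
  tissue). The alternative convention — keep the apical mass in the
  denominator — is available via `include_excluded_in_denominator`.
  Myocardial density is fixed at 1.05 g/mL and cancels in every percentage;
  it only scales the absolute gram masses reported alongside.

## Correction operators

**[a] Core filling (2-D, per slice, 8-connectivity).** Hypointense cores
(microvascular obstruction on LGE, haemorrhage on T2w) sit inside
enhancement and belong to the lesion. A non-enhanced myocardial component
is added to the enhancement mask unless it is 8-adjacent to the exterior of
the epicardium (computed as the complement of the hole-filled myocardium on
that slice). This fills cores even where they touch the endocardial border
— subendocardial MVO abuts the blood pool routinely — while remote
myocardium, which always communicates with the epicardial exterior, is
never filled. The operator is idempotent and runs slice-wise because core
inclusion is a per-image judgement.

**[b] Noise removal (3-D, 26-connectivity).** Enhancement components
spanning fewer than `min_slice_span` slices (default 2) are removed as
noise artefact lacking interslice continuity. A `protect_mask` exempts
components intersecting known infarct-related-artery territory; the package
never infers that territory — it is observer knowledge and enters only as
an optional mask. Both corrections commute on phantom inputs and are
applied [a] then [b] by default.

## ROI construction

A region of interest is the N myocardial voxels nearest the seed
(Euclidean, in mm), N = round(area / pixel area), ties broken by (row,
column). The seed is snapped to its containing pixel centre first, making
the ROI invariant to sub-pixel seed perturbation; observer variability is
modelled as whole-pixel seed jitter, which is also how real ROI placement
varies. `avoid_rim_px` optionally erodes the candidate myocardium before
ranking: with partial-volume blur, rim voxels blend with blood-pool or
epicardial signal and would inflate the remote-ROI SD, whereas an observer
places the reference ROI in clean mid-wall myocardium. Remote ROIs in the
pipeline use one pixel of rim avoidance; the default is off.

## Statistics

The intraclass correlation is the two-way single-measure **absolute
agreement** form, computed from the ANOVA mean squares
(MS_rows − MS_err) / (MS_rows + (k−1)MS_err + (k/n)(MS_cols − MS_err)); the
consistency form, which ignores systematic rater offsets, is available
behind a flag. Category bins: ≥0.75 excellent, 0.60–0.74 good, 0.40–0.59
fair, <0.40 poor. Bland–Altman limits use bias ± 1.96·SD of the paired
differences (sample SD; the multiplier is configurable but 1.96 matches
standard reporting). The paired t-test returns p = 0 for a constant nonzero
difference (infinite-t limit, documented) and raises on identical inputs.
The Wilcoxon comparison of reproducibilities tests d₁² − d₂² per subject:
exact null distribution for n ≤ 25 with no zeros or tied magnitudes,
otherwise the normal approximation with Pratt zero handling and continuity
correction. Exact p-values equal full sign-flip enumeration (verified for
all n ≤ 10). Normality checking is delegated to standard routines and not
re-derived here.

## The phantom: what it emulates and what it does not

Each slice is an idealised annulus (endocardial/epicardial circles); the
infarct is a circular sector with adjustable angular extent, transmurality
(from the endocardium, as infarction progresses in reality) and slice span;
the oedema wedge is transmural and wider by an angular margin, so infarct ⊆
oedema ⊆ myocardium holds by construction. The MVO/IMH core is the
innermost `mvo_fraction` of the infarct area (2-D distance-transform
ordering), hence enclosed by enhancement. Speckles are 2×2 single-slice
bright spots in remote myocardium, kept out of the at-risk wedge and away
from the conventional remote-ROI site opposite the infarct (observers place
reference ROIs in artifact-free tissue). Partial volume is in-plane
Gaussian blur of the noiseless SI map; noise is additive Gaussian by
default (Rician optional — method behaviour under test depends on SI
contrast, and Gaussian keeps the oracles simple).

Default signal levels (arbitrary units): remote 100, infarct 400, oedema
(T2w) 250, MVO/IMH 50, blood 450, background 20, noise SD 10, blur 0.6 mm.
`si_lge_border` sets the LGE intensity of the oedema-minus-infarct zone; it
defaults to the remote level (invisible on LGE), which preserves the exact
separability property: with zero noise and blur, any threshold between
remote and infarct recovers the true infarct exactly after corrections.
Border-zone experiments set it to 170 — between the expected 5SD threshold
(≈150) and 8SD threshold (≈180) and below the FWHM threshold (≈220) — which
engages the known overestimation mechanism of low-k thresholds
(intermediate signal intensities at the infarct border) while leaving FWHM
nearly unbiased; per-slice Otsu overestimates through a second mechanism,
thresholding slices that contain no infarct. No published value exists for
the border-zone intensity or blur width; these defaults are configurable
modelling choices, not claims about any particular scanner.

Ground-truth percentages are computed under the same convention as the
pipeline (apical slice excluded from numerator and denominator), so
method-vs-truth comparisons are like-for-like.

**What passing tests do not show**: the phantom has no papillary muscles,
trabeculae, motion or surface-coil shading — precisely the structures that
manual contouring excludes in practice, which is why contours are inputs
here. Noise-free recovery and the directional bias pattern therefore
validate the operators and their interactions, not performance on clinical
images.

## Cohort simulation

Observer variability enters through exactly the channels real observers
control: smooth low-order radial jitter of the contour polygons (three
angular harmonics, so polygons stay simple), whole-pixel remote-ROI seed
jitter, and a small Gaussian jitter on manual (visual) lesion calls. The
manual reference standard is the mean of six manual analyses (three
observers × two replicates). Reports give, per method: mean ± SD over
subjects (first observer, first replicate), ICC and Bland–Altman bias vs
the reference, paired t, and interobserver (R1 vs R2) and intraobserver (R1
replicate 1 vs 2) blocks — the standard layout of method-comparison tables.
`reproduce_supplementary` computes the same report from any long-format
raw measurement table, with a column-mapping loader for externally produced
files. Left-ventricular ejection fraction is accepted as per-subject
metadata for the IS–LVEF correlation; it is never computed from images
here. Multiplicity control for the per-method t-tests is not applied; raw
p-values are reported.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen for tight
feedback: 96–128-pixel matrices, 6–8 slices, 20-phantom bias cohorts,
10-subject pipeline cohorts, 100-phantom monotonicity sweeps, 1000-slice
threshold-oracle sweeps. These sizes are the package's own choice of
experiment scale; all conditions (signal levels, noise, blur, ROI size) are
the defaults documented above. Determinism: every stochastic component
consumes a `numpy` `SeedSequence` derived from a single user seed, and
identical seeds produce bit-identical volumes, tables and report CSVs
across platforms.

## Known limitations

- The annular geometry cannot express non-convex or multi-territory
  infarcts; correction [b]'s protect-mask path is therefore exercised with
  synthetic sectors only.
- DICOM support covers plain single-frame series with consistent
  orientation; enhanced multi-frame DICOM and PACS transport are out of
  scope, as are proprietary workstation contour formats.
- FWHM for AAR and 2–3SD for IS are deliberately not wired into the
  pipeline method lists: the former grossly overestimates at T2w
  contrast-to-noise, the latter is known to overestimate IS; both remain
  reachable through the generic operators (`threshold_fwhm`,
  `threshold_ksd`) for anyone who needs them.
- Infarct heterogeneity (peri-infarct grey zone) is not modelled or
  measured.
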