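# Methods

This note documents the models behind `bolusqa`, the parameters that matter,
what the synthetic phantom does and does not emulate, and the numerical
choices made where the design was open.

## Chest phantom

The phantom body is an elliptic cylinder in LPS coordinates (half axes
120 × 80 mm left–right × anterior–posterior, 150 mm cranio-caudal, 3 mm
isotropic voxels by default), surrounded by air. Structures:

- **chest-wall CTV**: the anterior-left wall shell, i.e. body voxels within
  `wall_thickness` (default 15 mm) of the surface, restricted to an
  anterior-lateral sector and the central 70% of the axial extent;
- **PTV**: the CTV expanded isotropically by `ptv_margin` (default 5 mm,
  the standard setup margin) and clipped to the body. The expansion is a
  Euclidean distance-transform dilation, so CTV ⊆ PTV ⊆ body holds for
  every valid parameter set;
- **ipsilateral lung** (ellipsoid, excluded from the wall shell), **heart**
  (ellipsoid, caudal-medial) and a **spinal-cord PRV** (8 mm-radius
  posterior cylinder), all clipped to the body.

CT values are two-level (tissue 40 HU, lung −750 HU, air −1000 HU): enough
to exercise threshold segmentation, not a realistic HU distribution.

## Beam model

Dose is analytic, not a transport calculation. Along an axis-aligned beam
direction (default anterior→posterior), each voxel's water-equivalent depth
`z` is the cumulative tissue path (body **and bolus** voxels count equally;
the bolus has unit relative density), and the per-fraction dose is

    D(z) ∝ (1 − exp(−z / z_b)) · exp(−μ · max(0, z − z_b))

with `z_b = 15 mm` (a typical 6 MV depth of dose maximum) and
`μ = 0.004 mm⁻¹` (effective exponential falloff past the maximum). These
two defaults are deliberately calibration-free: only the build-up
*mechanism* matters downstream — a 5 mm bolus moves the skin from
`z ≈ 0` to `z ≈ 5 mm`, raising the surface dose by the closed-form factor
`(1 − e^{−5/15})/(1 − e^{−z/15})`. Transversely the field is the PTV's
beam's-eye projection dilated by 10 mm with a 5 mm-σ Gaussian penumbra, so
out-of-field structures see realistic near-zero doses.

Two plan normalizations are provided: `mid_ctv` (the CTV voxel nearest the
CTV centroid receives the per-fraction prescription, 5000 cGy / 25
fractions by default) and `d95` (the dose covering 95% of the PTV equals
prescription — the clinical convention "at least 95% of the target meets
the prescribed dose"). The demo pipeline uses `d95`; with it the coverage
CI at the 100% isodose is ≥ 95 by construction.

**Limitations.** A single unmodulated beam through an elliptic phantom is
nothing like a six-field IMRT plan: PTV homogeneity is poor (HI ≫ 0.1) and
organ-at-risk doses are grossly pessimistic, because the beam exits through
the lung instead of being arranged tangentially. The phantom therefore
supports *relative* and *structural* checks (build-up monotonicity, bolus
surface-dose gain, metric definitions against brute-force oracles), not
clinical plan-quality numbers, which require a real treatment planning
system.

## Bolus design and air gap

The body is segmented by thresholding (default −300 HU), one binary closing
with a 1-voxel ball, largest 6-connected component, and hole filling. The
bolus shell is `{x ∉ body : dist(x, body) ≤ thickness}` on the Euclidean
distance field — not a mesh inflation, which self-intersects on concave
chest walls — intersected with the marked area (an angular × axial window
in phantom coordinates; clinically the area is marked on the patient).
Surfaces are 0.5-level marching-cubes iso-surfaces in world mm; STL output
is binary little-endian, and the STL importer validates the declared facet
count against the file size and reports the byte offset of any truncation.

The air gap at a skin sample point is the signed distance along the outward
surface normal (vertex normal of the nearest skin vertex, oriented away
from the mesh centroid) to the nearest bolus-surface intersection,
found with a vectorized Möller–Trumbore line–triangle test. Negative gaps
(surface-discretization interpenetration) are kept in the per-point list
but clamped to zero in the mean, so interpenetration cannot mask real gaps.
Because the designed shell grows directly off the segmented skin, its inner
surface coincides with the skin iso-surface and the phantom's mean gap is
zero to within the marching-cubes discretization (well under one voxel);
a physical bolus on a deformable patient would not achieve this, and
measured clinical gaps of ~1 mm are the realistic target.

Sub-voxel geometry checks (median shell thickness along surface normals
within one voxel of the requested 5 mm) run on a reduced phantom — half
axes 60 × 45 mm, 60 mm length — at 1 mm voxels, a size chosen to keep the
1 mm distance transforms comfortably in memory while preserving the
curvature the check exercises.

## DVH engine

Metrics operate on the raw voxel dose samples of a structure:
Dmin/Dmax/Dmean are exact voxel extremes/mean (no near-min/near-max
smoothing); `Dx%` is the linear-interpolated order statistic at cumulative
volume fraction x (so D100% = Dmin); `Vx` is an exact count. The
homogeneity index HI = (D2% − D98%)/D50% is reported rounded half-up to two
decimals, doses to whole cGy, volume percents to two decimals — the
precision clinical reports use, with half-up (not banker's) tie-breaking.

No standard conformity-index formula is universally agreed; here CI is
target coverage: the percent of PTV voxels at or above
`iso_fraction × prescription` (default 0.95). This choice is consistent
with clinically reported CIs clustering just below 100%.

The quantile/volume operators are inverse-consistent
(`volume_at_dose(dose_at_volume(q)) = q ± one voxel's share`) for
continuous dose samples; exact ties — which the analytic beam model
produces in abundance, whole depth-layers sharing one value — legitimately
count every tied voxel, so that property is checked on continuous random
grids.

## Film dosimetry

The calibration maps net optical density, `netOD = log₁₀(R_unexposed/R)`,
to dose with the standard radiochromic-film form
`D = a·netOD + b·netODⁿ`, defaults `a = 600 cGy`, `b = 2200 cGy`,
`n = 2.5`, chosen so ~200 cGy (one 2 Gy fraction plus scatter) corresponds
to netOD ≈ 0.24, typical of EBT3 red-channel response. Per scanning
session the curve is rescaled with two reference films: the unexposed one
re-anchors netOD = 0 and the exposed one (known dose) fixes a single
multiplicative dose factor, exact at both references by construction.
Dose→netOD inversion is a bracketed Brent solve (tolerance 10⁻¹² netOD,
round-trip error ≪ 0.1 cGy over 50–400 cGy). Film-scan image processing
(TIFF channel extraction, lateral-response correction, the 24 h
darkening-stabilization delay) is out of scope: the module consumes mean
ROI responses.

The planned counterpart is the mean dose of a 10 × 1 mm ROI tangent to the
skin, nearest-voxel sampled and averaged over the three axial slices
nearest the film center. Per patient, `D_fact`/`D_theory` are the means of
the eight sub-region values (the aggregation behind one-number-per-patient
reports), and `|%diff|` is rounded half-up to two decimals.

## Toxicity grading and simulation

The RTOG grade map is restricted to the presentation codes that occur in
chest-wall follow-up records: FE/DD → 1, MER/MED/PMD → 2, PE/CMD → 3,
NEC → 4, with the maximum over a patient's codes (adding a code never
lowers a grade). The cohort simulator draws grade, presentation
combination, and onset fraction bin from the observed 360-patient study
mix (grade shares 321:32:7:0, combination and onset-bin frequencies per
grade, interruption probability 4/7 among grade-3 patients); these defaults
are the study conditions and are not tuned. At n = 10,000 the empirical
grade shares recover the inputs within 1 percentage point.

One tabulation nuance: the published interruption row's onset bins exceed
the grade-3 row counts in one bin, so when reconstructing a cohort from the
printed table the interruption flags are assigned by the interruption row
alone, independent of grade rows; the interruption rate counts flags only,
so the reconstruction reproduces every printed count.

## Determinism and problem sizes

Every stochastic operation takes a single integer seed and builds its own
`numpy` generator; no global state. Default test-suite problem sizes — the
3 mm phantom (~0.5 M voxels), the 1 mm reduced phantom (~1 M voxels),
10×10×10 random DVH grids, 100-seed film cohorts, 10,000-patient toxicity
simulations — were chosen so the full suite runs in seconds on one CPU
while leaving each check statistically meaningful.
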