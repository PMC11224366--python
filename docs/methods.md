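# Methods

## Scope and model

`myometry` quantifies fatty replacement and inflammation-associated signal
in skeletal muscle from co-registered 3D MRI: a Dixon water/fat image pair,
an integer-coded muscle label map on the Dixon grid (from any segmentation
source — the toolkit is agnostic to whether labels come from a neural
network, an atlas, or manual tracing), and optionally a STIR volume that
may sit in its own frame. It targets slowly progressive myopathies such as
FSHD, where fatty infiltration is heterogeneous between and within muscles,
so per-muscle scalars are complemented by within-muscle spatial profiles.

### Composition (per muscle)

With fat and water signal intensities FSI, WSI per voxel and TP voxels in a
muscle label:

    FF (%)        = (1/TP) Σ_p FSI_p / (FSI_p + WSI_p) × 100
    BoundaryVol   = (voxel count) × voxel volume
    FatVol        = BoundaryVol × FF/100
    LeanVol       = BoundaryVol × (1 − FF/100)

FF is the mean of voxelwise ratios, deliberately not total-fat over
total-signal: the two differ under intensity inhomogeneity and the
voxel-mean form is the convention this pipeline standardizes on. Voxels
with FSI + WSI = 0 have an undefined ratio; they are excluded from the FF
average and counted separately, but still contribute to the boundary
volume, which is purely geometric. Fat + lean = boundary closes exactly by
construction; the test suite asserts it on every run. No noise-floor
correction is applied to the two-point Dixon ratio.

### Length-normalized profiles

Per axial slice: boundary CSA = labeled pixels × pixel area; area FF is the
voxel-ratio mean restricted to the slice; fat/lean CSA split the boundary
CSA by area FF. Profiles are re-expressed on a 0–100% inferior→superior
axis at 1% increments. Choices that matter:

- **Linear interpolation** between slice centres: linearity preserves
  lean + fat = boundary at every interpolated point, which a spline would
  not.
- **Physical positions, not slice counts**, define percent-of-length, so
  anisotropic or gapped acquisitions normalize correctly (identical for
  uniform spacing).
- A slice counts as occupied with ≥ 1 labeled voxel; there is a
  configurable minimum-voxel filter but it defaults off — end-effects are
  handled by the conventional 10–90% display trim instead, and the
  untrimmed profile is retained for metrics.

### Label erosion

Erosion is 2D in-plane only, per slice, per label code, with a discrete
disc (pixel-centre distance ≤ radius, ties at the exact radius included —
deterministic and matching the common convention). Two modes: a physical
~4 mm radial footprint (pixel radius = round(4 mm / in-plane spacing),
about one pixel on typical grids) used for the chemical-shift sensitivity
analysis, and a one-pixel layer used after registration in the STIR
pathway. Codes can only shrink, so they never merge; slices where a code
vanishes are counted and reported. The sensitivity analysis pairs the
baseline→follow-up FF change computed with raw and eroded labels for
correlation/agreement downstream. Note that for muscles whose FF *change*
varies along their length, erosion legitimately shifts the measured change
slightly, because per-slice voxel counts are reweighted; on spatially
uniform change the two agree exactly.

### STIR pathway

1. **Limb mask** — one volume-level air/tissue threshold (lowest 3-class
   Otsu level; the histogram is multimodal with fat-suppressed
   subcutaneous tissue), then per-slice hole filling and largest-component
   selection. Volume-level statistics avoid single slices whose lesion
   content skews a per-slice histogram.
2. **STIR+ segmentation** — deterministic tiling of circular windows with
   diameter 20% of the limb's per-slice equivalent diameter, 50% overlap
   (standing in for an operator's threshold-paint strokes). Each window
   contributes pixels above both its local Otsu threshold and a global
   hyperintensity floor. The floor encodes what "hyperintense" means: when
   the limb histogram holds a credible bright class, the upper 3-class
   Otsu threshold (which bisects muscle and lesion intensity, classifying
   partial-volume boundary voxels by majority tissue) is used; otherwise
   1.5× the limb's lower-quartile muscle intensity. A window whose local
   threshold fails a robust bimodality guard (threshold ≤ median +
   3 scaled-MAD) falls back to the floor alone, so homogeneous normal
   tissue is never labeled bright, while homogeneous lesion interiors
   still detect via the floor. Per-slice hole filling closes any remaining
   interior gaps, then pixels within an edge margin (default 2 px) of the
   limb boundary are discarded as smooth-edge artifacts. An optional veto
   removes candidates whose registered Dixon FF exceeds 50% — the
   automated form of cross-checking bright spots against the Dixon images
   so subcutaneous/confluent fat is not called hyperintense.
3. **Registration** — 6-DOF rigid, Mattes mutual information (the water
   and STIR contrasts differ), multi-resolution 4×/2×/1× with LBFGSB,
   initialized from moments- and geometry-centred starts. The metric is
   evaluated only inside a conservatively trimmed limb mask so values are
   comparable across candidate transforms (mutual information over a
   sliding overlap region is not), and a final full-resolution multi-start
   over ±1–2 axial slices resolves the through-plane local minima typical
   of thick-slice, near-cylindrical anatomy. A half-voxel Gaussian at full
   resolution keeps the metric surface differentiable against
   voxelization. Deterministic for a fixed seed.
4. **Content** — labels are nearest-neighbour resampled onto the STIR
   grid, eroded one layer in-plane (absorbing residual registration error
   at borders; configurable off), and STIR content (%) = STIR+ voxels
   inside the muscle ÷ muscle voxels × 100.

### Reliability statistics

- Overlap: both Jaccard |A∩B|/|A∪B| and Dice 2|A∩B|/(|A|+|B|) are
  reported — parts of the muscle-MRI literature print the IoU form under
  the name "Dice", and carrying both (they are linked by dice = 2j/(1+j))
  keeps results comparable with either convention.
- Relative volume error: 100·|a−b| / mean(a,b); FF difference: |a−b|
  (percentage points).
- Bland–Altman: differences oriented second − first; fixed bias by
  one-sample t (df = n−1), proportional bias by the least-squares slope of
  difference on pair mean (df = n−2); both are always reported because the
  two tests answer different questions about the same plot. Limits of
  agreement are bias ± 1.96 SD. Identical pairs are flagged degenerate
  (zero variance: no t).
- Spearman: average-rank ties; p by exhaustive permutation for n ≤ 9 and
  the t approximation above. No multiple-testing correction is applied by
  default (a Holm option exists); the statistics here validate a pipeline,
  not a confirmatory hypothesis family.
- Ordinal scales: volumetric FF maps to the 1–6 fat rating through
  monotone bins anchored at 30% and 60%; the sub-30% splits (5%, 15%) and
  the 85% split between ratings 5 and 6 have no standard quantitative
  anchors and are package defaults, configurable. STIR content maps to the
  0–4 grade through <30 / 30–60 / >60 bins; grade 1 ("mild diffuse
  elevation") is categorical rather than a volume fraction and is asserted
  by flag, never inferred from a percentage — a thresholding pipeline is
  expected to score mild diffuse lifts near 0%.

## The phantom generator

Everything above is validated against synthetic limbs with exact ground
truth: a cylindrical limb with a subcutaneous fat ring, tube-shaped muscles
with elliptical cross-sections and closed-form taper (none / linear /
sinusoidal, so CSA(z) is analytic), and a voxelwise FF field following one
of five archetypal patterns along normalized length — homogeneous,
logistic high-distal or high-proximal, and Gaussian-bump high-centre or
high-ends. Dixon channels follow the generative model

    water = S0 (1 − FF/100)(1 + ε_w),   fat = S0 (FF/100)(1 + ε_f)

with independent Gaussian ε of configurable fractional SD, clipped at zero
(Rician optionable; at phantom SNR the Gaussian approximation is adequate
and keeps oracles analytic). The STIR volume renders muscle at 100,
fat-suppressed tissue at 40 and lesions at 300 arbitrary units, placed as
full-cross-section axial slabs sized to programmed per-muscle STIR+
fractions (nearest achievable slab under slice granularity), optionally
resampled into an offset frame through a known rigid transform. Follow-up
timepoints add per-muscle mean FF increments weighted by |axial FF
gradient|^γ (γ default 2), mimicking progression concentrated in
transition zones, renormalized to the programmed mean, clipped at 100% with
the lost mass reported. A "rescan" helper re-positions the limb by a
sub-voxel jitter and redraws noise, emulating a short-interval repeat with
ground-truth segmentation at both visits.

Default study conditions used by the tests and the acceptance script:
three fixtures (a 3-muscle 40×40×24 @ 2×2×4 mm grid for fast tests; a
5-muscle 64×64×48 @ 1.5×1.5×3 mm five-pattern phantom; a 2-muscle
large-muscle variant whose muscles exceed 10,000 voxels), Dixon channel
noise 2% of S0, STIR noise SD 5 units, cohorts of 10 subjects × 3 muscles
with severity drawn uniformly across the rating scales, and rigid offsets
up to 5° / 10 mm.

What the phantoms do **not** emulate: bias fields, chemical-shift
displacement rendering (beyond an optional rim-bias construction in the
morphology tests), motion, partial-volume mixing beyond grid resampling,
realistic muscle shapes and packing, or biological progression. Passing
tests therefore demonstrate correctness of the measurement pipeline given
valid labels and signals — not robustness to acquisition artifacts, nor
segmentation quality, which is supplied by the upstream model and assessed
with the reliability module on real repeats.

## Numerical and design choices

- Single internal unit system (mm/mm²/mm³); rendering in cm³ is
  presentation-side only.
- Arrays are (x, y, z) with z axial and increasing-superior by default;
  both are per-file overridable, and profile normalization is invariant to
  storage direction.
- Spacing equality between grids uses a 1e-4 mm tolerance — header float
  noise, not real mismatch.
- Label dictionaries are JSON sidecars (code, name, side): diffable and
  format-conversion-proof. Left and right muscles are separate analysis
  units throughout.
- Histograms default to 1% bins over [0, 100] with the last bin closed.
- Muscles present in the dictionary but absent from a grid produce flagged
  zero rows, keeping multi-site tables rectangular.
- Metric tables are written with 6-significant-digit formatting so
  save→load→save is byte-stable.
- Every stochastic component (phantom noise, registration sampling) takes
  an explicit seed; reruns of a pipeline config produce hash-identical
  artifacts.
- Phantom truth for STIR content is recorded both against raw labels and
  against one-layer-eroded labels, because the pathway's default erosion
  changes the denominator; recovery is asserted against the convention
  actually measured.

## Known limitations

- The registration assumes overlapping anatomy and benefits from
  azimuthal/axial structure; on a perfectly symmetric object the rotation
  about the limb axis is unidentifiable (true of any rigid registration).
- The STIR window tiling is a deterministic stand-in for interactive
  operator strokes; the "20% of the limb" window size is interpreted as a
  diameter fraction and is configurable.
- Curved muscle axes are supported only as gentle bows; profiles use axial
  slices, not centerline reparameterization.
- Absolute CSA error statistics operate on the 101-point grid
  (configurable), one of several defensible conventions.
- DICOM ingestion, bias-field correction and general grid resampling are
  out of scope; volumes must arrive as co-registered NIfTI except for the
  rigid Dixon→STIR pathway.
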