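# Methods

`dwiaspects` turns a binary DWI lesion segmentation into the two imaging
biomarkers used for rapid severity assessment of middle-cerebral-artery
acute ischaemic stroke (MCA-AIS): the DWI-ASPECTS score and the infarct
core volume. This note documents the models, the parameters that matter,
the synthetic data used for validation, and the numerical choices.

## Scoring model

ASPECTS divides each MCA territory into ten regions: four deep "nuclear"
structures — caudate (CA), lentiform nucleus (LE), internal capsule (IC),
insular ribbon (IN) — and six cortical territories M1–M6 spread over the
ganglionic (M1–M3) and supraganglionic (M4–M6) axial levels. Scoring
starts from 10 and deducts one point per involved region:

* **nuclear rule** — any lesion involvement deducts (default: a single
  voxel; a configurable floor `nuclear_min_overlap_mL`, default 0, can
  absorb registration noise);
* **cortical rule** — a deduction requires the lesion to cover at least
  one third of the territory, threshold inclusive (`fraction >= 1/3`).

The 1/3 rule is evaluated on the volumetric fraction of the full 3-D
template region, not slice-wise; the threshold is configurable
(`cortical_fraction_threshold`) for sensitivity studies. Scores are
computed independently per hemisphere (hemisphere membership is defined
by the atlas labels, never by a runtime mid-plane split); the reported
score is the minimum over hemispheres containing lesion, with a
`bilateral` flag when both do, and 10 for an empty mask. The tool targets
unilateral MCA stroke; the bilateral case is reported conservatively and
flagged rather than defined away.

Core volume is foreground voxel count × voxel volume / 1000 (mL). Because
affine registration changes volume, the subject report carries both the
template-space volume (used in cohort analyses) and the native-space
volume when a native mask was supplied.

Imaging severity flags use the operating points established for
separating mild from moderate–severe stroke: ASPECTS ≤ 6 (low tail,
inclusive) and core volume ≥ 27.86 mL (high tail, inclusive). Both
cutoffs are configurable.

## Geometry and registration

All volumes are reoriented to RAS on load; voxel indexing is 0-based;
NIfTI-1 is the only supported format (DICOM conversion and skull
stripping are documented preconditions — a `strip_hook` can be plugged
into the pipeline). Resampling of masks and label maps is always
nearest-neighbour, so no label values can be invented; images use
trilinear interpolation.

Subject-to-template alignment is orientation matching followed by four
registration rounds — rigid, rigid, affine, affine — each initialised
from the previous round's result. The round schedule is the contract; the
optimiser behind it is a pluggable SimpleITK backend: Mattes mutual
information (32 bins, 30% random sampling with a fixed seed), 3-level
multi-resolution (shrink 4/2/1, smoothing 2/1/0 voxels), regular-step
gradient descent with physical-shift scaling. Mutual information is the
default because the clinical deployment registers DWI subjects to a
T1-weighted template (cross-modality); mean-squares and correlation
metrics are available. If the final similarity is worse than the starting
point the run fails loudly with per-round metrics. Transforms are stored
as 4×4 RAS world matrices (template-world → subject-world, the resampling
direction) with per-round provenance in a JSON sidecar. Lesion masks are
always transformed by the image-driven registration result with
nearest-neighbour interpolation — the mask never drives registration.

On synthetic phantoms, the schedule recovers sampled rigid perturbations
(|rotation| ≤ 10°, |translation| ≤ 10 mm) and mild affines (scale
0.9–1.1, shear ≤ 0.05) to well under 1 mm mean landmark error. Note that
decomposing a recovered *affine* into a rotation angle via the trace
formula is meaningless once scale/shear is present; recovery quality is
always assessed as mean landmark displacement.

## Synthetic atlas and phantoms

The hand-drawn ICBM-space ASPECTS template used clinically is not
redistributable, so validation runs on a generated stand-in: an
ellipsoidal brain split at the mid-sagittal plane, each hemisphere tiled
into 10 connected regions — a central nuclear block split into CA/LE/IC/IN
quadrants plus M1–M3 on the lower axial band and M4–M6 on the upper band,
echoing the two ASPECTS reading levels. Label numbering is fixed (left
1–10, right 11–20 in the order CA, LE, IC, IN, M1..M6). A T1-like
template image (tissue contrast + smooth gradient, lightly blurred) gives
registration a structured target. The default unit-test atlas is 64³ at
1 mm; cohort analyses use 64³ at 2 mm, giving a ~0.7 L brain with
cortical territories of ~40–90 mL and nuclear regions of ~6 mL. That
scale matters: region volumes are the denominators of the 1/3 rule, so
they must sit in the clinical range for lesions of 4–200 mL to interact
with the cortical threshold the way patient lesions do (on a much larger
ellipsoid the rule can never fire and the score–severity gradient
inverts). Real-data users supply their own atlas via `load_atlas` (NIfTI
label map + `label,code,hemisphere` CSV).

Phantom lesions are seeded random connected growths (randomised Prim
expansion over the voxel lattice). Exact-fraction phantoms clip growth to
the target region and realise `ceil(fraction × region voxels)` voxels —
within one voxel quantum of the request — which lets tests place cortical
coverage exactly at 0.30 / 1/3 / 0.40. Phantom images are background 100,
lesion 100 × contrast (default 2.5, DWI-like hyperintensity), Gaussian
smoothing σ 0.6 and additive noise σ 5; they emulate skull-stripped DWI
contrast, not diffusion physics (no b-value model, no ADC, no artifacts),
so passing tests demonstrate the pipeline's geometry and rules, not
robustness to scanner variability.

Cohorts link lesion anatomy to clinical severity (NIHSS bands: mild 0–7,
moderate 8–16, severe 17–42; default mix 0.64/0.26/0.10 following the
observed 390/158/60 prevalence). Per class, target volumes are log-normal
with medians 4 / 30 / 80 mL (sdlog 0.6 / 0.5 / 0.4) — chosen to straddle
the 27.86 mL operating point so threshold recovery is informative — and
region involvement encodes the qualitative topography gradient: mild
disease is confined mostly to one deep nucleus (the caudate most often)
with little cortical spread; moderate disease mixes deep and cortical
involvement weighted toward M2/M5; severe disease seeds cortically and
involves most of M1–M6. Growth spills beyond the sampled territory set
when the sampled volume demands it (large infarcts are not
territory-bounded). These choices make the generated mean ASPECTS
decrease and the mean volume increase monotonically across severity
classes — the structure the downstream analysis assumes — which the test
suite verifies empirically on each run. NIHSS is uniform within its
band — only the band structure is consumed downstream.
`analytic_volume_threshold` computes the population Youden point of the
designed mixture (the density-crossing point) that sampled thresholds
should recover; at the defaults it sits near 12.6 mL.

## Statistics

* Dice 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks.
* Spearman r (average ranks for ties) with a Fisher-z CI using the
  Bonett–Wright standard error sqrt((1+r²/2)/(n−3)); a bootstrap CI was
  considered unnecessary at the n used here.
* ICC fixed to the two-way random-effects, absolute-agreement, single
  measurement form, ICC(2,1), matching its use for method agreement; the
  consistency form ICC(3,1) is available behind a flag. Point estimates
  follow the mean-squares decomposition; CIs are the McGraw–Wong F-based
  intervals (via pingouin). Note the ratio estimator is noticeably
  upward-skewed with very few raters (k = 3).
* Group comparison: Mann-Whitney U for continuous variables (two
  groups); for categorical variables, Fisher's exact test when every
  contingency cell is below 10 (2×2), otherwise chi-square without
  continuity correction.
* ROC: empirical curve over observed thresholds; AUC equals the
  normalised Mann-Whitney statistic exactly; the Youden operating point
  maximises sensitivity + specificity − 1 with ties broken toward higher
  sensitivity; AUC CIs use the DeLong variance. Direction is explicit per
  marker: ASPECTS flags severity at the low tail (score ≤ threshold),
  volume at the high tail (volume ≥ threshold), matching the inclusive
  cutoffs above.
* DeLong test: two-sided comparison of paired empirical AUCs from the
  structural-component covariance; an exactly zero AUC difference
  (identical or rank-equivalent markers) returns p = 1.

Cohort-level severity analysis tallies per-region deduction frequencies
(denominator: severity-class size) per hemisphere and pooled, min-max
normalises them to [0,1] within each class (a constant class maps to 0),
tests each region's deducted/not-deducted × severity table with the
categorical rule above (never-deducted regions are flagged non-testable,
not errors), and derives ROC/Youden thresholds for the mild vs
moderate–severe contrast (moderate and severe merged). Raw p-values are
the reported quantity; a Bonferroni column is emitted for transparency
only.

## 3-D U-Net segmenter

The optional segmenter is a standard volumetric U-Net: 3×3×3
convolutions (2 per resolution block, configurable 2–4), 2×2×2 max
pooling over 3 encoder levels, batch normalisation, transposed-convolution
upsampling (nearest-neighbour interpolation available) with skip
connections, and a 1×1×1 sigmoid head; 16 base channels doubling per
level (~1.4 M parameters at the defaults). Training uses Adam at an
initial learning rate of 1e-2, 100 epochs and batch size 32 by default,
soft-Dice loss (cross-entropy + Dice available), and per-volume z-score
input normalisation. The head bias is initialised to −2 so initial
predictions sit near p ≈ 0.12: with rare foreground this keeps the
soft-Dice denominator small and early gradients informative (a standard
low-prevalence initialisation). Training is deterministic for a fixed
seed.

The implementation is pure NumPy: activations are kept channels-last and
convolutions run as one BLAS GEMM per kernel offset over the full padded
array with shifted-view accumulation; backward passes are hand-derived
adjoints verified against float64 finite differences. At desk scale
(batch 8 × 32³, 1 CPU) an epoch takes ~8 s. Input spatial dimensions must
be divisible by 2^depth; prediction errors advise padding. The validation
surface for this module is a memorisation check — 8 phantoms overfit to
training Dice ≥ 0.9 within 60 epochs — which demonstrates that the
architecture and optimisation learn; multi-centre patient-level Dice is
out of reach without patient data. The scoring pipeline accepts any
externally produced mask, so the segmenter is never required.

## Problem sizes and numerical choices

* Scoring-oracle and monotonicity checks run on a 40³ atlas (the oracle
  is a literal Python triple loop); rule-fidelity and registration checks
  on the 64³ @ 1 mm atlas; threshold recovery on 64³ @ 2 mm cohorts (400
  subjects in the test suite, 300 in `scripts/acceptance.py`).
* Registration recovery: 20 rigid + 10 affine cases in the suite, 5 + 3
  in the acceptance script; divergence tolerance 1e-3 on the metric.
* The acceptance script's U-Net run uses 4 phantoms (early-stopped at
  Dice 0.9, cap 60 epochs); the test suite runs the full 8-phantom
  configuration.
* End-to-end registration score-equality checks use a 0.05 mL nuclear
  floor: a perturb → register → nearest-neighbour resample round trip can
  flip single interface voxels into a nuclear region, and the any-voxel
  rule would otherwise fire spuriously. The package default remains 0.
* Exact-equality assertions are reserved for integer tallies and the
  AUC/Mann-Whitney identity; float comparisons use explicit tolerances
  (voxel quanta for realised fractions, 1e-12 relative for volumetry).

## Known limitations

* The synthetic atlas is geometric, not anatomical; region shapes,
  adjacencies and sizes only coarsely resemble the clinical template.
* Phantom DWI contrast is a two-level intensity model; segmenter results
  on phantoms say nothing about patient-level performance.
* Only unilateral anterior-circulation scoring is modelled (no
  pc-ASPECTS, no ADC-based core, no perfusion mismatch).
* Registration is linear (rigid/affine) by design; deformable residuals
  are absorbed, imperfectly, by the nuclear floor and the 1/3 threshold.
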