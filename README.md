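# dwiaspects

Automated DWI-ASPECTS scoring and infarct core volumetry for acute
ischaemic stroke in the middle cerebral artery territory.

Clinicians grade early ischaemic change with ASPECTS — a 10-point scale
over ten regions per hemisphere: the caudate (CA), lentiform nucleus
(LE), internal capsule (IC) and insular ribbon (IN), plus the cortical
MCA territories M1–M6. Applied to diffusion-weighted MRI (DWI-ASPECTS),
one point is deducted for any lesion in a nuclear region and one point
for a cortical territory whose volume is covered ≥ 1/3 by the lesion:

    score_h = 10 − #{deducted regions in hemisphere h}

Manual scoring is experience-dependent and slow; this package turns a
lesion segmentation mask into the score automatically. A skull-stripped
DWI volume is aligned to a template by orientation matching plus four
registration rounds (rigid, rigid, affine, affine; mutual-information
metric), the lesion mask follows by nearest-neighbour resampling, and
per-region overlap fractions against a 20-region ASPECTS atlas drive the
deduction rules. Alongside the score the tool reports the infarct core
volume (voxels × voxel volume, in mL) and two severity flags at the
operating points separating mild from moderate–severe stroke:
ASPECTS ≤ 6 and core volume ≥ 27.86 mL (both inclusive, both
configurable).

The package is aimed at imaging researchers validating automated ASPECTS
pipelines: it ships the full evaluation toolkit (Dice, Spearman with CI,
ICC(2,1), Mann-Whitney / chi-square / Fisher with the small-count rule,
ROC with Youden thresholds, the DeLong paired-AUC test), a cohort-level
severity analysis (deduction-frequency histograms, normalised frequency
maps, per-region association tests, data-driven thresholds), a synthetic
atlas/phantom/cohort generator for testing without patient data, and an
optional pure-NumPy 3-D U-Net segmenter. Patient data, the clinical
ICBM-space atlas and trained network weights are not distributed; users
with real data supply their own atlas (`load_atlas`).

## Worked example

Build a synthetic atlas, place a lesion with known per-region coverage
(40% of left M1, 35% of left M5, 2% of the left insular ribbon), and
score it:

```bash
dwiaspects make-atlas --shape 64 64 64 --seed 7 --out demo/atlas
python - <<'PY'
import dwiaspects as dw
from dwiaspects.volume_io import write_volume
atlas = dw.build_synthetic_atlas((64, 64, 64), seed=7)
sub = dw.generate_phantom(atlas, dw.PhantomSpec(
    {("M1", "left"): 0.40, ("M5", "left"): 0.35, ("IN", "left"): 0.02},
    seed=3))
write_volume(sub.volume, "demo/sub01_dwi.nii.gz")
write_volume(sub.truth_mask, "demo/sub01_mask.nii.gz")
PY
dwiaspects score \
    --atlas-labels demo/atlas/atlas_labels.nii.gz \
    --atlas-table  demo/atlas/atlas_regions.csv \
    --dwi demo/sub01_dwi.nii.gz --mask demo/sub01_mask.nii.gz \
    --template-space --out demo/out --subject-id sub01
```

prints

```json
{
  "subject_id": "sub01",
  "reported_score": 7,
  "reported_hemisphere": "left",
  "core_volume_mL": 6.115,
  "deductions": [["IN", "left"], ["M1", "left"], ["M5", "left"]]
}
```

Three rules fired: M1 (0.40 ≥ 1/3) and M5 (0.35 ≥ 1/3) deduct under the
cortical one-third rule, and the insular ribbon deducts on any
involvement because it is a nuclear region — so the left hemisphere
scores 10 − 3 = 7. The 6.1 mL core volume is the lesion voxel count at
1 mm isotropic spacing. A full per-region report
(`demo/out/sub01_report.json`) and a QC overlay NIfTI are written
alongside. Without `--template-space`, the DWI is first registered to the
atlas template and the mask follows the recovered transform.

Cohort runs (`dwiaspects cohort manifest.csv ...`) add the severity
analysis: per-region deduction frequencies by NIHSS band (mild 0–7,
moderate 8–16, severe 17–42), association tests, and ROC/Youden
thresholds for the mild vs moderate–severe contrast.

## Layout

    src/dwiaspects/
      volume_io.py      NIfTI I/O, canonical RAS orientation, resampling
      atlas.py          ASPECTS atlas model + synthetic atlas generator
      registration.py   4-round rigid/affine alignment (SimpleITK backend)
      scoring.py        region overlaps, deduction rules, score, volume
      phantoms.py       exact-fraction phantoms, severity-linked cohorts
      stats.py          Dice, Spearman, ICC, ROC/Youden, DeLong, group tests
      severity.py       deduction frequencies, association tests, thresholds
      unet.py           pure-NumPy 3-D U-Net segmenter (optional)
      pipeline.py       subject/cohort orchestration, JSON reports
      cli.py            `dwiaspects` command-line interface
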