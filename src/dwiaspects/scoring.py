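"""DWI-ASPECTS scoring from a template-space lesion mask and an atlas.

The ASPECTS deduction rules, as applied to a 3-D template-matched lesion
segmentation:

* a point is deducted for any lesion involvement of a nuclear region
  (caudate, lentiform nucleus, internal capsule, insular ribbon);
* a point is deducted for a cortical territory (M1-M6) when the lesion
  covers at least one third of the territory's volume (inclusive >=).

Scores are computed per hemisphere as 10 minus the hemisphere's deduction
count. The reported score is the minimum over hemispheres containing any
lesion (with a bilateral flag when both do) and 10 for an empty mask —
unilateral MCA stroke is the designed use case, so the conservative score
is reported when both hemispheres are involved.

The cortical threshold is applied to the volumetric fraction of the full
3-D region; both the threshold and a minimum nuclear overlap (in mL, to
absorb registration noise) are configurable via :class:`DeductionRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AspectsAtlas, AspectsRegion, CODES, HEMISPHERES
from .volume_io import LabeledVolume, VolumeError


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class DeductionRules:
    """Parameters of the deduction rules.

    cortical_fraction_threshold
        Volumetric lesion fraction at or above which a cortical region
        deducts; default 1/3, comparison inclusive.
    nuclear_min_overlap_mL
        Minimum lesion overlap (mL) for a nuclear deduction. Default 0:
        any lesion voxel deducts.
    """

    cortical_fraction_threshold: float = 1.0 / 3.0
    nuclear_min_overlap_mL: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cortical_fraction_threshold <= 1.0):
            raise ScoringError("cortical_fraction_threshold must be in (0, 1]")
        if self.nuclear_min_overlap_mL < 0:
            raise ScoringError("nuclear_min_overlap_mL must be >= 0")


@dataclass(frozen=True)
class RegionOverlap:
    region: AspectsRegion
    lesion_voxels: int
    region_voxels: int
    lesion_mL: float

    def __post_init__(self) -> None:
        if not (0 <= self.lesion_voxels <= self.region_voxels):
            raise ScoringError("lesion_voxels must lie in [0, region_voxels]")

    @property
    def fraction(self) -> float:
        return self.lesion_voxels / self.region_voxels


@dataclass
class AspectsResult:
    overlaps: list[RegionOverlap]
    deductions: set[tuple[str, str]]
    score_left: int
    score_right: int
    reported_score: int
    reported_hemisphere: str  # left | right | bilateral | none
    core_volume_mL: float
    native_volume_mL: float | None = None
    rules: DeductionRules = field(default_factory=DeductionRules)

    def overlap(self, code: str, hemisphere: str) -> RegionOverlap:
        for o in self.overlaps:
            if o.region.key == (code, hemisphere):
                return o
        raise KeyError((code, hemisphere))

    def to_dict(self) -> dict:
        return {
            "overlaps": [
                {
                    "code": o.region.code,
                    "hemisphere": o.region.hemisphere,
                    "lesion_voxels": o.lesion_voxels,
                    "region_voxels": o.region_voxels,
                    "fraction": o.fraction,
                    "lesion_mL": o.lesion_mL,
                }
                for o in self.overlaps
            ],
            "deductions": sorted(self.deductions),
            "score_left": self.score_left,
            "score_right": self.score_right,
            "reported_score": self.reported_score,
            "reported_hemisphere": self.reported_hemisphere,
            "core_volume_mL": self.core_volume_mL,
            "native_volume_mL": self.native_volume_mL,
            "rules": {
                "cortical_fraction_threshold": self.rules.cortical_fraction_threshold,
                "nuclear_min_overlap_mL": self.rules.nuclear_min_overlap_mL,
            },
        }


def _check_binary(mask: LabeledVolume) -> None:
    if not mask.is_binary():
        raise ScoringError("lesion mask must be binary {0,1}")


def compute_region_overlaps(
    lesion: LabeledVolume, atlas: AspectsAtlas
) -> list[RegionOverlap]:
    """Per-region lesion/region voxel overlap on the atlas grid.

    The lesion must already live on the atlas grid (same shape and affine);
    callers holding native-space masks should go through
    ``registration.transform_mask`` first.
    """
    _check_binary(lesion)
    if not lesion.same_grid(atlas.labels):
        raise ScoringError(
            "lesion and atlas grids differ; transform the mask to template "
            "space first (registration.transform_mask)"
        )
    lab = atlas.labels.data.astype(np.int64)
    counts_all = np.bincount(lab.ravel(), minlength=21)
    counts_lesion = np.bincount(lab.ravel(), weights=(lesion.data > 0).ravel(),
                                minlength=21)
    vv = atlas.labels.voxel_volume_mm3
    return [
        RegionOverlap(
            region=r,
            lesion_voxels=int(counts_lesion[r.label]),
            region_voxels=int(counts_all[r.label]),
            lesion_mL=float(counts_lesion[r.label]) * vv / 1000.0,
        )
        for r in atlas.regions
    ]


def score_aspects(
    overlaps: list[RegionOverlap], rules: DeductionRules | None = None
) -> AspectsResult:
    """Apply the deduction rules to 20 region overlaps."""
    rules = rules or DeductionRules()
    keys = [o.region.key for o in overlaps]
    expected = {(c, h) for c in CODES for h in HEMISPHERES}
    if len(keys) != 20 or set(keys) != expected:
        raise ScoringError("expected exactly one overlap per (code, hemisphere)")

    deductions: set[tuple[str, str]] = set()
    for o in overlaps:
        if o.region.kind == "nuclear":
            if o.lesion_voxels >= 1 and o.lesion_mL > rules.nuclear_min_overlap_mL:
                deductions.add(o.region.key)
        else:
            if o.fraction >= rules.cortical_fraction_threshold:
                deductions.add(o.region.key)

    score = {
        h: 10 - sum(1 for (c, hh) in deductions if hh == h) for h in HEMISPHERES
    }
    lesion_in = {
        h: any(o.lesion_voxels > 0 for o in overlaps if o.region.hemisphere == h)
        for h in HEMISPHERES
    }
    if lesion_in["left"] and lesion_in["right"]:
        hemi = "bilateral"
        reported = min(score.values())
    elif lesion_in["left"]:
        hemi, reported = "left", score["left"]
    elif lesion_in["right"]:
        hemi, reported = "right", score["right"]
    else:
        hemi, reported = "none", 10

    vv_mL = sum(o.lesion_mL for o in overlaps)
    return AspectsResult(
        overlaps=list(overlaps),
        deductions=deductions,
        score_left=score["left"],
        score_right=score["right"],
        reported_score=reported,
        reported_hemisphere=hemi,
        core_volume_mL=vv_mL,
        rules=rules,
    )


def core_volume(lesion: LabeledVolume) -> float:
    """Infarct core volume in mL: foreground voxels x voxel volume / 1000."""
    _check_binary(lesion)
    n = int(np.count_nonzero(lesion.data))
    return n * lesion.voxel_volume_mm3 / 1000.0


def score_mask(
    lesion: LabeledVolume,
    atlas: AspectsAtlas,
    rules: DeductionRules | None = None,
    native_lesion: LabeledVolume | None = None,
) -> AspectsResult:
    """Convenience: overlaps + scoring + core volume in one call.

    ``core_volume_mL`` is measured on the template-space mask; when the
    original native-space mask is supplied its volume is reported alongside
    (affine registration changes volume, so both are of interest).
    """
    result = score_aspects(compute_region_overlaps(lesion, atlas), rules)
    result.core_volume_mL = core_volume(lesion)
    if native_lesion is not None:
        result.native_volume_mL = core_volume(native_lesion)
    return result


def classify_severity_imaging(
    result: AspectsResult,
    aspects_cutoff: int = 6,
    volume_cutoff_mL: float = 27.86,
) -> tuple[str, str]:
    """Imaging-marker severity flags (ASPECTS marker, volume marker).

    A score at or below the ASPECTS cutoff, or a core volume at or above
    the volume cutoff, flags moderate-severe; both comparisons inclusive.
    Defaults are the ROC/Youden operating points for separating mild from
    moderate-severe MCA stroke: score <= 6 and volume >= 27.86 mL.
    """
    aspects_flag = ("moderate_severe" if result.reported_score <= aspects_cutoff
                    else "mild")
    volume_flag = ("moderate_severe" if result.core_volume_mL >= volume_cutoff_mL
                   else "mild")
    return aspects_flag, volume_flag
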