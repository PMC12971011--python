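"""The 20-region ASPECTS atlas: representation, validation, synthesis.

An ASPECTS atlas is an integer label volume over the template grid plus a
region table. The ten region codes are the four deep ("nuclear") structures
— caudate (CA), lentiform nucleus (LE), internal capsule (IC), insular
ribbon (IN) — and the six MCA cortical territories M1..M6, each present
once per hemisphere. The hemisphere of a voxel is defined by its atlas
label, never by a runtime mid-plane split: scoring happens in template
space where the atlas is authoritative.

Label numbering is fixed: left hemisphere 1-10, right 11-20, in the code
order CA, LE, IC, IN, M1, M2, M3, M4, M5, M6.

Because the hand-drawn ICBM-space template used in clinical work is not
redistributable, :func:`build_synthetic_atlas` provides a geometric
stand-in: an ellipsoidal brain split at the mid-sagittal plane, each
hemisphere tiled into 10 disjoint connected regions on two axial bands
mirroring the ganglionic / supraganglionic levels of ASPECTS reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import LabeledVolume, read_volume, write_volume

NUCLEAR_CODES = ("CA", "LE", "IC", "IN")
CORTICAL_CODES = ("M1", "M2", "M3", "M4", "M5", "M6")
CODES = NUCLEAR_CODES + CORTICAL_CODES
HEMISPHERES = ("left", "right")


class AtlasError(ValueError):
    """Raised on atlas consistency violations."""


@dataclass(frozen=True)
class AspectsRegion:
    code: str
    hemisphere: str
    label: int

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise AtlasError(f"unknown ASPECTS code {self.code!r}")
        if self.hemisphere not in HEMISPHERES:
            raise AtlasError(f"unknown hemisphere {self.hemisphere!r}")
        if self.label <= 0:
            raise AtlasError("region labels must be positive integers")

    @property
    def kind(self) -> str:
        """'nuclear' for CA/LE/IC/IN, 'cortical' for M1..M6."""
        return "nuclear" if self.code in NUCLEAR_CODES else "cortical"

    @property
    def key(self) -> tuple[str, str]:
        return (self.code, self.hemisphere)


def standard_label(code: str, hemisphere: str) -> int:
    """The package's fixed label convention (left 1-10, right 11-20)."""
    base = CODES.index(code) + 1
    return base if hemisphere == "left" else base + 10


@dataclass
class AspectsAtlas:
    """Integer label volume + region table (+ optional registration template)."""

    labels: LabeledVolume
    regions: list[AspectsRegion]
    template: LabeledVolume | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        keys = [r.key for r in self.regions]
        if len(set(keys)) != len(keys):
            raise AtlasError("duplicate (code, hemisphere) in region table")
        if set(keys) != {(c, h) for c in CODES for h in HEMISPHERES}:
            missing = {(c, h) for c in CODES for h in HEMISPHERES} - set(keys)
            raise AtlasError(f"atlas must contain exactly 20 regions; missing {sorted(missing)}")
        table_labels = {r.label for r in self.regions}
        if len(table_labels) != 20:
            raise AtlasError("region labels must be unique")
        volume_labels = set(np.unique(self.labels.data)) - {0}
        if volume_labels != table_labels:
            raise AtlasError(
                "label volume and region table disagree: "
                f"volume-only={sorted(volume_labels - table_labels)}, "
                f"table-only={sorted(table_labels - volume_labels)}"
            )
        counts = np.bincount(self.labels.data.ravel().astype(np.int64))
        for r in self.regions:
            if counts[r.label] < 1:
                raise AtlasError(f"region {r.key} has no voxels")

    @property
    def by_key(self) -> dict[tuple[str, str], AspectsRegion]:
        return {r.key: r for r in self.regions}

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels.data > 0

    def region_mask(self, code: str, hemisphere: str) -> np.ndarray:
        return self.labels.data == self.by_key[(code, hemisphere)].label

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        labels = [r.label for r in self.regions if r.hemisphere == hemisphere]
        return np.isin(self.labels.data, labels)


def region_volumes(atlas: AspectsAtlas) -> dict[tuple[str, str], float]:
    """Per-region volumes in mL (voxel count x voxel volume / 1000)."""
    counts = np.bincount(atlas.labels.data.ravel().astype(np.int64))
    vv = atlas.labels.voxel_volume_mm3
    return {
        r.key: counts[r.label] * vv / 1000.0
        for r in atlas.regions
    }


def region_voxel_counts(atlas: AspectsAtlas) -> dict[tuple[str, str], int]:
    counts = np.bincount(atlas.labels.data.ravel().astype(np.int64))
    return {r.key: int(counts[r.label]) for r in atlas.regions}


# ---------------------------------------------------------------------------
# persistence

def save_atlas(atlas: AspectsAtlas, label_path: str | Path, table_path: str | Path,
               template_path: str | Path | None = None) -> None:
    write_volume(atlas.labels, label_path)
    pd.DataFrame(
        [{"label": r.label, "code": r.code, "hemisphere": r.hemisphere}
         for r in sorted(atlas.regions, key=lambda r: r.label)]
    ).to_csv(table_path, index=False)
    if template_path is not None and atlas.template is not None:
        write_volume(atlas.template, template_path)


def load_atlas(label_path: str | Path, table_path: str | Path,
               template_path: str | Path | None = None) -> AspectsAtlas:
    """Load and validate an atlas from a NIfTI label map and a CSV table.

    The CSV must have columns ``label,code,hemisphere``; region kind is
    derived from the code. Any mismatch between the table and the labels
    present in the volume is a consistency error.
    """
    labels = read_volume(label_path)
    labels.data = np.rint(labels.data).astype(np.int32)
    table = pd.read_csv(table_path)
    required = {"label", "code", "hemisphere"}
    if not required.issubset(table.columns):
        raise AtlasError(f"region table needs columns {sorted(required)}")
    regions = [
        AspectsRegion(code=str(row.code), hemisphere=str(row.hemisphere), label=int(row.label))
        for row in table.itertuples()
    ]
    template = read_volume(template_path) if template_path is not None else None
    return AspectsAtlas(labels=labels, regions=regions, template=template)


# ---------------------------------------------------------------------------
# synthetic atlas

def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray,
               semi_axes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d <= 1.0


def build_synthetic_atlas(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    min_region_voxels: int = 8,
    with_template: bool = True,
) -> AspectsAtlas:
    """Build a deterministic geometric ASPECTS atlas for testing.

    The brain is an axis-aligned ellipsoid; the mid-sagittal plane splits
    it into hemispheres; a z-plane splits each hemisphere into a lower
    (ganglionic) and an upper (supraganglionic) band. The lower band holds
    a central nuclear block partitioned into CA/LE/IC/IN quadrants and a
    cortical remainder partitioned into M1-M3 anterior-posterior thirds;
    the upper band is partitioned into M4-M6 thirds. The seed jitters band
    positions slightly (identically in both hemispheres, so mirrored
    regions stay near-symmetric).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise AtlasError("synthetic atlas needs shape >= 32 per axis")
    rng = np.random.default_rng(seed)
    affine = np.diag([*spacing, 1.0]).astype(float)
    # center the world origin on the mid-sagittal plane for readability
    affine[:3, 3] = -np.asarray(shape) * np.asarray(spacing) / 2.0

    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.asarray([0.42, 0.46, 0.42])
    brain = _ellipsoid(shape, center, semi)

    jitter = rng.uniform(-0.02, 0.02, size=2)  # band / nucleus placement
    z_split = center[2] + jitter[0] * shape[2]
    zz = np.arange(shape[2])[None, None, :] * np.ones(shape)
    lower_band = zz <= z_split
    xx = np.arange(shape[0])[:, None, None] * np.ones(shape)
    yy = np.arange(shape[1])[None, :, None] * np.ones(shape)

    labels = np.zeros(shape, dtype=np.int32)
    for hemi, hemi_mask in (
        ("left", brain & (xx < center[0])),
        ("right", brain & (xx >= center[0])),
    ):
        hemi_center_x = center[0] + (-0.45 if hemi == "left" else 0.45) * semi[0]
        # nuclear block: ellipsoid near the deep part of the lower band
        nuc_center = np.array([
            hemi_center_x * 0.55 + center[0] * 0.45,  # pulled toward midline
            center[1] + jitter[1] * shape[1],
            z_split - 0.22 * semi[2],
        ])
        nuc_semi = semi * np.array([0.30, 0.38, 0.30])
        nuclear = _ellipsoid(shape, nuc_center, nuc_semi) & hemi_mask & lower_band
        quads = {
            "CA": (yy >= nuc_center[1]) & (zz >= nuc_center[2]),
            "LE": (yy < nuc_center[1]) & (zz >= nuc_center[2]),
            "IC": (yy >= nuc_center[1]) & (zz < nuc_center[2]),
            "IN": (yy < nuc_center[1]) & (zz < nuc_center[2]),
        }
        for code, quad in quads.items():
            labels[nuclear & quad] = standard_label(code, hemi)

        cortical_lower = hemi_mask & lower_band & ~nuclear
        cortical_upper = hemi_mask & ~lower_band
        for band_mask, codes in ((cortical_lower, ("M1", "M2", "M3")),
                                 (cortical_upper, ("M4", "M5", "M6"))):
            ys = yy[band_mask]
            lo, hi = ys.min(), ys.max()
            cuts = [lo - 0.5, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3, hi + 0.5]
            for code, a, b in zip(codes, cuts[:-1], cuts[1:]):
                labels[band_mask & (yy > a) & (yy <= b)] = standard_label(code, hemi)

    regions = [
        AspectsRegion(code=c, hemisphere=h, label=standard_label(c, h))
        for h in HEMISPHERES for c in CODES
    ]
    counts = np.bincount(labels.ravel(), minlength=21)
    small = [r.key for r in regions if counts[r.label] < min_region_voxels]
    if small:
        raise AtlasError(f"shape {shape} too small: regions {small} have < "
                         f"{min_region_voxels} voxels")

    label_vol = LabeledVolume(labels, affine)
    template = _synthetic_template(label_vol, brain, rng) if with_template else None
    return AspectsAtlas(labels=label_vol, regions=regions, template=template)


def _synthetic_template(labels: LabeledVolume, brain: np.ndarray,
                        rng: np.random.Generator) -> LabeledVolume:
    """T1-like template image: tissue contrast + smooth gradient, lightly blurred.

    Gives the registration metric structured intensity to lock onto.
    """
    data = np.zeros(labels.shape, dtype=np.float32)
    data[brain] = 80.0
    nuclear = np.isin(labels.data, [standard_label(c, h)
                                    for c in NUCLEAR_CODES for h in HEMISPHERES])
    data[nuclear] = 120.0
    gx, gy, gz = np.meshgrid(*[np.linspace(-1, 1, s) for s in labels.shape],
                             indexing="ij")
    data += brain * 15.0 * (gy + 0.5 * gz)
    data = ndimage.gaussian_filter(data, sigma=1.0)
    return LabeledVolume(data, labels.affine.copy())
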