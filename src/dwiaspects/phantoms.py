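"""Synthetic DWI-like phantoms and severity-structured cohorts.

Two generators:

* :func:`generate_phantom` — a single subject whose lesion achieves exact
  requested per-region coverage fractions (to one voxel of rounding). Used
  to exercise the deduction rules at constructed operating points such as
  0.30 / exactly 1/3 / 0.40 cortical coverage.

* :func:`generate_cohort` — subjects whose lesion topography and size are
  drawn from severity-conditional distributions emulating the clinical
  structure of MCA stroke: mild cases are small lesions seeded in the deep
  nuclear regions (caudate most often) with little cortical spread;
  moderate cases add cortical territories, weighted toward M2/M5; severe
  cases show multi-territory cortical involvement with large volumes.
  NIHSS is sampled uniformly within the class band (mild 0-7, moderate
  8-16, severe 17-42) — only the band structure is consumed downstream.

Lesion shapes are seeded random connected growths (randomised Prim
expansion over the voxel lattice), clipped to the target region for
exact-fraction phantoms and allowed to spill across adjacent territory in
cohort mode. Phantom images are brain background + hyperintense lesion +
Gaussian noise; they emulate skull-stripped DWI contrast, not DWI physics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas import AspectsAtlas, CORTICAL_CODES, NUCLEAR_CODES
from .volume_io import LabeledVolume, write_volume

SEVERITIES = ("mild", "moderate", "severe")
NIHSS_BANDS = {"mild": (0, 7), "moderate": (8, 16), "severe": (17, 42)}


class PhantomError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Recipe for a single exact-fraction phantom."""

    target_fractions: dict[tuple[str, str], float]
    intensity_contrast: float = 2.5   # lesion/background mean ratio (DWI hyperintensity)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, f in self.target_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise PhantomError(f"fraction for {key} must lie in [0,1], got {f}")
        if self.intensity_contrast <= 1.0:
            raise PhantomError("intensity_contrast must exceed 1 (hyperintense lesion)")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    volume: LabeledVolume | None
    truth_mask: LabeledVolume
    nihss: int | None = None
    severity: str | None = None
    hemisphere: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.nihss is not None:
            lo, hi = 0, 42
            if not (lo <= self.nihss <= hi):
                raise PhantomError("NIHSS must lie in [0, 42]")
            if self.severity is not None:
                blo, bhi = NIHSS_BANDS[self.severity]
                if not (blo <= self.nihss <= bhi):
                    raise PhantomError(
                        f"NIHSS {self.nihss} outside {self.severity} band {NIHSS_BANDS[self.severity]}"
                    )


@dataclass
class EffectModel:
    """Severity-conditional lesion model for cohort generation.

    Volumes are log-normal per class; the medians (4 / 30 / 80 mL) straddle
    the clinically used 27.86 mL operating point so threshold-recovery
    analyses are informative. Cortical inclusion probabilities encode the
    qualitative topography gradient: nuclear-dominant mild disease,
    M2/M5-weighted moderate disease, multi-territory severe disease.
    """

    volume_median_mL: dict[str, float] = field(
        default_factory=lambda: {"mild": 4.0, "moderate": 30.0, "severe": 80.0})
    volume_sigma_log: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.6, "moderate": 0.5, "severe": 0.4})
    # probability that each nuclear region is part of the allowed lesion extent
    nuclear_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "mild": {"CA": 0.9, "LE": 0.15, "IC": 0.1, "IN": 0.2},
        "moderate": {"CA": 0.45, "LE": 0.45, "IC": 0.35, "IN": 0.55},
        "severe": {"CA": 0.6, "LE": 0.6, "IC": 0.6, "IN": 0.8},
    })
    cortical_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "mild": {c: 0.03 for c in CORTICAL_CODES},
        "moderate": {"M1": 0.25, "M2": 0.7, "M3": 0.35, "M4": 0.25, "M5": 0.7, "M6": 0.25},
        "severe": {c: 0.85 for c in CORTICAL_CODES},
    })
    # class from which the growth seed voxel is drawn
    start_kind: dict[str, str] = field(default_factory=lambda: {
        "mild": "nuclear", "moderate": "any", "severe": "cortical"})

    def volume_dist(self, severity: str) -> stats.rv_continuous:
        s = self.volume_sigma_log[severity]
        return stats.lognorm(s=s, scale=self.volume_median_mL[severity])


def analytic_volume_threshold(
    effect_model: EffectModel,
    severity_mix: tuple[float, float, float],
    grid_mL: np.ndarray | None = None,
) -> float:
    """Population Youden threshold of core volume for mild vs moderate-severe.

    Maximises J(t) = P(V >= t | moderate-severe) - P(V >= t | mild) over a
    fine grid; this is the designed density-crossing point the sampled
    Youden threshold should converge to.
    """
    p_mild, p_mod, p_sev = severity_mix
    if p_mod + p_sev <= 0 or p_mild <= 0:
        raise PhantomError("severity_mix must include mild and moderate/severe mass")
    if grid_mL is None:
        grid_mL = np.linspace(0.2, 200.0, 20000)
    sf_mild = effect_model.volume_dist("mild").sf(grid_mL)
    w_mod = p_mod / (p_mod + p_sev)
    sf_ms = (w_mod * effect_model.volume_dist("moderate").sf(grid_mL)
             + (1 - w_mod) * effect_model.volume_dist("severe").sf(grid_mL))
    j = sf_ms - sf_mild
    return float(grid_mL[int(np.argmax(j))])


# ---------------------------------------------------------------------------
# random connected growth

_OFFSETS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_blob(allowed: np.ndarray, n_target: int, rng: np.random.Generator,
               start: tuple[int, int, int] | None = None) -> np.ndarray:
    """Grow a random connected voxel set of exactly min(n_target, |allowed|).

    Randomised Prim expansion: neighbours enter a priority queue with
    uniform random keys, producing compact-ish, connected, irregular blobs.
    If growth exhausts a connected component before reaching the target, it
    restarts from another allowed voxel (the result may then have several
    components, each connected).
    """
    shape = allowed.shape
    avail = int(np.count_nonzero(allowed))
    n_target = min(n_target, avail)
    grown = np.zeros(shape, dtype=bool)
    if n_target == 0:
        return grown

    allowed_idx = np.argwhere(allowed)
    in_heap = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []

    def push(v):
        if allowed[v] and not grown[v] and not in_heap[v]:
            in_heap[v] = True
            heapq.heappush(heap, (rng.random(), *v))

    if start is None:
        start = tuple(allowed_idx[rng.integers(len(allowed_idx))])
    push(tuple(start))
    count = 0
    while count < n_target:
        if not heap:
            remaining = np.argwhere(allowed & ~grown)
            push(tuple(remaining[rng.integers(len(remaining))]))
        _, i, j, k = heapq.heappop(heap)
        if grown[i, j, k]:
            continue
        grown[i, j, k] = True
        count += 1
        for di, dj, dk in _OFFSETS:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                push((ni, nj, nk))
    return grown


def _render_image(atlas: AspectsAtlas, mask: np.ndarray, contrast: float,
                  noise_sd: float, rng: np.random.Generator) -> LabeledVolume:
    background = 100.0
    data = np.zeros(atlas.labels.shape, dtype=np.float32)
    data[atlas.brain_mask] = background
    data[mask] = background * contrast
    data = ndimage.gaussian_filter(data, sigma=0.6)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    return LabeledVolume(data, atlas.labels.affine.copy())


def generate_phantom(atlas: AspectsAtlas, spec: PhantomSpec,
                     with_image: bool = True) -> SyntheticSubject:
    """Phantom whose lesion hits each requested per-region fraction exactly.

    The realised per-region voxel count is ceil(fraction x region size),
    i.e. within one voxel quantum of the request; fractions of 0 leave a
    region untouched, 1.0 fills it completely.
    """
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros(atlas.labels.shape, dtype=bool)
    hemis = set()
    for (code, hemi), f in sorted(spec.target_fractions.items()):
        if f == 0:
            continue
        region = atlas.region_mask(code, hemi)
        n_region = int(np.count_nonzero(region))
        n_target = int(np.ceil(f * n_region))
        if n_target > n_region:
            raise PhantomError(f"fraction {f} unreachable in region {(code, hemi)}")
        mask |= _grow_blob(region, n_target, rng)
        hemis.add(hemi)
    truth = LabeledVolume(mask.astype(np.uint8), atlas.labels.affine.copy())
    image = (_render_image(atlas, mask, spec.intensity_contrast, spec.noise_sd, rng)
             if with_image else None)
    hemisphere = hemis.pop() if len(hemis) == 1 else ("bilateral" if hemis else None)
    return SyntheticSubject(volume=image, truth_mask=truth, hemisphere=hemisphere)


def _sample_allowed_regions(atlas: AspectsAtlas, severity: str, hemisphere: str,
                            model: EffectModel, rng: np.random.Generator
                            ) -> tuple[np.ndarray, tuple[int, int, int]]:
    chosen: list[str] = []
    for code in NUCLEAR_CODES:
        if rng.random() < model.nuclear_probs[severity][code]:
            chosen.append(code)
    for code in CORTICAL_CODES:
        if rng.random() < model.cortical_probs[severity][code]:
            chosen.append(code)
    kind = model.start_kind[severity]
    pool = [c for c in chosen if
            (kind == "any")
            or (kind == "nuclear" and c in NUCLEAR_CODES)
            or (kind == "cortical" and c in CORTICAL_CODES)]
    if not pool:
        pool = chosen or (["CA"] if kind != "cortical" else ["M2"])
        chosen = chosen or pool
    start_code = pool[rng.integers(len(pool))]
    allowed = np.zeros(atlas.labels.shape, dtype=bool)
    for code in set(chosen):
        allowed |= atlas.region_mask(code, hemisphere)
    start_region = np.argwhere(atlas.region_mask(start_code, hemisphere))
    start = tuple(start_region[rng.integers(len(start_region))])
    return allowed, start


def generate_cohort(
    atlas: AspectsAtlas,
    n: int,
    severity_mix: tuple[float, float, float] = (0.64, 0.26, 0.10),
    effect_model: EffectModel | None = None,
    seed: int = 0,
    with_images: bool = False,
) -> list[SyntheticSubject]:
    """Generate a severity-structured cohort of ``n`` synthetic subjects.

    The default severity mix (0.64/0.26/0.10) follows the observed clinical
    prevalence of mild/moderate/severe MCA stroke (390/158/60 of 608).
    Lesion growth is allowed to spill into the rest of the hemisphere when
    the sampled volume exceeds the sampled territory set — large infarcts
    are not territory-bounded. Deterministic for a fixed seed.

    Images are rendered only on request (cohort analyses consume masks).
    """
    if n <= 0:
        raise PhantomError("cohort size must be positive")
    mix = np.asarray(severity_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise PhantomError("severity_mix must be non-negative and sum to 1")
    model = effect_model or EffectModel()
    rng = np.random.default_rng(seed)
    vv = atlas.labels.voxel_volume_mm3

    subjects: list[SyntheticSubject] = []
    for i in range(n):
        severity = SEVERITIES[rng.choice(3, p=mix)]
        hemisphere = "left" if rng.random() < 0.5 else "right"
        target_mL = float(model.volume_dist(severity).rvs(random_state=rng))
        n_target = max(1, int(round(target_mL * 1000.0 / vv)))

        allowed, start = _sample_allowed_regions(atlas, severity, hemisphere, model, rng)
        if n_target > np.count_nonzero(allowed):
            allowed = atlas.hemisphere_mask(hemisphere)  # spill beyond sampled set
        mask = _grow_blob(allowed, n_target, rng, start=start)

        lo, hi = NIHSS_BANDS[severity]
        nihss = int(rng.integers(lo, hi + 1))
        truth = LabeledVolume(mask.astype(np.uint8), atlas.labels.affine.copy())
        image = (_render_image(atlas, mask, 2.5, 5.0, rng) if with_images else None)
        subjects.append(SyntheticSubject(
            volume=image, truth_mask=truth, nihss=nihss,
            severity=severity, hemisphere=hemisphere,
            subject_id=f"sub-{i:04d}",
        ))
    return subjects


def write_cohort(subjects: list[SyntheticSubject], outdir: str | Path) -> Path:
    """Write cohort volumes/masks as NIfTI plus a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(subjects):
        sid = s.subject_id or f"sub-{i:04d}"
        mask_path = outdir / f"{sid}_mask.nii.gz"
        write_volume(s.truth_mask, mask_path)
        vol_path = ""
        if s.volume is not None:
            vol_path = str(outdir / f"{sid}_dwi.nii.gz")
            write_volume(s.volume, vol_path)
        rows.append({
            "subject_id": sid, "volume_path": vol_path, "mask_path": str(mask_path),
            "nihss": s.nihss if s.nihss is not None else "",
            "severity": s.severity or "", "hemisphere": s.hemisphere or "",
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
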