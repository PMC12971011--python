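"""Subject-to-template alignment: orientation matching plus four
consecutive registration rounds (rigid, rigid, affine, affine).

The registration contract is the round schedule and its recovery
behaviour; the optimiser and similarity metric are a pluggable backend
(SimpleITK, default Mattes mutual information with multi-resolution
gradient descent — an information-theoretic metric, since the clinical
use registers DWI subjects to a T1 template). Each round initialises from
the previous round's result, so the final transform of the last round is
the composite subject-to-template mapping.

Transforms are stored as 4x4 homogeneous matrices in RAS world
coordinates, mapping *template (fixed) world points to subject (moving)
world points* — the resampling direction. Masks are always transformed
with nearest-neighbour interpolation after registering the underlying
image; the image drives registration, never the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume_io import LabeledVolume, VolumeError

_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])

DEFAULT_SCHEDULE = ("rigid", "rigid", "affine", "affine")


class RegistrationError(RuntimeError):
    """Optimizer divergence; carries per-round metric values."""

    def __init__(self, message: str, round_metrics: list[float] | None = None):
        super().__init__(message)
        self.round_metrics = round_metrics or []


@dataclass
class SpatialTransform:
    """A rigid/affine/composite world-coordinate mapping (RAS, mm)."""

    kind: str
    matrix: np.ndarray
    rounds: list[tuple[str, np.ndarray]] = field(default_factory=list)
    round_metrics: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if self.kind == "rigid":
            r = self.matrix[:3, :3]
            if not (np.allclose(r @ r.T, np.eye(3), atol=1e-6)
                    and abs(np.linalg.det(r) - 1.0) < 1e-6):
                raise ValueError("rigid transform requires an orthonormal, "
                                 "determinant +1 rotation block")

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        return (self.matrix[:3, :3] @ xyz.T).T + self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind="rigid", matrix=np.eye(4))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "rounds": [{"kind": k, "matrix": m.tolist()} for k, m in self.rounds],
            "round_metrics": self.round_metrics,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            matrix=np.asarray(payload["matrix"]),
            rounds=[(r["kind"], np.asarray(r["matrix"])) for r in payload["rounds"]],
            round_metrics=payload.get("round_metrics", []),
        )


# ---------------------------------------------------------------------------
# orientation

def align_orientation(moving: LabeledVolume, fixed: LabeledVolume) -> LabeledVolume:
    """Reindex ``moving``'s array to ``fixed``'s axis code.

    Pure reindexing: the world coordinate of every voxel is unchanged.
    """
    import nibabel as nib

    if moving.affine is None or fixed.affine is None:  # defensive; dataclass enforces
        raise VolumeError("both volumes must carry orientation metadata")
    src = nib.io_orientation(moving.affine)
    dst = nib.io_orientation(fixed.affine)
    ornt = nib.orientations.ornt_transform(src, dst)
    data = nib.orientations.apply_orientation(moving.data, ornt)
    affine = moving.affine @ nib.orientations.inv_ornt_aff(ornt, moving.shape)
    return LabeledVolume(data, affine)


# ---------------------------------------------------------------------------
# SimpleITK bridge

def _to_sitk(vol: LabeledVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.astype(np.float32).transpose(2, 1, 0)))
    lps = _RAS2LPS @ vol.affine
    spacing = np.linalg.norm(lps[:3, :3], axis=0)
    direction = lps[:3, :3] / spacing
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(lps[:3, 3]))
    img.SetDirection(tuple(direction.ravel()))
    return img


def _sitk_transform_to_matrix(t: sitk.Transform) -> np.ndarray:
    """ITK transform -> 4x4 RAS world matrix (fixed-world -> moving-world)."""
    t = sitk.AffineTransform(sitk.CompositeTransform(t).GetBackTransform()) \
        if isinstance(t, sitk.CompositeTransform) else t
    a = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(t.GetCenter(), dtype=float)
    tr = np.asarray(t.GetTranslation(), dtype=float)
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = tr + c - a @ c
    return _RAS2LPS @ m @ _RAS2LPS  # LPS -> RAS conjugation


def _matrix_metric(similarity: str):
    def configure(reg: sitk.ImageRegistrationMethod) -> None:
        if similarity == "mattes":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        elif similarity == "mse":
            reg.SetMetricAsMeanSquares()
        elif similarity == "correlation":
            reg.SetMetricAsCorrelation()
        else:
            raise ValueError(f"unknown similarity metric {similarity!r}")
    return configure


def register(
    moving: LabeledVolume,
    fixed: LabeledVolume,
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE,
    similarity: str = "mattes",
    seed: int = 0,
    sampling_fraction: float = 0.3,
    divergence_tolerance: float = 1e-3,
) -> tuple[SpatialTransform, LabeledVolume]:
    """Run the round schedule and return (composite transform, warped image).

    Each round's optimisation initialises from the previous round's
    result; rigid rounds optimise a 6-dof Euler transform, affine rounds a
    full 12-dof transform seeded with the rigid solution. If the final
    similarity is worse than the orientation-aligned starting point beyond
    ``divergence_tolerance``, a :class:`RegistrationError` carrying the
    per-round metric values is raised.
    """
    if any(k not in ("rigid", "affine") for k in schedule):
        raise ValueError("schedule entries must be 'rigid' or 'affine'")
    moving = align_orientation(moving, fixed)
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    configure_metric = _matrix_metric(similarity)

    current: sitk.Transform = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    def evaluate(t: sitk.Transform) -> float:
        reg = sitk.ImageRegistrationMethod()
        configure_metric(reg)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetInitialTransform(t, inPlace=False)
        return float(reg.MetricEvaluate(f_img, m_img))

    initial_metric = evaluate(sitk.Euler3DTransform())
    metrics: list[float] = []
    rounds: list[tuple[str, np.ndarray]] = []

    for i, kind in enumerate(schedule):
        if kind == "rigid":
            init = sitk.Euler3DTransform(current) \
                if current.GetName() == "Euler3DTransform" else None
            if init is None:
                raise RegistrationError(
                    "rigid round scheduled after an affine round", metrics)
        else:
            if current.GetName() == "Euler3DTransform":
                e = sitk.Euler3DTransform(current)
                init = sitk.AffineTransform(3)
                init.SetMatrix(e.GetMatrix())
                init.SetCenter(e.GetCenter())
                init.SetTranslation(e.GetTranslation())
            else:
                init = sitk.AffineTransform(current)

        reg = sitk.ImageRegistrationMethod()
        configure_metric(reg)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed + i)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=120,
            relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SetInitialTransform(init, inPlace=True)
        current = reg.Execute(f_img, m_img)
        metrics.append(evaluate(current))
        rounds.append((kind, _sitk_transform_to_matrix(current)))

    if metrics[-1] > initial_metric + divergence_tolerance:
        raise RegistrationError(
            f"registration diverged: final metric {metrics[-1]:.5f} worse than "
            f"initial {initial_metric:.5f}", metrics)

    composite_kind = "affine" if "affine" in schedule else "rigid"
    transform = SpatialTransform(
        kind=composite_kind,
        matrix=rounds[-1][1],
        rounds=rounds,
        round_metrics=metrics,
    )
    warped = apply_transform(moving, transform, fixed, mode="linear")
    return transform, warped


# ---------------------------------------------------------------------------
# resampling through a world transform

def apply_transform(
    vol: LabeledVolume,
    transform: SpatialTransform | np.ndarray,
    reference: LabeledVolume,
    mode: str = "linear",
) -> LabeledVolume:
    """Resample ``vol`` onto ``reference``'s grid through a world transform.

    The transform maps reference-world points into ``vol``-world points
    (the resampling/pullback direction).
    """
    matrix = transform.matrix if isinstance(transform, SpatialTransform) else np.asarray(transform)
    m = np.linalg.inv(vol.affine) @ matrix @ reference.affine
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in reference.shape], indexing="ij")
    coords = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (m @ coords)[:3]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32 if mode == "linear" else vol.data.dtype),
        src, order=order, mode="constant", cval=0,
    ).reshape(reference.shape)
    if mode == "nearest":
        out = out.astype(vol.data.dtype)
    return LabeledVolume(out, reference.affine.copy())


def transform_mask(
    mask: LabeledVolume,
    transform: SpatialTransform | np.ndarray,
    reference: LabeledVolume,
) -> LabeledVolume:
    """Nearest-neighbour transform of a binary mask onto the reference grid."""
    if not mask.is_binary():
        raise VolumeError("transform_mask requires a binary mask")
    out = apply_transform(mask, transform, reference, mode="nearest")
    out.data = out.data.astype(np.uint8)
    return out


def mean_landmark_error(
    transform: SpatialTransform | np.ndarray,
    expected: np.ndarray,
    landmarks_world: np.ndarray,
) -> float:
    """Mean distance (mm) between the recovered and expected mapping of landmarks."""
    matrix = transform.matrix if isinstance(transform, SpatialTransform) else np.asarray(transform)
    pts = np.atleast_2d(landmarks_world)
    got = (matrix[:3, :3] @ pts.T).T + matrix[:3, 3]
    want = (expected[:3, :3] @ pts.T).T + expected[:3, 3]
    return float(np.linalg.norm(got - want, axis=1).mean())
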