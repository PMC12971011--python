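"""NIfTI volume I/O and the geometric conventions shared by every module.

All volumes are carried as :class:`LabeledVolume`: a 3-D array plus a 4x4
RAS voxel-to-world affine. On load every volume is reoriented to the
canonical RAS axis order (x increasing toward the subject's right, y
anterior, z superior), so downstream hemisphere logic can rely on a single
convention. Voxel indexing is 0-based; voxel volume is dx*dy*dz mm^3 and
millilitres are mm^3 / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for unreadable files, wrong dimensionality or contract breaches."""


@dataclass
class LabeledVolume:
    """A 3-D scalar image or integer label map with world geometry.

    Parameters
    ----------
    data
        3-D array. Images are floats; masks and label maps are
        non-negative integers.
    affine
        4x4 voxel-to-world matrix in RAS millimetre coordinates.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3-D volume, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be a 4x4 matrix")
        if np.any(np.asarray(self.spacing) <= 0):
            raise VolumeError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel edge lengths (dx, dy, dz) in mm, from affine column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))  # type: ignore[return-value]

    @property
    def orientation(self) -> str:
        """Three-letter axis code, e.g. 'RAS'."""
        return "".join(nib.aff2axcodes(self.affine))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def copy_with(self, data: np.ndarray | None = None) -> "LabeledVolume":
        return LabeledVolume(
            data=self.data.copy() if data is None else data,
            affine=self.affine.copy(),
        )

    def same_grid(self, other: "LabeledVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def to_canonical(vol: LabeledVolume) -> LabeledVolume:
    """Reorient to RAS axis order, leaving world coordinates untouched."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    can = nib.as_closest_canonical(img)
    return LabeledVolume(np.asanyarray(can.dataobj), can.affine)


def read_volume(path: str | Path) -> LabeledVolume:
    """Read a NIfTI volume and normalise it to the canonical orientation.

    Raises
    ------
    VolumeError
        If the file cannot be parsed or the payload is not 3-D.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise VolumeError(
            f"{path}: expected a 3-D payload, found {img.ndim}-D "
            "(split 4-D series before scoring)"
        )
    can = nib.as_closest_canonical(img)
    data = np.asanyarray(can.dataobj)
    return LabeledVolume(data=data, affine=can.affine)


def write_volume(vol: LabeledVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    path = Path(path)
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), path)
    return path


def resample_to_grid(
    vol: LabeledVolume, reference: LabeledVolume, mode: str = "linear"
) -> LabeledVolume:
    """Resample ``vol`` onto ``reference``'s grid.

    ``mode='nearest'`` is mandatory for masks and label maps so no new label
    values can be invented; ``mode='linear'`` on an integer volume is a
    contract error.
    """
    if mode not in ("linear", "nearest"):
        raise VolumeError(f"unknown resampling mode {mode!r}")
    integer_payload = np.issubdtype(vol.data.dtype, np.integer) or vol.data.dtype == bool
    if mode == "linear" and integer_payload:
        raise VolumeError("linear resampling of an integer label volume; use mode='nearest'")
    # voxel(ref) -> world -> voxel(vol)
    m = np.linalg.inv(vol.affine) @ reference.affine
    ii, jj, kk = np.meshgrid(
        np.arange(reference.shape[0]),
        np.arange(reference.shape[1]),
        np.arange(reference.shape[2]),
        indexing="ij",
    )
    coords = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (m @ coords)[:3]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32 if mode == "linear" else vol.data.dtype),
        src,
        order=order,
        mode="constant",
        cval=0,
    ).reshape(reference.shape)
    if mode == "nearest":
        out = out.astype(vol.data.dtype)
    return LabeledVolume(out, reference.affine.copy())
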