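"""3-D angiogram volumes and the coordinate conventions used throughout.

Every stage of the planning pipeline works in one fixed anatomical frame:

* ``x`` — left to right (L→R)
* ``y`` — anterior to posterior (A→P)
* ``z`` — feet to head (F→H, inferior→superior)

A :class:`Volume3D` stores its scalar grid in that axis order together with
the voxel spacing in millimetres and the mm coordinate of the centre of
voxel ``(0, 0, 0)``.  NIfTI-1 files are accepted in any axis-aligned
orientation and remapped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "BinaryMask3D",
    "read_volume",
    "write_volume",
    "voxel_to_mm",
    "mm_to_voxel",
    "volume_center_mm",
]

#: axis codes of the in-memory frame, in nibabel's RAS-relative vocabulary:
#: +x = Right, +y = Posterior, +z = Superior.
_AXIS_CODES = ("R", "P", "S")


@dataclass
class Volume3D:
    """Scalar intensity grid with spacing (mm) in the L→R / A→P / F→H frame."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D data")
        if min(self.data.shape) < 8:
            raise ValueError(f"each axis needs >= 8 voxels, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.min(self.data) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask3D:
    """Boolean grid congruent with a parent :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def from_parent(cls, parent: Volume3D, data: np.ndarray) -> "BinaryMask3D":
        data = np.asarray(data, dtype=bool)
        if data.shape != parent.shape:
            raise ValueError(f"mask shape {data.shape} != volume shape {parent.shape}")
        return cls(data=data, spacing=parent.spacing, origin=parent.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _rps_affine(volume: Volume3D) -> np.ndarray:
    """Index→RAS affine for a volume stored in the (R, P, S) frame."""
    dx, dy, dz = volume.spacing
    ox, oy, oz = volume.origin
    # +y in memory points Posterior, i.e. along -y of RAS.
    return np.array(
        [
            [dx, 0.0, 0.0, ox],
            [0.0, -dy, 0.0, -oy],
            [0.0, 0.0, dz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3-D NIfTI-1 image and remap it to the L→R, A→P, F→H frame.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    ValueError
        for non-3-D images or an affine that is not axis-aligned
        (oblique sform/qform), naming the offending header field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape} (header dim)")
    affine = img.affine
    if not np.all(np.isfinite(affine)):
        raise ValueError("unreadable orientation: non-finite sform/qform affine")
    ornt = nib.orientations.io_orientation(affine)
    if np.any(np.isnan(ornt)):
        raise ValueError("ambiguous orientation in sform/qform affine")
    target = nib.orientations.axcodes2ornt(_AXIS_CODES)
    xfm = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), xfm)
    new_affine = affine @ nib.orientations.inv_ornt_aff(xfm, data.shape)
    rot = new_affine[:3, :3]
    diag = np.diag(np.diag(rot))
    if not np.allclose(rot, diag, atol=1e-4 * max(abs(np.diag(rot)))):
        raise ValueError("oblique sform/qform affine not supported (off-diagonal terms)")
    # new_affine maps memory index -> RAS; convert to the RPS frame.
    spacing = (float(rot[0, 0]), float(-rot[1, 1]), float(rot[2, 2]))
    origin = (float(new_affine[0, 3]), float(-new_affine[1, 3]), float(new_affine[2, 3]))
    return Volume3D(data=data, spacing=spacing, origin=origin)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write *volume* as NIfTI-1 preserving grid, spacing, and orientation."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = _rps_affine(volume)
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_qform(affine, code=1)
    img.header.set_sform(affine, code=1)
    nib.save(img, str(path))


def voxel_to_mm(volume: Volume3D, index) -> np.ndarray:
    """mm coordinate of the centre of voxel *index* (0-based triple)."""
    index = np.asarray(index)
    if np.any(index < 0) or np.any(index >= np.array(volume.shape)):
        raise IndexError(f"index {tuple(index)} out of bounds for shape {volume.shape}")
    return np.asarray(volume.origin) + index * np.asarray(volume.spacing)


def mm_to_voxel(volume: Volume3D, mm) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm`, rounded to the nearest voxel."""
    cont = (np.asarray(mm, dtype=float) - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    return np.rint(cont).astype(int)


def volume_center_mm(volume: Volume3D) -> np.ndarray:
    """mm coordinate of the geometric centre of the grid."""
    shape = np.asarray(volume.shape, dtype=float)
    return np.asarray(volume.origin) + (shape - 1) / 2.0 * np.asarray(volume.spacing)
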