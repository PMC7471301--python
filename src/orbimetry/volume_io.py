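"""CT volume and mask I/O, and voxel/world coordinate transforms.

Volumes live on a regular grid described by per-axis spacing (mm), the world
position of the center of voxel (0, 0, 0), and an orthonormal direction matrix
mapping voxel axes to anatomical right/anterior/superior (RAS) axes.  Voxel
indices are 0-based; voxel *centers* define world positions.  The anterior
axis is the one along which proptosis is positive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

_ORTHO_TOL = 1e-6


def _validate_geometry(shape, spacing, origin, direction):
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("volume grid must be 3-D with at least 1 voxel per axis")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be 3 positive components (mm)")
    origin = np.asarray(origin, dtype=float)
    if origin.shape != (3,):
        raise ValueError("origin must be a 3-vector (mm)")
    direction = np.asarray(direction, dtype=float)
    if direction.shape != (3, 3):
        raise ValueError("direction must be a 3x3 matrix")
    if not np.allclose(direction @ direction.T, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError("direction matrix is not orthonormal")
    det = np.linalg.det(direction)
    if not (abs(abs(det) - 1.0) < 1e-6):
        raise ValueError("direction matrix determinant must be +/-1")
    return spacing, origin, direction


@dataclass
class CTVolume:
    """A 3-D scalar attenuation grid (Hounsfield units) with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Attenuation values in HU.
    spacing : array-like of 3 floats
        Voxel size along each grid axis, mm, all > 0.
    origin : array-like of 3 floats
        World (RAS, mm) position of the center of voxel (0, 0, 0).
    direction : (3, 3) array-like
        Orthonormal map from voxel axes to world axes.  Identity means grid
        axis 0 is right, axis 1 anterior, axis 2 superior.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        self.spacing, self.origin, self.direction = _validate_geometry(
            self.data.shape, self.spacing, self.origin, self.direction
        )

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine, voxel-center convention."""
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def voxel_to_world(self, index) -> np.ndarray:
        """Map (fractional) voxel indices to world mm, shape (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_voxel(self, point) -> np.ndarray:
        """Exact inverse of :meth:`voxel_to_world`; returns fractional indices."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    def same_geometry(self, other, atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class BinaryMask(CTVolume):
    """An eyeball segmentation on the identical grid as its parent volume.

    Values are {0, 1} stored as uint8; all geometry fields must equal the
    parent volume's.
    """

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    @classmethod
    def from_volume(cls, volume: CTVolume, values: np.ndarray) -> "BinaryMask":
        """Wrap a {0,1} array on the geometry of ``volume``."""
        return cls(
            data=values,
            spacing=volume.spacing.copy(),
            origin=volume.origin.copy(),
            direction=volume.direction.copy(),
        )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# -- NIfTI ---------------------------------------------------------------


def _from_nifti(img) -> CTVolume:
    import nibabel as nib  # noqa: F401  (kept local: optional at import time)

    A = np.asarray(img.affine, dtype=float)
    M = A[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("non-positive voxel spacing in NIfTI affine")
    direction = M / spacing
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-4):
        raise ValueError(
            "non-orthogonal orientation in NIfTI affine (srow/qform): "
            "sheared grids are not supported"
        )
    # re-orthonormalize to clean up float32 header noise
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    data = np.asanyarray(img.dataobj)
    return CTVolume(data=data, spacing=spacing, origin=A[:3, 3], direction=direction)


def _read_nifti(path: str) -> CTVolume:
    import nibabel as nib

    return _from_nifti(nib.load(path))


def write_volume(volume: CTVolume, path: str) -> None:
    """Write a volume (or mask) to NIfTI-1, preserving geometry exactly."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, path)


# -- DICOM series --------------------------------------------------------


def _read_dicom_series(path: str) -> CTVolume:
    """Read one axial DICOM series from a directory.

    Slices are sorted along the slice normal (cross product of the in-plane
    image-orientation vectors); a gap or irregularity in slice positions of
    more than 1% of the median spacing is rejected.
    """
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise FileNotFoundError(f"no DICOM slices with ImagePositionPatient under {path}")

    iop = np.array(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    if abs(row_dir @ col_dir) > 1e-4:
        raise ValueError(
            "non-orthogonal orientation: ImageOrientationPatient row and "
            "column vectors are not perpendicular"
        )
    normal = np.cross(row_dir, col_dir)

    slices.sort(key=lambda ds: float(np.array(ds.ImagePositionPatient, float) @ normal))
    positions = np.array([np.array(s.ImagePositionPatient, float) @ normal for s in slices])
    if len(slices) > 1:
        steps = np.diff(positions)
        med = np.median(steps)
        if med <= 0 or np.any(np.abs(steps - med) > 0.01 * med):
            raise ValueError(
                "inconsistent slice spacing: gaps in ImagePositionPatient "
                f"(steps range {steps.min():.3f}..{steps.max():.3f} mm)"
            )
        slice_spacing = float(med)
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))

    ps = np.array(slices[0].PixelSpacing, dtype=float)  # (between-rows, between-cols) mm
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))

    # DICOM pixel_array is (row, col); volume index order (col, row, slice)
    # so that axis 0 steps along row_dir, axis 1 along col_dir.
    stack = np.stack([s.pixel_array.T for s in slices], axis=-1).astype(np.float64)
    data = stack * slope + intercept

    # DICOM world frame is LPS; convert direction and origin to RAS.
    lps_to_ras = np.diag([-1.0, -1.0, 1.0])
    direction = lps_to_ras @ np.column_stack([row_dir, col_dir, normal])
    origin = lps_to_ras @ np.array(slices[0].ImagePositionPatient, dtype=float)
    # volume axis 0 steps along row_dir (increasing column index), whose
    # step is the between-columns spacing
    spacing = np.array([ps[1], ps[0], slice_spacing])
    return CTVolume(data=data, spacing=spacing, origin=origin, direction=direction)


def read_volume(path: str, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI (.nii/.nii.gz) or a DICOM series directory.

    Parameters
    ----------
    path : str
        File path (NIfTI) or directory of one DICOM series.
    format : {"nifti", "dicom_series", None}
        Explicit format; inferred from the path when None.
    """
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return _read_nifti(path)
    if format == "dicom_series":
        if not os.path.isdir(path):
            raise FileNotFoundError(f"{path} is not a directory of a DICOM series")
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a {0,1} mask to NIfTI with its parent geometry."""
    write_volume(mask, path)


def read_mask(path: str) -> BinaryMask:
    """Read a NIfTI mask; values are validated to be {0, 1}."""
    vol = _read_nifti(path)
    return BinaryMask.from_volume(vol, np.rint(np.asarray(vol.data)).astype(np.uint8))
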