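"""Volume I/O and the voxel-grid geometry model.

A :class:`Volume` is a rank-3 scalar grid with physical geometry: per-axis
spacing in mm, the mm position of voxel (0, 0, 0), and a 3x3 direction-cosine
matrix whose *columns* are the physical directions of the voxel axes.  Arrays
are indexed ``voxels[x, y, z]``; after canonical alignment +Z points superior,
+Y anterior and +X to the subject's left.

:class:`BinaryVolume` restricts voxel values to {0, 1} (uint8) and is the
currency of the whole pipeline: 1 = bone or implant material, 0 = background.

NRRD files are read and written through SimpleITK (gzip-encoded on write, any
supported encoding on read); DICOM series are read slice-wise with pydicom.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, InputError

__all__ = [
    "Volume",
    "BinaryVolume",
    "read_nrrd",
    "write_nrrd",
    "read_dicom_series",
    "threshold_bone",
    "export_stl",
]

_ORTHO_TOL = 1e-6


def _check_geometry(voxels, spacing, orientation):
    if voxels.ndim != 3:
        raise InputError(f"voxels must be rank-3, got rank {voxels.ndim}")
    if min(voxels.shape) < 1:
        raise InputError(f"all dims must be >= 1, got {voxels.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InputError(f"spacing must be three positive floats, got {spacing}")
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3):
        raise InputError("orientation must be a 3x3 matrix")
    if not np.allclose(orientation @ orientation.T, np.eye(3), atol=1e-5):
        raise InputError("orientation rows must be orthonormal")
    return spacing, orientation


@dataclass
class Volume:
    """Scalar voxel grid with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (X, Y, Z)
        Scalar intensities, any numeric dtype.
    spacing : tuple of float
        mm per voxel along (X, Y, Z); all components > 0.
    origin : tuple of float
        mm offset of voxel (0, 0, 0).
    orientation : ndarray, shape (3, 3)
        Direction-cosine matrix; columns are the voxel-axis directions.
    source_id : str
        Free-text provenance tag.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    source_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing, self.orientation = _check_geometry(
            self.voxels, self.spacing, self.orientation
        )
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def dims(self):
        return self.voxels.shape

    def physical_extent(self):
        """Per-axis physical size in mm (dims x spacing)."""
        return tuple(d * s for d, s in zip(self.voxels.shape, self.spacing))

    def with_voxels(self, voxels):
        """Copy of this volume's geometry around a new voxel grid."""
        return replace(self, voxels=voxels)


@dataclass
class BinaryVolume(Volume):
    """Volume whose voxels are exactly 0 or 1 (stored uint8)."""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise InputError(
                f"BinaryVolume voxels must be 0/1; found values {vals[:8]}"
            )
        self.voxels = self.voxels.astype(np.uint8)
        super().__post_init__()

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


def _from_sitk(img: sitk.Image, source_id: str, binary: bool):
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    orientation = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    cls = BinaryVolume if binary else Volume
    return cls(
        voxels=voxels,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        orientation=orientation,
        source_id=source_id,
    )


def read_nrrd(path, binary: bool = False) -> Volume:
    """Read a 3-D NRRD file.

    Parameters
    ----------
    path : str or Path
        NRRD file (raw or gzip encoded).
    binary : bool
        If True, return a :class:`BinaryVolume` (values must be 0/1).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # unreadable header / truncated payload
        raise FormatError(f"cannot read NRRD {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path}: expected a 3-D payload, got {img.GetDimension()}-D"
        )
    return _from_sitk(img, source_id=os.path.basename(path), binary=binary)


def write_nrrd(vol: Volume, path) -> str:
    """Write a volume as gzip-encoded NRRD; returns the path written."""
    path = os.fspath(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.orientation, dtype=float).ravel()))
    sitk.WriteImage(img, path, useCompression=True)
    return path


def read_dicom_series(directory) -> Volume:
    """Assemble one DICOM series from ``directory`` into a Volume.

    Slices are sorted by their position along the slice normal into ascending
    Z.  Directories holding a single slice are rejected (incomplete imaging
    data); directories mixing several series are a format error listing the
    series identifiers found.
    """
    import pydicom

    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise InputError(f"no such directory: {directory}")
    datasets = []
    for name in sorted(os.listdir(directory)):
        full = os.path.join(directory, name)
        if not os.path.isfile(full):
            continue
        try:
            ds = pydicom.dcmread(full)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise InputError(f"{directory}: no DICOM slices found")
    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise FormatError(
            f"{directory}: multiple series in one directory: {', '.join(uids)}"
        )
    if len(datasets) == 1:
        raise InputError(
            f"{directory}: series has a single slice; single-slice studies are "
            "excluded as incomplete imaging data"
        )

    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    iop = tuple(float(v) for v in first.ImageOrientationPatient)
    pxsp = tuple(float(v) for v in first.PixelSpacing)
    for ds in datasets[1:]:
        same = (
            int(ds.Rows) == rows
            and int(ds.Columns) == cols
            and tuple(float(v) for v in ds.ImageOrientationPatient) == iop
            and tuple(float(v) for v in ds.PixelSpacing) == pxsp
        )
        if not same:
            raise FormatError(f"{directory}: inconsistent slice geometry in series")

    row_dir = np.array(iop[:3])  # direction of increasing column index (x)
    col_dir = np.array(iop[3:])  # direction of increasing row index (y)
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(np.dot(normal, np.asarray(ds.ImagePositionPatient, float))))
    zpos = [float(np.dot(normal, np.asarray(ds.ImagePositionPatient, float))) for ds in datasets]
    dz = np.diff(zpos)
    if np.any(dz <= 0) or (len(dz) > 1 and not np.allclose(dz, dz[0], atol=1e-3)):
        raise FormatError(f"{directory}: non-uniform or duplicate slice positions")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pixel_array is (row=y, col=x); volume is (x, y, z)
    voxels = np.stack([s.T for s in slices], axis=2)
    orientation = np.column_stack([row_dir, col_dir, normal])
    return Volume(
        voxels=voxels,
        spacing=(pxsp[1], pxsp[0], float(dz[0])),
        origin=tuple(float(v) for v in datasets[0].ImagePositionPatient),
        orientation=orientation,
        source_id=f"dicom:{uids[0]}",
    )


def threshold_bone(vol: Volume, lo: float) -> BinaryVolume:
    """Binarize ``vol`` with the inclusive rule voxel = 1 iff intensity >= lo.

    Geometry is carried over unchanged.  The threshold is a configuration
    value: phantom inputs arrive already binary and pass through a threshold
    of 0.5 untouched, while raw CT ingest needs a bone-window value.
    """
    mask = (np.asarray(vol.voxels) >= lo).astype(np.uint8)
    return BinaryVolume(
        voxels=mask,
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
        source_id=vol.source_id,
    )


def export_stl(mask: BinaryVolume, path) -> str:
    """Export the foreground surface as a binary STL mesh (convenience).

    Uses a marching-cubes surface at the 0.5 level, scaled to mm.
    """
    from skimage import measure
    import trimesh

    if mask.count() == 0:
        raise InputError("cannot mesh an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * np.asarray(mask.spacing)
    trimesh.Trimesh(vertices=verts, faces=faces).export(os.fspath(path))
    return os.fspath(path)
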