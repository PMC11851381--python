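"""Preprocessing chain for raw skull volumes.

The chain standardizes heterogeneous CT input into clean, canonically
oriented binary bone masks: bone thresholding (for scalar input), median
denoising, connected-component artefact removal, principal-axes alignment,
and physical-extent-preserving resampling, applied in that order.

Alignment is template-free: the foreground's second-moment principal axes
are mapped onto the canonical frame (+Y = largest-extent axis, +X = middle,
+Z = smallest; head-like shapes are wider front-to-back than tall).
Eigenvector signs are chosen nearest the identity, then flipped by a
third-moment (skewness) heuristic when the mass distribution is clearly
asymmetric.  Shapes with near-degenerate inertia (e.g. spherical shells)
are returned unchanged with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, PipelineError
from .volio import BinaryVolume, Volume, threshold_bone

__all__ = [
    "RigidTransform",
    "PreprocessConfig",
    "median_denoise",
    "remove_artefacts_cca",
    "align_canonical",
    "apply_rigid",
    "resample",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)

#: 26-connectivity structuring element for foreground components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RigidTransform:
    """Physical-space rigid map y = R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise InputError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-5):
            raise InputError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise InputError("rotation must have determinant +1")

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(
            self.translation, 0.0
        )


def median_denoise(vol: Volume, kernel: int = 3) -> Volume:
    """Median filter with a cubic ``kernel`` window and reflected borders.

    The standard remedy for salt-and-pepper noise at minimal blurring; on
    binary masks it acts as a majority vote per neighborhood.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise InputError(f"kernel must be odd and >= 1, got {kernel}")
    out = ndimage.median_filter(vol.voxels, size=kernel, mode="reflect")
    return vol.with_voxels(out.astype(vol.voxels.dtype))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if n <= 1:
        return mask.astype(np.uint8)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) > 1:
        # tie: keep the component containing the smallest linear index
        flat = labels.ravel()
        firsts = {int(lab): int(np.flatnonzero(flat == lab)[0]) for lab in candidates}
        keep = min(firsts, key=firsts.get)
    else:
        keep = int(candidates[0])
    return (labels == keep).astype(np.uint8)


def remove_artefacts_cca(mask: BinaryVolume) -> BinaryVolume:
    """Keep only the largest 26-connected foreground component.

    Support plates, positioning aids and noise specks are disconnected from
    the skull and fall away.  Size ties are broken toward the component
    containing the smallest linear voxel index.
    """
    if mask.count() == 0:
        raise InputError("mask is empty; nothing to analyse")
    return mask.with_voxels(_largest_component(mask.voxels))


def _canonical_rotation(mask: BinaryVolume, degeneracy_rtol: float = 0.02):
    """Principal-axes rotation mapping the mask into the canonical frame.

    Returns None when the inertia spectrum is too degenerate to orient.
    """
    coords = np.argwhere(mask.voxels > 0).astype(float) * np.asarray(mask.spacing)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    spread = evals[-1]
    if spread <= 0 or np.any(np.diff(evals) < degeneracy_rtol * spread):
        return None, centroid
    # canonical destination rows: X <- middle, Y <- largest, Z <- smallest
    axes = [evecs[:, 1], evecs[:, 2], evecs[:, 0]]
    R = np.stack(axes, axis=0)
    # resolve signs: nearest to identity, then enforce det +1
    for i in range(3):
        if R[i, i] < 0:
            R[i] = -R[i]
    if np.linalg.det(R) < 0:
        flip = int(np.argmin(np.abs(np.diag(R))))
        R[flip] = -R[flip]
    # skewness heuristic: superior mass up (+Z), anterior mass forward (+Y);
    # each flip is paired with an X flip to stay a proper rotation
    canon = centered @ R.T
    std = np.maximum(canon.std(axis=0), 1e-9)
    skew = (canon**3).mean(axis=0) / std**3
    for axis in (2, 1):
        if skew[axis] < -0.1:
            R[axis] = -R[axis]
            R[0] = -R[0]
    return R, centroid


def apply_rigid(mask: BinaryVolume, transform: RigidTransform) -> BinaryVolume:
    """Resample ``mask`` under a physical-space rigid transform (nearest
    neighbor), keeping the grid geometry fixed."""
    sp = np.asarray(mask.spacing)
    R, t = transform.rotation, transform.translation
    # out[o] = in[x] with x_mm = R^T (o_mm - t)
    A = np.diag(1.0 / sp) @ R.T @ np.diag(sp)
    b = np.diag(1.0 / sp) @ (R.T @ (-t))
    out = ndimage.affine_transform(
        mask.voxels, A, offset=b, order=0, mode="constant", cval=0,
        output=np.uint8,
    )
    return mask.with_voxels(out)


def align_canonical(mask: BinaryVolume) -> tuple[BinaryVolume, RigidTransform]:
    """Rotate the foreground's principal axes onto the canonical frame.

    Returns the aligned mask (nearest-neighbor resampled on the same grid)
    and the applied physical-space transform.  Degenerate inertia (near-equal
    principal extents) yields the identity transform with a warning.
    """
    if mask.count() == 0:
        raise InputError("mask is empty; cannot align")
    R, centroid = _canonical_rotation(mask)
    if R is None:
        warnings.warn(
            "degenerate principal axes; returning identity alignment", stacklevel=2
        )
        ident = RigidTransform(np.eye(3), np.zeros(3))
        return mask.with_voxels(mask.voxels.copy()), ident
    t = centroid - R @ centroid  # rotate about the foreground centroid
    transform = RigidTransform(R, t)
    return apply_rigid(mask, transform), transform


def resample(vol: Volume, target_dims) -> Volume:
    """Resample to ``target_dims`` preserving the physical extent per axis.

    Scalar volumes are interpolated trilinearly.  Binary masks are resampled
    anti-aliased: trilinear interpolation of the {0,1} field re-thresholded
    at 0.5, which avoids the half-voxel surface bias of pure nearest-neighbor
    picking on thin shells.  Spacing is rescaled so dims x spacing is
    unchanged.
    """
    target_dims = tuple(int(d) for d in target_dims)
    if any(d < 1 for d in target_dims):
        raise InputError(f"target dims must be >= 1, got {target_dims}")
    if target_dims == vol.dims:
        return vol.with_voxels(vol.voxels.copy())
    binary = isinstance(vol, BinaryVolume)
    factor = np.asarray(vol.dims, float) / np.asarray(target_dims, float)
    # voxel-center mapping: in = (out + 0.5) * factor - 0.5
    A = np.diag(factor)
    b = 0.5 * factor - 0.5
    out = ndimage.affine_transform(
        vol.voxels.astype(np.float32),
        A, offset=b, output_shape=target_dims, order=1,
        mode="nearest",
    )
    if binary:
        out = out >= 0.5
    new_spacing = tuple(
        e / d for e, d in zip(vol.physical_extent(), target_dims)
    )
    cls = BinaryVolume if binary else Volume
    return cls(
        voxels=out.astype(np.uint8) if binary else out,
        spacing=new_spacing,
        origin=vol.origin,
        orientation=vol.orientation,
        source_id=vol.source_id,
    )


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing chain.

    ``threshold`` only matters for scalar (raw CT) input; binary input skips
    the thresholding stage.  ``target_dims=None`` skips resampling.
    """

    threshold: float = 300.0
    median_kernel: int = 3
    skip_median: bool = False
    skip_cca: bool = False
    skip_align: bool = False
    target_dims: tuple | None = None
    extra: dict = field(default_factory=dict)


def preprocess_pipeline(raw: Volume, cfg: PreprocessConfig = PreprocessConfig()) -> BinaryVolume:
    """Full chain: threshold -> median -> CCA -> align -> resample.

    Raises :class:`PipelineError` naming the failing stage.
    """
    stage = "threshold"
    try:
        if isinstance(raw, BinaryVolume):
            mask = raw
        else:
            mask = threshold_bone(raw, cfg.threshold)
        if mask.count() == 0:
            raise InputError("bone mask empty after thresholding")
        log.info("preprocess[%s]: %d foreground voxels", stage, mask.count())

        if not cfg.skip_median:
            stage = "median_denoise"
            mask = median_denoise(mask, cfg.median_kernel)
            if mask.count() == 0:
                raise InputError("mask empty after median denoising")
            log.info("preprocess[%s]: %d foreground voxels", stage, mask.count())

        if not cfg.skip_cca:
            stage = "remove_artefacts_cca"
            mask = remove_artefacts_cca(mask)
            log.info("preprocess[%s]: %d foreground voxels", stage, mask.count())

        if not cfg.skip_align:
            stage = "align_canonical"
            mask, _ = align_canonical(mask)
            log.info("preprocess[%s]: %d foreground voxels", stage, mask.count())

        if cfg.target_dims is not None:
            stage = "resample"
            mask = resample(mask, cfg.target_dims)
            log.info("preprocess[%s]: dims=%s", stage, mask.dims)
    except InputError as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return mask
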