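"""Synthetic skull phantoms.

Real cranial CT cohorts are large hollow bone shells with scanner artefacts
(support plates, positioning aids) and salt-and-pepper noise.  This module
generates binary stand-ins with the same gross topology: a hollow closed
ellipsoidal shell of configurable semi-axes and thickness, an optional
disconnected slab artefact, and Bernoulli voxel-flip noise.  Phantoms are
emitted already binarized, matching the entry state of a thresholded skull
database, and are fully determined by their spec (seed included), so any
cohort member can be regenerated in isolation.

The default desk-scale grid is 64x64x32 voxels at 2 mm spacing (physical
extent 128x128x64 mm); full-scale 256x256x128 grids are supported but not
required anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .volio import BinaryVolume

__all__ = ["PhantomSpec", "make_skull_phantom", "add_artefacts", "make_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one skull phantom.

    radii/thickness are in mm; ``base_cut`` removes that fraction of the
    inferior extent (0 keeps the shell closed); ``noise_density`` is the
    per-voxel Bernoulli flip probability.
    """

    dims: tuple = (64, 64, 32)
    spacing: tuple = (2.0, 2.0, 2.0)
    radii: tuple = (42.0, 52.0, 26.0)
    thickness: float = 5.0
    base_cut: float = 0.0
    artefact_plate: bool = False
    noise_density: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.thickness < min(self.radii)):
            raise InputError("need 0 < thickness < min(radii)")
        if not (0 <= self.noise_density < 0.5):
            raise InputError("need 0 <= noise_density < 0.5")
        if not (0 <= self.base_cut < 0.5):
            raise InputError("need 0 <= base_cut < 0.5")


def _shell_mask(spec: PhantomSpec) -> np.ndarray:
    dims = spec.dims
    sp = np.asarray(spec.spacing, float)
    center = (np.asarray(dims, float) - 1.0) / 2.0 * sp
    half_extent = np.asarray(dims, float) * sp / 2.0
    if np.any(np.asarray(spec.radii) > half_extent):
        raise InputError(
            f"ellipsoid radii {spec.radii} exceed grid half-extent {tuple(half_extent)}"
        )
    ax = [(np.arange(d) * s - c) for d, s, c in zip(dims, sp, center)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    outer = np.asarray(spec.radii, float)
    inner = outer - spec.thickness
    q_out = (x / outer[0]) ** 2 + (y / outer[1]) ** 2 + (z / outer[2]) ** 2
    q_in = (x / inner[0]) ** 2 + (y / inner[1]) ** 2 + (z / inner[2]) ** 2
    shell = (q_out <= 1.0) & (q_in > 1.0)
    if spec.base_cut > 0:
        zmin = -outer[2]
        cut_plane = zmin + spec.base_cut * 2.0 * outer[2]
        shell &= z > cut_plane
    return shell.astype(np.uint8)


def make_skull_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Build the hollow shell (plus artefacts/noise if the spec asks).

    A voxel is foreground iff its center lies between the inner and outer
    ellipsoid surfaces (inclusive on the outer) and above the base cut.
    Deterministic for a fixed spec.
    """
    shell = _shell_mask(spec)
    vol = BinaryVolume(
        voxels=shell,
        spacing=spec.spacing,
        source_id=f"phantom:seed={spec.seed}",
    )
    if spec.artefact_plate or spec.noise_density > 0:
        vol = add_artefacts(
            vol, plate=spec.artefact_plate, noise_density=spec.noise_density,
            seed=spec.seed,
        )
    return vol


def add_artefacts(
    skull: BinaryVolume, plate: bool = False, noise_density: float = 0.0,
    seed: int = 0,
) -> BinaryVolume:
    """Add a disconnected support-plate slab and/or salt-and-pepper noise.

    The plate is a thin axial slab at the inferior edge of the grid, kept
    >= 2 background voxels away from the skull; each voxel is then flipped
    independently with probability ``noise_density``.
    """
    if skull.count() == 0:
        raise InputError("skull mask is empty")
    vox = skull.voxels.copy()
    if plate:
        occupied_z = np.flatnonzero(vox.any(axis=(0, 1)))
        lowest = occupied_z[0]
        # slab occupies z slices [0, lowest - 3]; need >= 2 empty slices between
        if lowest < 3:
            raise InputError("no room for a plate disjoint from the skull")
        x0, x1 = vox.shape[0] // 4, 3 * vox.shape[0] // 4
        y0, y1 = vox.shape[1] // 4, 3 * vox.shape[1] // 4
        vox[x0:x1, y0:y1, 0 : max(1, lowest - 2)] = 1
    if noise_density > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(vox.shape) < noise_density
        vox = np.where(flips, 1 - vox, vox).astype(np.uint8)
    return BinaryVolume(
        voxels=vox,
        spacing=skull.spacing,
        origin=skull.origin,
        orientation=skull.orientation,
        source_id=skull.source_id,
    )


def make_cohort(
    n: int, base_spec: PhantomSpec = PhantomSpec(), jitter: float = 0.1,
    seed: int = 0,
) -> list[BinaryVolume]:
    """Generate ``n`` phantoms with radii/thickness jittered within +/-jitter.

    Each member's randomness comes from its own stream derived as
    ``seed + index`` so the cohort is reproducible independent of order.
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    cohort = []
    for i in range(n):
        member_seed = int(seed) + i
        rng = np.random.default_rng(member_seed)
        f = 1.0 + jitter * rng.uniform(-1, 1, size=4)
        spec = dataclasses.replace(
            base_spec,
            radii=tuple(r * fi for r, fi in zip(base_spec.radii, f[:3])),
            thickness=base_spec.thickness * f[3],
            seed=member_seed,
        )
        vol = make_skull_phantom(spec)
        vol.source_id = f"phantom:{i:04d}:seed={member_seed}"
        cohort.append(vol)
    return cohort
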