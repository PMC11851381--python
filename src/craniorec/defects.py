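"""Parametric cranial defect injection and dataset composition.

A defect is a closed parametric solid (sphere, cube, cylinder or triangular
prism) voxelized onto the skull grid and subtracted from the bone mask;
the removed bone is kept as the ground-truth implant.  Defects are placed
on the shell surface inside one of five angular regions of the cranial
vault -- front (frontal), back (occipital), left/right (parietotemporal)
and top (parietal) -- defined about the skull centroid in the canonical
frame.

The dataset composer mirrors a 5-region x 4-shape plan: the training cohort
is split evenly into five region subsets, each skull receiving all four
shapes in its assigned region, while every test skull receives all four
shapes in all five regions.  With 360 training and 36 test skulls this
yields 1440 + 720 = 2160 defected samples over 20 case types.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .volio import BinaryVolume

__all__ = [
    "SHAPES",
    "REGIONS",
    "RegionAtlas",
    "DefectSpec",
    "DefectPair",
    "make_shape_mask",
    "sample_defect_center",
    "inject_defect",
    "enumerate_cases",
    "build_dataset",
    "realize_case",
]

SHAPES = ("sphere", "cube", "cylinder", "triangular_prism")
REGIONS = ("front", "back", "left", "right", "top")


@dataclass(frozen=True)
class RegionAtlas:
    """Angular sectors of the cranial vault about the skull centroid.

    ``top`` is everything above ``top_elevation_deg``; the four lateral
    regions are azimuth quadrants (centered on +Y anterior for ``front``,
    -Y for ``back``, +X subject-left for ``left``, -X for ``right``) with
    elevation in (``floor_deg``, ``top_elevation_deg``].
    """

    top_elevation_deg: float = 60.0
    floor_deg: float = 10.0

    def classify(self, offset_mm: np.ndarray) -> str | None:
        """Region label for a point at mm offset from the centroid."""
        x, y, z = offset_mm
        r_plane = float(np.hypot(x, y))
        elev = float(np.degrees(np.arctan2(z, r_plane)))
        if elev > self.top_elevation_deg:
            return "top"
        if elev <= self.floor_deg:
            return None
        az = float(np.degrees(np.arctan2(y, x)))  # 0 = +X (left)
        if -45 <= az < 45:
            return "left"
        if 45 <= az < 135:
            return "front"
        if az >= 135 or az < -135:
            return "right"
        return "back"


@dataclass
class DefectSpec:
    """Geometric parameters of one defect, in mm about ``center`` (voxels).

    ``axis`` orients the cylinder/prism extrusion (defaults to +Z); the
    prism's triangular cross-section is a right triangle with legs
    ``base_mm`` and ``height_mm`` in the plane normal to ``axis``.
    """

    shape: str
    region: str = ""
    center: tuple = (0, 0, 0)
    radius_mm: float = 0.0  # sphere, cylinder
    edges_mm: tuple = (0.0, 0.0, 0.0)  # cube
    height_mm: float = 0.0  # cylinder
    base_mm: float = 0.0  # prism triangle leg u
    tri_height_mm: float = 0.0  # prism triangle leg v
    extrusion_mm: float = 0.0  # prism length along axis
    axis: tuple = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise InputError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        lengths = {
            "sphere": (self.radius_mm,),
            "cube": tuple(self.edges_mm),
            "cylinder": (self.radius_mm, self.height_mm),
            "triangular_prism": (self.base_mm, self.tri_height_mm, self.extrusion_mm),
        }[self.shape]
        if any(v <= 0 for v in lengths):
            raise InputError(f"all {self.shape} dimensions must be > 0, got {lengths}")


@dataclass
class DefectPair:
    """(healthy, defected, ground-truth implant) triple for one case."""

    healthy: BinaryVolume
    defected: BinaryVolume
    implant_gt: BinaryVolume
    spec: DefectSpec
    usable: bool = True


def _orthonormal_frame(axis):
    w = np.asarray(axis, dtype=float)
    n = np.linalg.norm(w)
    if n == 0:
        raise InputError("shape axis must be nonzero")
    w = w / n
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def make_shape_mask(spec: DefectSpec, like: BinaryVolume) -> BinaryVolume:
    """Voxelize the spec's solid on the grid of ``like``.

    A voxel is set iff its center lies inside or on the closed boundary
    (inclusive <=); the prism's extrusion interval is the centered half-open
    band ``[-L/2, L/2)`` along its axis, so an extrusion of k unit-spaced
    voxels covers exactly k slices.
    """
    dims = like.dims
    center = np.asarray(spec.center, dtype=float)
    if np.any(center < 0) or np.any(center >= np.asarray(dims)):
        raise InputError(f"center {spec.center} outside grid {dims}")
    sp = np.asarray(like.spacing)
    gx = (np.arange(dims[0]) - center[0]) * sp[0]
    gy = (np.arange(dims[1]) - center[1]) * sp[1]
    gz = (np.arange(dims[2]) - center[2]) * sp[2]
    dx = gx[:, None, None]
    dy = gy[None, :, None]
    dz = gz[None, None, :]

    if spec.shape == "sphere":
        mask = dx**2 + dy**2 + dz**2 <= spec.radius_mm**2
    elif spec.shape == "cube":
        e = np.asarray(spec.edges_mm) / 2.0
        mask = (np.abs(dx) <= e[0]) & (np.abs(dy) <= e[1]) & (np.abs(dz) <= e[2])
    else:
        u, v, w = _orthonormal_frame(spec.axis)
        cu = dx * u[0] + dy * u[1] + dz * u[2]
        cv = dx * v[0] + dy * v[1] + dz * v[2]
        cw = dx * w[0] + dy * w[1] + dz * w[2]
        if spec.shape == "cylinder":
            mask = (cu**2 + cv**2 <= spec.radius_mm**2) & (
                np.abs(cw) <= spec.height_mm / 2.0
            )
        else:  # triangular_prism
            b, h = spec.base_mm, spec.tri_height_mm
            tri = (cu >= 0) & (cv >= 0) & (cu * h + cv * b <= b * h)
            half = spec.extrusion_mm / 2.0
            mask = tri & (cw >= -half) & (cw < half)
    if not mask.any():
        raise InputError("shape does not cover any voxel center on this grid")
    return like.with_voxels(mask.astype(np.uint8))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Outer-surface voxels: boundary of the cavity-filled foreground.

    Using the filled mask keeps defect centers on the exterior shell surface
    rather than the wall of the cranial cavity.
    """
    from scipy import ndimage

    filled = ndimage.binary_fill_holes(mask)
    eroded = ndimage.binary_erosion(
        filled, structure=ndimage.generate_binary_structure(3, 1)
    )
    return (filled & ~eroded) & mask.astype(bool)


def sample_defect_center(
    skull: BinaryVolume, region: str, atlas: RegionAtlas = RegionAtlas(),
    seed: int = 0,
) -> tuple:
    """Uniformly pick a shell-surface voxel inside the region's sector."""
    if region not in REGIONS:
        raise InputError(f"unknown region {region!r}")
    surf = np.argwhere(_surface_voxels(skull.voxels))
    if len(surf) == 0:
        raise InputError("skull has no surface voxels")
    sp = np.asarray(skull.spacing)
    coords_mm = surf * sp
    centroid = (np.argwhere(skull.voxels > 0) * sp).mean(axis=0)
    labels = np.array([atlas.classify(c - centroid) for c in coords_mm], dtype=object)
    in_sector = np.flatnonzero(labels == region)
    if len(in_sector) == 0:
        raise InputError(f"region {region!r} does not intersect the shell")
    rng = np.random.default_rng(seed)
    pick = surf[in_sector[rng.integers(len(in_sector))]]
    return tuple(int(p) for p in pick)


def inject_defect(skull: BinaryVolume, spec: DefectSpec) -> DefectPair:
    """Subtract the spec's shape from the skull, keeping the removed bone.

    ``defected = skull AND NOT mask``; ``implant_gt = skull AND mask``.
    A mask that misses the skull entirely produces a warning and a pair
    flagged unusable (empty implant).
    """
    mask = make_shape_mask(spec, skull)
    overlap = mask.voxels & skull.voxels
    usable = bool(overlap.any())
    if not usable:
        warnings.warn("defect mask does not overlap the skull", stacklevel=2)
    defected = skull.with_voxels((skull.voxels & ~mask.voxels).astype(np.uint8))
    implant = skull.with_voxels(overlap.astype(np.uint8))
    return DefectPair(
        healthy=skull, defected=defected, implant_gt=implant, spec=spec,
        usable=usable,
    )


def enumerate_cases(
    regions=REGIONS, shapes=SHAPES
) -> list[tuple[str, str]]:
    """Stable (region, shape) Cartesian product: 5 x 4 = 20 full-plan cases."""
    return [(r, s) for r in regions for s in shapes]


def _pair_seed(cohort_seed: int, skull_id: str, region: str, shape: str) -> int:
    key = f"{cohort_seed}|{skull_id}|{region}|{shape}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _characteristic_length(skull: BinaryVolume) -> float:
    """Mean semi-axis estimated from the foreground bounding box (mm)."""
    idx = np.argwhere(skull.voxels > 0)
    extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(skull.spacing)
    return float(extent.mean() / 2.0)


def _draw_spec(
    skull: BinaryVolume, region: str, shape: str, seed: int,
    atlas: RegionAtlas, size_band=(0.15, 0.25),
) -> DefectSpec:
    rng = np.random.default_rng(seed)
    center = sample_defect_center(skull, region, atlas, seed=int(rng.integers(2**31)))
    ell = _characteristic_length(skull)
    lo, hi = size_band

    def draw():
        return float(rng.uniform(lo, hi) * ell)

    sp = np.asarray(skull.spacing)
    centroid = (np.argwhere(skull.voxels > 0) * sp).mean(axis=0)
    normal = np.asarray(center) * sp - centroid
    if np.linalg.norm(normal) == 0:
        normal = np.array([0.0, 0.0, 1.0])
    kwargs = dict(shape=shape, region=region, center=center, seed=seed,
                  axis=tuple(normal / np.linalg.norm(normal)))
    if shape == "sphere":
        kwargs["radius_mm"] = draw()
    elif shape == "cube":
        kwargs["edges_mm"] = (draw(), draw(), draw())
    elif shape == "cylinder":
        kwargs.update(radius_mm=draw(), height_mm=2 * draw())
    else:
        kwargs.update(base_mm=2 * draw(), tri_height_mm=2 * draw(),
                      extrusion_mm=2 * draw())
    return DefectSpec(**kwargs)


def realize_case(
    skull: BinaryVolume, region: str, shape: str, seed: int,
    atlas: RegionAtlas = RegionAtlas(), size_band=(0.15, 0.25),
) -> DefectPair:
    """Draw the per-case defect parameters and inject the defect."""
    spec = _draw_spec(skull, region, shape, seed, atlas, size_band)
    return inject_defect(skull, spec)


@dataclass
class DatasetManifest:
    """Composition plan: one row per (skull, region, shape) defect case."""

    rows: pd.DataFrame
    seed: int
    atlas: RegionAtlas = field(default_factory=RegionAtlas)

    @property
    def n_train(self) -> int:
        return int((self.rows["split"] == "train").sum())

    @property
    def n_test(self) -> int:
        return int((self.rows["split"] == "test").sum())

    def __len__(self) -> int:
        return len(self.rows)


def build_dataset(
    train_skulls: dict, test_skulls: dict,
    atlas: RegionAtlas = RegionAtlas(), shapes=SHAPES, seed: int = 0,
    regions=REGIONS,
) -> DatasetManifest:
    """Compose the defect-injection plan over named skull cohorts.

    ``train_skulls``/``test_skulls`` map skull id -> BinaryVolume (or any
    placeholder when only the plan is needed; volumes are not touched here).
    The training cohort is split into ``len(regions)`` equal region subsets
    (truncating with a warning if not divisible); each training skull gets
    every shape in its assigned region.  Every test skull gets every shape
    in every region.  Per-case seeds derive from (seed, skull id, region,
    shape) so any row is reproducible in isolation.
    """
    if not train_skulls or not test_skulls:
        raise InputError("train and test cohorts must be nonempty")
    train_ids = list(train_skulls)
    n_regions = len(regions)
    usable = len(train_ids) - len(train_ids) % n_regions
    if usable != len(train_ids):
        warnings.warn(
            f"training cohort truncated from {len(train_ids)} to {usable} "
            f"(must be divisible by {n_regions})", stacklevel=2,
        )
        train_ids = train_ids[:usable]
    if not train_ids:
        raise InputError(f"need at least {n_regions} training skulls")
    per = len(train_ids) // n_regions
    records = []
    for ri, region in enumerate(regions):
        for sid in train_ids[ri * per : (ri + 1) * per]:
            for shape in shapes:
                records.append(
                    ("train", sid, region, shape, _pair_seed(seed, sid, region, shape))
                )
    for sid in test_skulls:
        for region in regions:
            for shape in shapes:
                records.append(
                    ("test", sid, region, shape, _pair_seed(seed, sid, region, shape))
                )
    rows = pd.DataFrame(
        records, columns=["split", "skull_id", "region", "shape", "case_seed"]
    )
    rows["defected_path"] = [
        f"{split}/{sid}_{region}_{shape}_defected.nrrd"
        for split, sid, region, shape in zip(
            rows["split"], rows["skull_id"], rows["region"], rows["shape"]
        )
    ]
    rows["implant_path"] = rows["defected_path"].str.replace(
        "_defected.nrrd", "_implant.nrrd", regex=False
    )
    return DatasetManifest(rows=rows, seed=seed, atlas=atlas)
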