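"""Quantitative evaluation of reconstructions and implant fitment.

Six voxelwise reconstruction metrics (DSC, JSC, Hausdorff distance in mm,
precision, recall, specificity) computed per case and aggregated per
(region, shape) case type, plus a rim edge-gap measurement summarizing
implant fitment as mean mm gaps on the four sides (L, B, R, T) of the
cavity.

The Hausdorff distance is taken over foreground *surface* voxels (those
with at least one face-adjacent background neighbor), scaled by physical
spacing; the classical maximum is the default, with a 95th-percentile
variant available.  When both masks are empty the overlap metrics default
to 1 (perfect agreement) and HD is undefined (NaN) -- both logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .defects import DefectPair
from .errors import InputError
from .volio import BinaryVolume

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dsc",
    "jsc",
    "precision",
    "recall",
    "specificity",
    "hausdorff_mm",
    "evaluate_case",
    "evaluate_suite",
    "EdgeGapReport",
    "edge_gap_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _vox(v):
    return v.voxels if isinstance(v, BinaryVolume) else np.asarray(v)


def confusion(pred, truth) -> ConfusionCounts:
    """Exhaustive voxel tally of pred against truth."""
    p, t = _vox(pred).astype(bool), _vox(truth).astype(bool)
    if p.shape != t.shape:
        raise InputError(f"dims mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num, den, name, empty_value=np.nan):
    if den == 0:
        log.warning("%s undefined (zero denominator); reporting %s", name, empty_value)
        return float(empty_value)
    return num / den


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); both-empty masks score 1."""
    if c.tp + c.fp + c.fn == 0:
        log.warning("both masks empty; DSC defined as 1 by convention")
        return 1.0
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def jsc(c: ConfusionCounts) -> float:
    """Jaccard TP/(TP+FP+FN); both-empty masks score 1."""
    if c.tp + c.fp + c.fn == 0:
        log.warning("both masks empty; JSC defined as 1 by convention")
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def _surface_coords_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """mm coordinates of foreground voxels with a face-adjacent background
    neighbor (grid borders count as background)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = mask.astype(bool) & ~eroded
    return np.argwhere(surf) * np.asarray(spacing, dtype=float)


def hausdorff_mm(a: BinaryVolume, b, mode: str = "max", spacing=None) -> float:
    """Symmetric Hausdorff distance between foreground surfaces, in mm.

    ``mode='max'`` is the classical maximum deviation; ``mode='p95'`` takes
    the 95th percentile of each directed distance set before the outer max.
    """
    if mode not in ("max", "p95"):
        raise InputError(f"mode must be 'max' or 'p95', got {mode!r}")
    if spacing is None:
        spacing = a.spacing if isinstance(a, BinaryVolume) else (1.0, 1.0, 1.0)
    av, bv = _vox(a), _vox(b)
    if av.shape != bv.shape:
        raise InputError(f"dims mismatch: {av.shape} vs {bv.shape}")
    pa = _surface_coords_mm(av, spacing)
    pb = _surface_coords_mm(bv, spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise InputError("hausdorff_mm requires two nonempty masks")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if mode == "max":
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


_METRIC_COLUMNS = ["dsc", "jsc", "hd_mm", "precision", "recall", "specificity"]


def evaluate_case(pred, truth, spacing=None, hd_mode: str = "max") -> dict:
    """All six metrics for one (prediction, ground truth) mask pair."""
    c = confusion(pred, truth)
    try:
        hd = hausdorff_mm(pred, truth, mode=hd_mode, spacing=spacing)
    except InputError:
        hd = float("nan")
    return {
        "dsc": dsc(c),
        "jsc": jsc(c),
        "hd_mm": hd,
        "precision": precision(c),
        "recall": recall(c),
        "specificity": specificity(c),
    }


def evaluate_suite(records, hd_mode: str = "max") -> pd.DataFrame:
    """Aggregate per-case metrics into the 20-row case-type table.

    ``records`` is an iterable of dicts with keys ``region``, ``shape``,
    ``pred``, ``truth`` and optionally ``spacing``.  Records with a missing
    prediction are listed in a warning and excluded.  Returns per-(region,
    shape) means plus a trailing ``overall`` row of grand means.
    """
    rows, missing = [], []
    for rec in records:
        if rec.get("pred") is None:
            missing.append((rec.get("region"), rec.get("shape")))
            continue
        m = evaluate_case(rec["pred"], rec["truth"], rec.get("spacing"), hd_mode)
        rows.append({"region": rec["region"], "shape": rec["shape"], **m})
    if missing:
        warnings.warn(f"missing predictions excluded: {missing}", stacklevel=2)
    if not rows:
        raise InputError("no evaluable records")
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["region", "shape"], sort=False)[_METRIC_COLUMNS]
        .mean()
        .reset_index()
    )
    overall = df[_METRIC_COLUMNS].mean()
    table.loc[len(table)] = {"region": "overall", "shape": "", **overall.to_dict()}
    table.attrs["hd_mode"] = hd_mode
    return table


@dataclass
class EdgeGapReport:
    """Mean rim gaps (mm) per cavity side and overall."""

    side_means: dict  # {"L": mm, "B": mm, "R": mm, "T": mm} (NaN = undefined)
    overall: float
    n_points: int


def edge_gap_report(
    implant: BinaryVolume, pair: DefectPair, n_per_side: int = 10, seed: int = 0
) -> EdgeGapReport:
    """Measure the implant-to-cavity rim gap on four sides of the defect.

    The cavity rim is the ring of ground-truth cavity voxels face-adjacent
    to the residual (defected) skull.  Rim voxels are partitioned into four
    angular quadrants (L, B, R, T) in the tangent plane at the defect
    center (as viewed along the outward normal), ``n_per_side`` points are
    sampled uniformly per quadrant, and each gap is the mm distance from
    the rim point to the nearest implant voxel.  A perfect implant scores
    0 on every side.
    """
    if implant.count() == 0:
        raise InputError("implant is empty")
    sp = np.asarray(implant.spacing, dtype=float)
    gt = pair.implant_gt.voxels.astype(bool)
    if not gt.any():
        raise InputError("pair has an empty ground-truth implant")
    touching = ndimage.binary_dilation(
        pair.defected.voxels.astype(bool),
        structure=ndimage.generate_binary_structure(3, 1),
    )
    rim = np.argwhere(gt & touching)
    if len(rim) == 0:
        raise InputError("cavity rim is empty (defect does not border the skull)")
    rim_mm = rim * sp

    skull_centroid = (np.argwhere(pair.healthy.voxels > 0) * sp).mean(axis=0)
    center = (np.argwhere(gt) * sp).mean(axis=0)
    w = center - skull_centroid
    if np.linalg.norm(w) == 0:
        w = np.array([0.0, 0.0, 1.0])
    w = w / np.linalg.norm(w)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)

    d = rim_mm - center
    ang = np.degrees(np.arctan2(d @ v, d @ u)) % 360.0
    quadrants = {
        "R": (ang >= 315) | (ang < 45),
        "T": (ang >= 45) & (ang < 135),
        "L": (ang >= 135) & (ang < 225),
        "B": (ang >= 225) & (ang < 315),
    }
    tree = cKDTree(np.argwhere(implant.voxels > 0) * sp)
    rng = np.random.default_rng(seed)
    side_means, gaps_all = {}, []
    for side, sel in quadrants.items():
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            warnings.warn(f"side {side}: empty quadrant; gap undefined", stacklevel=2)
            side_means[side] = float("nan")
            continue
        take = rng.choice(idx, size=min(n_per_side, len(idx)), replace=False)
        gaps = tree.query(rim_mm[take])[0]
        side_means[side] = float(gaps.mean())
        gaps_all.extend(gaps)
    return EdgeGapReport(
        side_means=side_means,
        overall=float(np.mean(gaps_all)),
        n_points=len(gaps_all),
    )
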