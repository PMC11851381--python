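"""Implant extraction by Boolean subtraction.

The reconstructed (completed) skull minus the defected skull is the
implant: ``implant = reconstructed AND NOT defected``.  Reconstruction
noise outside the skull survives subtraction, so a largest-component
cleanup pass (same rule as artefact removal) is applied by default.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .preprocess import _largest_component
from .volio import BinaryVolume, Volume

__all__ = ["binarize", "extract_implant", "clean_implant"]


def binarize(prob, tau: float = 0.5, like: Volume | None = None) -> BinaryVolume:
    """Threshold a probability volume at ``tau`` (inclusive: p >= tau -> 1).

    ``prob`` may be a raw array (geometry taken from ``like`` or defaulted)
    or a Volume.  ``tau`` must lie strictly inside (0, 1).
    """
    if not (0.0 < tau < 1.0):
        raise InputError(f"tau must be in (0, 1), got {tau}")
    if isinstance(prob, Volume):
        like, prob = prob, prob.voxels
    arr = np.asarray(prob)
    if arr.min() < 0 or arr.max() > 1:
        raise InputError("probability volume must have values in [0, 1]")
    mask = (arr >= tau).astype(np.uint8)
    if like is not None:
        return BinaryVolume(mask, spacing=like.spacing, origin=like.origin,
                            orientation=like.orientation, source_id=like.source_id)
    return BinaryVolume(mask)


def extract_implant(reconstructed: BinaryVolume, defected: BinaryVolume) -> BinaryVolume:
    """Boolean subtraction: reconstruction minus the defected skull."""
    if reconstructed.dims != defected.dims or not np.allclose(
        reconstructed.spacing, defected.spacing
    ):
        raise InputError("reconstructed and defected volumes must share geometry")
    imp = (reconstructed.voxels & ~defected.voxels).astype(np.uint8)
    return defected.with_voxels(imp)


def clean_implant(implant: BinaryVolume) -> BinaryVolume:
    """Keep only the largest 26-connected component of the implant."""
    if implant.count() == 0:
        raise InputError("implant is empty; nothing to clean")
    return implant.with_voxels(_largest_component(implant.voxels))
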