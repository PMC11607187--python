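"""Segmentation-quality and probability-calibration metrics.

All metrics accept an optional ``exclude`` mask (the conformal "uncertain"
voxels); excluded voxels are removed from both prediction and reference
before anything is computed, which models a deployment where withheld
voxels are simply not scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import GridMismatchError, LabelMask, ProbabilityMap

__all__ = ["UndefinedMetricError", "ExamMetrics", "dice", "asd", "ece", "brier"]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. empty mask after exclusion);
    callers should record a missing value, never 0."""


@dataclass
class ExamMetrics:
    """Per-exam metric bundle for one condition (with or without conformal masking)."""

    exam_id: str
    condition: str  # "WITHOUT_CP" | "WITH_CP"
    alpha: float | None
    dsc: float
    asd_mm: float
    rvd: float
    ece: float
    brier: float
    pv_ml: float


def _as_bool(mask: LabelMask | np.ndarray) -> np.ndarray:
    arr = mask.voxels if isinstance(mask, LabelMask) else np.asarray(mask)
    return arr.astype(bool)


def _check_shapes(*arrays) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise GridMismatchError(f"mask shapes differ: {shapes}")


def dice(pred: LabelMask, ref: LabelMask, exclude: LabelMask | None = None) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Voxels flagged in ``exclude`` are dropped from both masks first; if both
    masks are empty after exclusion the score is 1 by convention.
    """
    a, b = _as_bool(pred), _as_bool(ref)
    _check_shapes(a, b)
    if exclude is not None:
        e = _as_bool(exclude)
        _check_shapes(a, e)
        a, b = a & ~e, b & ~e
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one face-adjacent background neighbor."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def asd(pred: LabelMask, ref: LabelMask, exclude: LabelMask | None = None) -> float:
    """Symmetric average surface distance in mm.

    Boundaries use face adjacency; every boundary voxel of each mask
    contributes its minimal center-to-center physical distance to the other
    mask's boundary, and all distances are averaged together.
    """
    a, b = _as_bool(pred), _as_bool(ref)
    _check_shapes(a, b)
    spacing = np.asarray(pred.spacing if isinstance(pred, LabelMask) else ref.spacing)
    if exclude is not None:
        e = _as_bool(exclude)
        _check_shapes(a, e)
        a, b = a & ~e, b & ~e
    if not a.any() or not b.any():
        raise UndefinedMetricError("ASD undefined: a mask is empty after exclusion")
    pa = np.argwhere(_boundary(a)) * spacing
    pb = np.argwhere(_boundary(b)) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.concatenate([d_ab, d_ba]).mean())


def _included(p: ProbabilityMap, ref: LabelMask, exclude: LabelMask | None):
    probs = p.probs
    labels = _as_bool(ref)
    _check_shapes(probs, labels.astype(np.uint8))
    keep = np.ones(probs.shape, dtype=bool)
    if exclude is not None:
        keep &= ~_as_bool(exclude)
    if not keep.any():
        raise UndefinedMetricError("no voxels left after exclusion")
    return probs[keep], labels[keep]


def ece(
    p: ProbabilityMap, ref: LabelMask, n_bins: int = 10, exclude: LabelMask | None = None
) -> float:
    """Expected calibration error with equal-width bins on the foreground probability.

    ECE = sum_b (n_b / N) * |acc_b - conf_b|, where conf_b is the mean
    predicted probability in bin b and acc_b the empirical foreground rate.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    probs, labels = _included(p, ref, exclude)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    total = probs.size
    out = 0.0
    for b in range(n_bins):
        sel = bins == b
        n_b = int(sel.sum())
        if n_b == 0:
            continue
        conf = probs[sel].mean()
        acc = labels[sel].mean()
        out += (n_b / total) * abs(acc - conf)
    return float(out)


def brier(p: ProbabilityMap, ref: LabelMask, exclude: LabelMask | None = None) -> float:
    """Brier score: mean squared error between p_fg and the binary label."""
    probs, labels = _included(p, ref, exclude)
    return float(np.mean((probs - labels) ** 2))
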