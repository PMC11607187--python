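"""Organ volume computation: voxel counting, the PI-RADS ellipsoid formula,
and the relative volume difference (RVD).

Sign convention: ``rvd = (pv - pv_ref) / pv_ref``, so positive values mean
the method overestimates the reference.  Overestimation is not bounded by
+1 under this definition; values are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LabelMask

__all__ = ["VolumeMeasure", "mask_volume", "ellipsoid_volume", "rvd"]

_SOURCES = frozenset({"DL", "CP", "REF"})


@dataclass(frozen=True)
class VolumeMeasure:
    """A volume in mL tagged with its origin: DL (thresholded model mask),
    CP (certain-foreground after conformal masking) or REF (ellipsoid formula)."""

    value_ml: float
    source: str
    exam_id: str = ""

    def __post_init__(self) -> None:
        if self.value_ml < 0:
            raise ValueError(f"volume must be >= 0, got {self.value_ml}")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {sorted(_SOURCES)}, got {self.source!r}")


def mask_volume(mask: LabelMask) -> float:
    """Volume of the foreground in mL: voxel count times voxel volume."""
    return float(mask.voxels.sum(dtype=np.int64)) * mask.voxel_volume_mm3 / 1000.0


def ellipsoid_volume(width_mm: float, height_mm: float, depth_mm: float) -> float:
    """PI-RADS 2.1 ellipsoid formula: (pi/6) * W * H * D, in mL."""
    if width_mm <= 0 or height_mm <= 0 or depth_mm <= 0:
        raise ValueError(
            f"all diameters must be positive, got ({width_mm}, {height_mm}, {depth_mm})"
        )
    return float(np.pi / 6.0 * width_mm * height_mm * depth_mm / 1000.0)


def rvd(pv_ml: float, pv_ref_ml: float) -> float:
    """Relative volume difference ``(pv - pv_ref) / pv_ref``; > 0 = overestimation."""
    if pv_ref_ml <= 0:
        raise ValueError(f"reference volume must be positive, got {pv_ref_ml}")
    return (pv_ml - pv_ref_ml) / pv_ref_ml
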