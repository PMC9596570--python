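"""Object-level false-positive filters for live-cell (high-recall) detections.

Autotuned detection deliberately over-detects; precision is restored by
three per-object filters:

1. **Effect size** — the object's intensity distribution must have a
   non-negative Cohen's d against the cell's intensity distribution
   (a real punctum is at least as bright as the cytosol it sits in).
2. **Peak outlier** — the object's maximum intensity must be an upper
   outlier of the cell intensity distribution, beyond the Tukey fence
   Q3 + 1.5 * IQR.
3. **Minimal area** — objects of area <= 4 px are below the 2-px precision
   of the system and are discarded.

Quartiles use linear interpolation (the common default); the cell
distribution is every pixel inside the valid cell mask of the same channel,
object pixels included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import MIN_AREA_LIVE, PunctaObject

#: Tukey fence multiplier for the peak-outlier filter.
OUTLIER_IQR_FACTOR = 1.5


@dataclass
class QCRecord:
    puncta_id: int
    cohens_d: float
    peak_intensity: float
    cell_q3: float
    cell_iqr: float
    area_px: int
    passed_effect_size: bool
    passed_peak_outlier: bool
    passed_area: bool

    @property
    def passed(self) -> bool:
        return self.passed_effect_size and self.passed_peak_outlier and self.passed_area


def cohens_d(object_pixels: np.ndarray, cell_pixels: np.ndarray) -> float:
    """Pooled-SD Cohen's d of object intensities against cell intensities.

    ``d = (mean_obj - mean_cell) / s_pooled`` with the textbook pooled
    standard deviation.  Degenerate cases: when ``s_pooled`` is zero, d is 0
    for equal means and signed infinity otherwise; fewer than 3 pixels in
    total is undefined (NaN) and treated downstream as a failure.
    """
    x = np.asarray(object_pixels, dtype=float)
    y = np.asarray(cell_pixels, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both intensity lists must be nonempty")
    n1, n2 = x.size, y.size
    if n1 + n2 < 3:
        return math.nan
    diff = float(x.mean() - y.mean())
    s1 = float(x.var(ddof=1)) if n1 > 1 else 0.0
    s2 = float(y.var(ddof=1)) if n2 > 1 else 0.0
    pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        return math.inf if diff > 0 else -math.inf
    return diff / pooled


def apply_qc(
    objects: list[PunctaObject],
    cell_mask: np.ndarray,
    frame: np.ndarray,
    min_area_px: int = MIN_AREA_LIVE,
) -> tuple[list[PunctaObject], list[QCRecord]]:
    """Apply the three live-cell filters; keep objects passing all of them.

    Returns the surviving objects and one :class:`QCRecord` per input
    object.  Idempotent: re-running on the kept set keeps every object.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    frame = np.asarray(frame, dtype=float)
    cell_values = frame[cell_mask]
    q1, q3 = np.percentile(cell_values, [25, 75])  # linear interpolation
    iqr = float(q3 - q1)
    fence = float(q3) + OUTLIER_IQR_FACTOR * iqr

    kept: list[PunctaObject] = []
    records: list[QCRecord] = []
    for obj in objects:
        d = cohens_d(obj.pixel_values, cell_values)
        ok_d = (not math.isnan(d)) and d >= 0
        ok_peak = obj.max_intensity > fence
        ok_area = obj.area_px > min_area_px
        records.append(
            QCRecord(
                puncta_id=obj.id,
                cohens_d=d,
                peak_intensity=obj.max_intensity,
                cell_q3=float(q3),
                cell_iqr=iqr,
                area_px=obj.area_px,
                passed_effect_size=ok_d,
                passed_peak_outlier=ok_peak,
                passed_area=ok_area,
            )
        )
        if ok_d and ok_peak and ok_area:
            kept.append(obj)
    return kept, records
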