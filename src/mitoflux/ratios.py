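"""Mitochondrial-potential ratio under autophagosomes.

For each dual (GFP+mRFP) punctum overlapping the mitochondrial mask, the
mean mitochondrial-dye intensity over the overlapping mito-positive pixels
is expressed relative to (a) the mean intensity of the adjacent
mitochondrial segment and (b) the mean intensity of all mitochondrial
segments in the cell.  Because dye intensity tracks membrane potential, a
per-cell median ratio below 1 indicates that autophagosomes preferentially
sit on mitochondria of below-average potential.  Ratios are scale-free:
multiplying the dye frame by a positive constant leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .associate import DualPuncta, PixelObject, min_edge_distance

logger = logging.getLogger(__name__)


@dataclass
class RatioRecord:
    dual_id: int
    segment_id: int
    overlap_mean: float
    segment_mean: float
    cell_mean: float
    ratio_segment: float
    ratio_cell: float


@dataclass
class CellRatioSummary:
    """Boxplot statistics of one per-cell ratio distribution."""

    cell_id: str
    which: str  # "segment" or "cell"
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def compute_ratios(
    duals: Sequence[DualPuncta],
    mito_objects: Sequence[PixelObject],
    mito_frame: np.ndarray,
    association_cutoff_px: float = 5.0,
) -> list[RatioRecord]:
    """Per-punctum dye-intensity ratios against segment and cell baselines.

    Overlap pixels are the intersection of the punctum's pixel set with the
    union of mito-object pixels; the adjacent segment is the mito object
    sharing the most overlap pixels (ties broken by nearest centroid;
    fallback to the nearest-by-edge segment when the punctum is within the
    association cutoff but shares no pixel).  Intensities come from the raw
    dye frame, never the filter response.  Puncta with no overlap and no
    near segment yield no record; zero baseline means drop the record with
    a warning.
    """
    if not mito_objects:
        return []
    mito_frame = np.asarray(mito_frame, dtype=float)
    pixel_owner: dict[tuple[int, int], int] = {}
    for idx, m in enumerate(mito_objects):
        for r, c in m.pixels:
            pixel_owner[(int(r), int(c))] = idx
    seg_means = [
        float(mito_frame[m.pixels[:, 0], m.pixels[:, 1]].mean()) for m in mito_objects
    ]
    all_pix = np.vstack([m.pixels for m in mito_objects])
    cell_mean = float(mito_frame[all_pix[:, 0], all_pix[:, 1]].mean())
    centroids = [m.pixels.mean(axis=0) for m in mito_objects]

    records: list[RatioRecord] = []
    for dual in duals:
        overlap_by_seg: dict[int, list[tuple[int, int]]] = {}
        for r, c in dual.pixels:
            idx = pixel_owner.get((int(r), int(c)))
            if idx is not None:
                overlap_by_seg.setdefault(idx, []).append((int(r), int(c)))
        if overlap_by_seg:
            overlap_pix = [p for pix in overlap_by_seg.values() for p in pix]
            max_n = max(len(v) for v in overlap_by_seg.values())
            tied = [i for i, v in overlap_by_seg.items() if len(v) == max_n]
            if len(tied) > 1:
                dc = np.array(dual.centroid)
                tied.sort(key=lambda i: float(np.sum((centroids[i] - dc) ** 2)))
            seg_idx = tied[0]
            vals = np.array([mito_frame[r, c] for r, c in overlap_pix])
            overlap_mean = float(vals.mean())
        else:
            # no shared pixel: fall back to the nearest segment if the punctum
            # is within the association cutoff, sampling the nearest mito pixels
            best_idx, best_d = None, float("inf")
            for i, m in enumerate(mito_objects):
                d = min_edge_distance(dual.pixels, m.pixels)
                if d < best_d:
                    best_idx, best_d = i, d
            if best_idx is None or best_d > association_cutoff_px:
                continue
            seg_idx = best_idx
            overlap_mean = seg_means[seg_idx]
        segment_mean = seg_means[seg_idx]
        if segment_mean == 0 or cell_mean == 0:
            logger.warning("dropping dual %d: zero-mean mito baseline", dual.id)
            continue
        records.append(
            RatioRecord(
                dual_id=dual.id,
                segment_id=mito_objects[seg_idx].id,
                overlap_mean=overlap_mean,
                segment_mean=segment_mean,
                cell_mean=cell_mean,
                ratio_segment=overlap_mean / segment_mean,
                ratio_cell=overlap_mean / cell_mean,
            )
        )
    return records


def summarize_ratios(
    records: Sequence[RatioRecord],
    cell_id: str = "",
    which: str = "cell",
) -> CellRatioSummary:
    """Boxplot statistics (linear-interpolation quartiles, Tukey whiskers).

    When the records pool a movie (7 Z-slices x 40 timepoints), they are
    simply concatenated before summarising.
    """
    if not records:
        raise ValueError("need at least one ratio record")
    if which not in ("segment", "cell"):
        raise ValueError("which must be 'segment' or 'cell'")
    values = np.array(
        [r.ratio_segment if which == "segment" else r.ratio_cell for r in records]
    )
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_low = values[values >= q1 - 1.5 * iqr]
    in_high = values[values <= q3 + 1.5 * iqr]
    return CellRatioSummary(
        cell_id=cell_id,
        which=which,
        n=len(values),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
    )
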