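"""Automated single-cell segmentation and ROI validity checks.

Time-lapse mode cannot rely on manually drawn ROIs, so the pipeline
recovers a cell outline per frame: suppress everything at or below the
per-image 90th-percentile intensity (the cell is the bright minority of
pixels), despeckle with a cascade of median filters (3x3, 5x5, 9x9),
binarise, and keep the largest connected component.  The mask is then
widened by four dilations with a radius-2 disk — two times the 2-px system
precision — so objects at the cell edge are not clipped, and closed so no
holes remain.  Two validity checks guard automation: the mask must be
consistent across channels (pairwise Jaccard), and frames where the mask
touches the image border are discarded outright.

Fixed-cell mode bypasses segmentation: user-supplied ROI masks are ingested
as-is but still pass through the border check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import closing, disk


@dataclass(frozen=True)
class MaskParams:
    quantile: float = 0.90
    median_windows: tuple[int, ...] = (3, 5, 9)
    n_dilations: int = 4
    dilation_radius_px: int = 2
    consistency_min_jaccard: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if any(w % 2 == 0 for w in self.median_windows):
            raise ValueError("median windows must be odd")
        if list(self.median_windows) != sorted(self.median_windows):
            raise ValueError("median windows must be increasing")


@dataclass
class CellMask:
    """A validated single-cell region.

    ``valid`` is False when a check failed; ``rejection_reason`` is one of
    ``none``, ``touches_border``, ``channel_inconsistent``.
    """

    mask: np.ndarray
    source: str = "automatic"  # or "manual_roi"
    valid: bool = True
    rejection_reason: str = "none"
    meta: dict = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _segment_channel(frame: np.ndarray, params: MaskParams) -> np.ndarray:
    """Quantile suppression -> median cascade -> binarise -> largest object."""
    frame = np.asarray(frame, dtype=float)
    q = np.quantile(frame, params.quantile)
    suppressed = np.where(frame > q, frame, 0.0)
    for w in params.median_windows:
        suppressed = ndimage.median_filter(suppressed, size=w)
    binary = suppressed > 0
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return np.zeros(frame.shape, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def segment_cell(
    channels: dict[str, np.ndarray],
    params: MaskParams | None = None,
    reference_channels: tuple[str, ...] | None = None,
) -> CellMask:
    """Segment the single complete cell, cross-checking channels.

    Each reference channel is segmented independently; the per-channel
    masks are refined (dilation + closing) and then required to agree
    (:func:`check_consistency`) before the border check runs.
    """
    if params is None:
        params = MaskParams()
    names = reference_channels or tuple(channels)
    per_channel: dict[str, np.ndarray] = {}
    shape = None
    for ch in names:
        frame = np.asarray(channels[ch], dtype=float)
        shape = frame.shape
        if frame.std() == 0:
            continue
        raw = _segment_channel(frame, params)
        if not raw.any():
            continue
        per_channel[ch] = refine_mask(CellMask(raw), params).mask
    if not per_channel:
        return CellMask(
            np.zeros(shape, dtype=bool), valid=False, rejection_reason="channel_inconsistent"
        )
    if len(per_channel) == 1:
        consensus = CellMask(next(iter(per_channel.values())))
    else:
        consensus = check_consistency(per_channel, params)
        if not consensus.valid:
            return consensus
    return check_border(consensus)


def refine_mask(mask: CellMask, params: MaskParams | None = None) -> CellMask:
    """Widen and close a cell mask.

    Widens by ``n_dilations`` dilations of ``dilation_radius_px`` each
    (default 4 x radius 2 = 2 x the 2-px system precision), realised as one
    exact Euclidean dilation by the cumulative radius — iterating discrete
    disk dilations would accumulate an octagonal bias.  Then morphological
    closing and hole filling.  The output is a superset of the input.
    """
    if params is None:
        params = MaskParams()
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise ValueError("refine_mask requires a nonempty mask")
    total_radius = params.n_dilations * params.dilation_radius_px
    m = ndimage.distance_transform_edt(~m) <= total_radius
    selem = disk(params.dilation_radius_px)
    m = closing(m, selem)  # skimage closing: no spurious erosion at image borders
    m = ndimage.binary_fill_holes(m)
    return CellMask(m, source=mask.source, valid=mask.valid, rejection_reason=mask.rejection_reason)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def check_consistency(
    channel_masks: dict[str, np.ndarray],
    params: MaskParams | None = None,
) -> CellMask:
    """Require the cell mask to agree across channels.

    All pairwise Jaccard overlaps must reach ``consistency_min_jaccard``;
    the consensus is the union of channel masks (so weak labelling in one
    channel does not clip objects at the cell edge).
    """
    if params is None:
        params = MaskParams()
    if len(channel_masks) < 2:
        raise ValueError("need at least two channel masks")
    masks = [np.asarray(m, dtype=bool) for m in channel_masks.values()]
    min_j = min(
        jaccard(masks[i], masks[j])
        for i in range(len(masks))
        for j in range(i + 1, len(masks))
    )
    union = np.logical_or.reduce(masks)
    if min_j < params.consistency_min_jaccard:
        return CellMask(
            union,
            valid=False,
            rejection_reason="channel_inconsistent",
            meta={"min_jaccard": min_j},
        )
    return CellMask(union, valid=True, meta={"min_jaccard": min_j})


def check_border(mask: CellMask) -> CellMask:
    """Invalidate masks touching any image border row or column."""
    m = np.asarray(mask.mask, dtype=bool)
    touches = bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())
    if touches:
        return CellMask(m, source=mask.source, valid=False, rejection_reason="touches_border")
    return CellMask(m, source=mask.source, valid=mask.valid, rejection_reason=mask.rejection_reason)


def ingest_roi(roi: np.ndarray) -> CellMask:
    """Fixed-cell mode: wrap a manually drawn ROI, applying the border check."""
    return check_border(CellMask(np.asarray(roi) > 0, source="manual_roi"))
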