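"""Intensity-adaptive Laplacian-of-Gaussian (LoG) spot detection.

The detector is the pipeline's core measurement: a scale-normalised LoG
filter at a fixed spot scale (``sigma_px``, default 3 px for a ~56.6 nm
pixel), followed by an automatic threshold expressed as a z-score of the
response distribution.  The user's preference for precision over recall is
a single unitless parameter ``z``: pixels whose (negated) LoG response
exceeds ``mean + z * std`` of the response over the support region are kept.
Because both the response and its summary statistics scale linearly under
affine intensity changes ``a*I + b`` (a > 0), the decision is intensity
scale-free — the property that lets one threshold preference transfer
across channels and images.

Higher ``z`` yields higher precision at the cost of recall; the puncta
count is therefore non-increasing in ``z``.  A small-object area filter
removes detections below the optical precision limit (area <= 25 px in
fixed-cell mode, <= 4 px in live mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

#: Default threshold preference used for fixed-cell analysis.
DEFAULT_Z = 1.75
#: Default LoG scale, round(precision / 2) pixels.
DEFAULT_SIGMA_PX = 3.0
#: Fixed-cell mode: objects of area <= 25 px are below the precision limit.
MIN_AREA_FIXED = 25
#: Live-cell mode: objects of area <= 4 px are below the precision limit.
MIN_AREA_LIVE = 4
#: Autotune recall/precision preference used in live-cell mode.
AUTOTUNE_RATIO = 3.75


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of one detection run.

    ``support`` optionally restricts the threshold statistics (and the
    resulting mask) to a region of interest such as a cell mask, so that
    dark out-of-cell background does not bias the adaptive threshold.
    """

    z: float = DEFAULT_Z
    sigma_px: float = DEFAULT_SIGMA_PX
    min_area_px: int = MIN_AREA_FIXED
    connectivity: int = 8
    area_filter_inclusive: bool = True
    support: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.sigma_px < 1:
            raise ValueError("sigma_px must be >= 1")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class PunctaObject:
    """One detected connected component ("punctum") in one channel.

    ``pixels`` is an ``(n, 2)`` integer array of (row, col) coordinates;
    intensity summaries are sampled from the originating frame, never from
    the filter response.
    """

    id: int
    channel: str
    pixels: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    max_intensity: float
    mean_intensity: float
    pixel_values: np.ndarray

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def log_filter(frame: np.ndarray, sigma_px: float = DEFAULT_SIGMA_PX) -> np.ndarray:
    """Negated, scale-normalised LoG response of a 2-D frame.

    The response is ``-sigma**2 * LoG(frame)`` with reflective boundary
    handling, so bright blobs of scale ~sigma produce positive peaks and the
    response magnitude is comparable across choices of sigma.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if sigma_px < 1:
        raise ValueError("sigma_px must be >= 1")
    # the truncated LoG kernel has a tiny nonzero sum; subtracting that DC
    # leak (times a unit-sum Gaussian blur) makes the response exactly zero
    # on constant frames and exactly equivariant under a*I + b
    dc = _log_kernel_dc(sigma_px)
    raw = ndimage.gaussian_laplace(frame, sigma=sigma_px, mode="reflect")
    if dc != 0.0:
        raw = raw - dc * ndimage.gaussian_filter(frame, sigma=sigma_px, mode="reflect")
    return -(sigma_px**2) * raw


_DC_CACHE: dict[float, float] = {}


def _log_kernel_dc(sigma_px: float) -> float:
    if sigma_px not in _DC_CACHE:
        k = 2 * int(np.ceil(4 * sigma_px)) + 3
        ones = np.ones((k, k))
        _DC_CACHE[sigma_px] = float(
            ndimage.gaussian_laplace(ones, sigma=sigma_px, mode="reflect")[k // 2, k // 2]
        )
    return _DC_CACHE[sigma_px]


def threshold_response(
    response: np.ndarray,
    z: float,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Binarise a LoG response at the adaptive threshold ``mean + z*std``.

    The mean and standard deviation are computed over ``support`` (the whole
    frame when no support is given); pixels outside the support are never
    selected.  The mask is pixelwise non-increasing in ``z``.  A response
    with zero variance yields an empty mask with a warning, not an error.
    """
    if z <= 0:
        raise ValueError("z must be > 0")
    response = np.asarray(response, dtype=float)
    if support is not None:
        support = np.asarray(support, dtype=bool)
        if support.shape != response.shape:
            raise ValueError("support shape does not match response")
        if not support.any():
            raise ValueError("support is empty")
        values = response[support]
    else:
        values = response.ravel()
    mu = float(values.mean())
    sd = float(values.std())
    if sd == 0.0:
        logger.warning("zero response variance; returning empty mask")
        warnings.warn("zero response variance; empty detection mask", stacklevel=2)
        return np.zeros(response.shape, dtype=bool)
    mask = response > mu + z * sd
    if support is not None:
        mask &= support
    return mask


def label_objects(
    mask: np.ndarray,
    frame: np.ndarray,
    connectivity: int = 8,
    channel: str = "",
) -> list[PunctaObject]:
    """Split a binary mask into connected components as PunctaObjects.

    Intensities are sampled from ``frame`` (the raw image the mask was
    derived from).  Connectivity 8 treats diagonal neighbours as connected.
    """
    mask = np.asarray(mask, dtype=bool)
    frame = np.asarray(frame, dtype=float)
    skimage_conn = {4: 1, 8: 2}[connectivity]
    labels = measure.label(mask, connectivity=skimage_conn)
    objects: list[PunctaObject] = []
    for region in measure.regionprops(labels, intensity_image=frame):
        pixels = np.asarray(region.coords, dtype=int)
        values = frame[pixels[:, 0], pixels[:, 1]]
        objects.append(
            PunctaObject(
                id=int(region.label),
                channel=channel,
                pixels=pixels,
                area_px=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                max_intensity=float(values.max()),
                mean_intensity=float(values.mean()),
                pixel_values=np.asarray(values, dtype=float),
            )
        )
    return objects


def filter_min_area(
    objects: list[PunctaObject],
    min_area_px: int,
    inclusive: bool = True,
) -> list[PunctaObject]:
    """Drop objects at or below the precision-limit area.

    With ``inclusive=True`` (default) an object of area exactly
    ``min_area_px`` is removed — only objects strictly larger survive.
    """
    if inclusive:
        return [o for o in objects if o.area_px > min_area_px]
    return [o for o in objects if o.area_px >= min_area_px]


def detect_puncta(
    frame: np.ndarray,
    params: DetectionParams | None = None,
    channel: str = "",
) -> list[PunctaObject]:
    """Full detection chain: LoG filter, adaptive threshold, label, area filter."""
    if params is None:
        params = DetectionParams()
    response = log_filter(frame, params.sigma_px)
    mask = threshold_response(response, params.z, params.support)
    objects = label_objects(mask, frame, params.connectivity, channel=channel)
    return filter_min_area(objects, params.min_area_px, params.area_filter_inclusive)


def autotune_z(ratio: float, z_base: float = DEFAULT_Z) -> float:
    """Map a recall/precision preference ratio to an effective threshold z.

    ``ratio`` > 1 trades precision for recall by lowering the threshold to
    ``z_base / ratio``.  The mapping is isolated here so it can be swapped.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return z_base / ratio


def autotune_detect(
    frame: np.ndarray,
    ratio: float = AUTOTUNE_RATIO,
    params: DetectionParams | None = None,
    channel: str = "",
) -> list[PunctaObject]:
    """High-recall detection intended to be followed by the QC filters.

    Runs :func:`detect_puncta` at ``z = z_base / ratio`` with the live-mode
    area filter (area <= 4 px removed); the heavy lifting of restoring
    precision is delegated to the downstream object-level QC filters.
    """
    if params is None:
        params = DetectionParams()
    tuned = replace(params, z=autotune_z(ratio, params.z), min_area_px=MIN_AREA_LIVE)
    return detect_puncta(frame, tuned, channel=channel)
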