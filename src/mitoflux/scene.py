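"""In-memory containers for multi-channel fluorescence frames.

A :class:`Scene` bundles the co-registered 2-D channel frames of one field
of view at one Z-slice and timepoint.  All coordinates in the package are
0-based ``(row, col)`` pixel indices; physical units appear only in reports,
via ``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel names used throughout the pipeline.
CHANNELS = ("gfp", "rfp", "mito")

#: Default physical pixel size of the acquisition, in nanometres.
DEFAULT_PIXEL_SIZE_NM = 56.6


@dataclass
class Scene:
    """One multi-channel 2-D field of view.

    Parameters
    ----------
    channels
        Mapping from channel name (``"gfp"``, ``"rfp"``, ``"mito"``) to a
        2-D float array of intensities.  All frames must share one shape.
    pixel_size_nm
        Physical pixel size in nanometres.
    z_index, timepoint
        Position of this scene inside a Z-stack / time series; 0 for
        single-plane acquisitions.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    z_index: int = 0
    timepoint: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel frames have inconsistent shapes: {shapes}")
        for ch, a in self.channels.items():
            arr = np.asarray(a, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not a 2-D frame")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]
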