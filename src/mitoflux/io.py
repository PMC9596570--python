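"""TIFF and CSV input/output.

Scenes and movies are stored as multi-page TIFF with pages ordered
timepoint-major, then Z-slice, then channel (T -> Z -> C); the dimension
order, channel names and pixel size are recorded in the TIFF description as
JSON so files are self-describing.  All tabular outputs are plain CSV with
fixed headers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .associate import AssociationRecord, CellSummary, DualPuncta
from .detect import PunctaObject
from .qc import QCRecord
from .ratios import RatioRecord
from .scene import CHANNELS, DEFAULT_PIXEL_SIZE_NM, Scene
from .synth import GroundTruth


def write_scene_tiff(path: str | Path, scenes: Scene | Sequence[Scene] | Sequence[Sequence[Scene]]) -> None:
    """Write a scene, a Z-stack, or a movie (list of Z-stacks) as TIFF.

    Pages are ordered T -> Z -> channel; channel order follows
    :data:`mitoflux.scene.CHANNELS` restricted to the channels present.
    """
    if isinstance(scenes, Scene):
        movie: list[list[Scene]] = [[scenes]]
    elif scenes and isinstance(scenes[0], Scene):
        movie = [list(scenes)]  # type: ignore[list-item]
    else:
        movie = [list(stack) for stack in scenes]  # type: ignore[union-attr]
    first = movie[0][0]
    channels = [ch for ch in CHANNELS if ch in first.channels]
    meta = {
        "dimension_order": "TZC",
        "channels": channels,
        "n_timepoints": len(movie),
        "n_zslices": len(movie[0]),
        "pixel_size_nm": first.pixel_size_nm,
    }
    pages = [
        scene.channels[ch].astype(np.float32)
        for stack in movie
        for scene in stack
        for ch in channels
    ]
    tifffile.imwrite(
        str(path), np.stack(pages), photometric="minisblack", description=json.dumps(meta)
    )


def read_stack(
    path: str | Path,
    channels: Sequence[str] | None = None,
    pixel_size_nm: float | None = None,
) -> list[list[Scene]]:
    """Read a T -> Z -> C multi-page TIFF back into a movie of Scenes.

    Channel names, page layout and pixel size are taken from the JSON
    description written by :func:`write_scene_tiff`; ``channels`` overrides
    the channel names for foreign files (pages are then assumed T=Z=1
    unless the metadata says otherwise).  Raises a ValueError naming the
    problem when the declared channels do not match the page count.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    ch_names = list(channels or meta.get("channels") or CHANNELS)
    n_t = int(meta.get("n_timepoints", 1))
    n_z = int(meta.get("n_zslices", 1))
    px = pixel_size_nm or float(meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM))
    if pages.ndim == 2:
        pages = pages[None]
    expected = n_t * n_z * len(ch_names)
    if len(pages) != expected:
        if len(pages) % (n_t * n_z) == 0:
            have = len(pages) // (n_t * n_z)
            missing = ch_names[have:] or ch_names
            raise ValueError(
                f"{path.name}: expected channels {ch_names} but file has {have} "
                f"page(s) per frame (missing: {missing})"
            )
        raise ValueError(
            f"{path.name}: {len(pages)} pages incompatible with T={n_t}, Z={n_z}, "
            f"channels={ch_names}"
        )
    movie: list[list[Scene]] = []
    idx = 0
    for t in range(n_t):
        stack = []
        for z in range(n_z):
            frames = {ch: pages[idx + k].astype(float) for k, ch in enumerate(ch_names)}
            idx += len(ch_names)
            stack.append(Scene(frames, pixel_size_nm=px, z_index=z, timepoint=t))
        movie.append(stack)
    return movie


def write_ground_truth(path_prefix: str | Path, truth: GroundTruth) -> None:
    """GroundTruth as a puncta CSV plus a JSON sidecar of scene-level facts."""
    prefix = Path(path_prefix)
    rows = [
        {
            "id": p.id,
            "kind": p.kind,
            "center_row": p.center[0],
            "center_col": p.center[1],
            "sigma": p.sigma,
            "near_mito": p.near_mito,
        }
        for p in truth.puncta
    ]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".puncta.csv"), index=False)
    sidecar = {
        "expected_n_dual": truth.expected_n_dual,
        "expected_n_dual_near_mito": truth.expected_n_dual_near_mito,
        "n_mito_segments": len(truth.mito_segments),
        "mito_potentials": [s.potential for s in truth.mito_segments],
        "valid": truth.valid,
        "rejection_reason": truth.rejection_reason,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def objects_frame(objects: Sequence[PunctaObject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [o.id for o in objects],
            "channel": [o.channel for o in objects],
            "area_px": [o.area_px for o in objects],
            "centroid_row": [o.centroid[0] for o in objects],
            "centroid_col": [o.centroid[1] for o in objects],
            "mean_intensity": [o.mean_intensity for o in objects],
            "max_intensity": [o.max_intensity for o in objects],
        }
    )


def label_map(objects: Sequence[PunctaObject], shape: tuple[int, int]) -> np.ndarray:
    """16-bit label image with each object's pixels set to its 1-based index."""
    out = np.zeros(shape, dtype=np.uint16)
    for k, obj in enumerate(objects, start=1):
        out[obj.pixels[:, 0], obj.pixels[:, 1]] = k
    return out


def duals_frame(duals: Sequence[DualPuncta], records: Sequence[AssociationRecord]) -> pd.DataFrame:
    by_id = {r.dual_id: r for r in records}
    return pd.DataFrame(
        {
            "id": [d.id for d in duals],
            "area_px": [d.area_px for d in duals],
            "centroid_row": [d.centroid[0] for d in duals],
            "centroid_col": [d.centroid[1] for d in duals],
            "edge_distance_px": [
                by_id[d.id].edge_distance_px if d.id in by_id else np.nan for d in duals
            ],
            "associated": [by_id[d.id].associated if d.id in by_id else False for d in duals],
        }
    )


def summaries_frame(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(s) for s in summaries])
    if not df.empty:
        df["fraction_near_mito"] = [s.fraction_near_mito for s in summaries]
    return df


def qc_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def ratios_frame(records: Sequence[RatioRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
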