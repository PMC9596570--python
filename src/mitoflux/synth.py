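"""Synthetic fluorescence-microscopy scenes with ground truth.

This module renders the kind of data the analysis pipeline assumes: a
single bright, roughly elliptical cell on a dark background; diffuse
cytosolic LC3 fluorescence in the GFP and mRFP channels carrying isotropic
Gaussian puncta (GFP-only, mRFP-only, and coincident dual puncta); a
tubular mitochondrial network whose per-segment intensity encodes membrane
potential; and Poisson + Gaussian camera noise.  Every scene comes with a
:class:`GroundTruth` record, so that detection, association and ratio
statistics can be validated against construction rather than against other
software.

Design notes
------------
* Puncta are isotropic 2-D Gaussians truncated at 4 sigma — the same spot
  model the LoG detector assumes.
* The cell boundary is smoothed with a Gaussian falloff (``cell_edge_sigma_px``)
  to emulate the gradual falloff of diffuse cytosolic signal; a hard step
  edge would be an artifact no confocal image shows.
* Mitochondrial segments are dilated random-walk polylines, mutually
  separated so each segment is one connected component.
* "Near mito" dual puncta are centred on a mitochondrial pixel (edge
  distance 0); "far" puncta are kept at edge distance well beyond the
  association cutoff, so ground-truth association flags are unambiguous
  under the same edge-distance metric the measurement uses.
* Peak amplitudes are expressed as a peak signal-to-noise ratio against the
  background noise SD ``sqrt(gain * background + read_sd**2)`` (or
  ``sqrt(background)`` for noise-free renders), so SNR is an explicit dial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .scene import CHANNELS, DEFAULT_PIXEL_SIZE_NM, Scene

#: Association cutoff (px) shared with the association module; ground truth
#: uses the same value so expected counts match the measurement definition.
ASSOCIATION_CUTOFF_PX = 5.0


class PlacementError(RuntimeError):
    """Raised when puncta cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene.

    The seed fully determines the output; two calls with the same spec are
    bit-identical.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    cell_center: tuple[float, float] | None = None  # None -> image centre
    cell_axes: tuple[float, float] = (100.0, 80.0)  # semi-axes, px
    cell_orientation: float = 0.0  # radians
    cytosol_level: dict[str, float] = field(
        default_factory=lambda: {"gfp": 40.0, "rfp": 40.0, "mito": 6.0}
    )
    outside_level: float = 2.0
    cell_edge_sigma_px: float = 10.0
    n_gfp_only: int = 5
    n_rfp_only: int = 5
    n_dual: int = 10
    puncta_sigma_px: float = 3.0
    puncta_peak_snr: float = 6.0
    puncta_min_sep_px: float = 16.0
    placement_margin_px: float = 20.0
    frac_near_mito: float = 0.5
    near_segment_ids: tuple[int, ...] | None = None
    far_edge_distance_px: float = 12.0
    mito_n_segments: int = 6
    mito_width_px: float = 5.0
    mito_segment_length_px: int = 60
    mito_base_intensity: float = 150.0
    mito_potential_range: tuple[float, float] = (0.5, 1.0)
    mito_potentials: tuple[float, ...] | None = None
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_gfp_only, self.n_rfp_only, self.n_dual) < 0:
            raise ValueError("puncta counts must be >= 0")
        if not 0.0 <= self.frac_near_mito <= 1.0:
            raise ValueError("frac_near_mito must be in [0, 1]")
        if self.mito_potentials is not None and len(self.mito_potentials) != self.mito_n_segments:
            raise ValueError("mito_potentials length must equal mito_n_segments")
        lo, hi = self.mito_potential_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("mito_potential_range must lie in (0, 1]")

    @property
    def noise_enabled(self) -> bool:
        return self.poisson_gain > 0 or self.read_noise_sd > 0

    def background_noise_sd(self, channel: str) -> float:
        """Reference noise SD at the cytosolic background of a channel."""
        level = self.cytosol_level[channel]
        var = self.poisson_gain * level + self.read_noise_sd**2
        if var <= 0:
            var = level  # shot-noise-limited equivalent for noise-free renders
        return math.sqrt(var)


@dataclass(frozen=True)
class TimelapseSpec:
    """A time series of Z-stacks built from one base SceneSpec.

    The cell translates by ``drift_px_per_frame`` per timepoint; puncta
    jitter independently by ``puncta_motion_px`` per timepoint.  Z-slices
    within a timepoint share geometry and differ only in noise realisation.
    """

    scene: SceneSpec
    n_timepoints: int = 5
    n_zslices: int = 7
    z_spacing_nm: float = 500.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    puncta_motion_px: float = 0.0
    # ground-truth invalidity margin: the segmentation stage dilates its mask
    # by 8 px (4 x radius 2) on top of a ~2 px segmentation overshoot, so a
    # cell whose true outline comes within ~10 px of the border will be
    # border-rejected by the pipeline
    border_margin_px: float = 10.0

    def __post_init__(self) -> None:
        if self.n_zslices < 1:
            raise ValueError("n_zslices must be >= 1")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")


@dataclass
class TruthPunctum:
    """Ground truth for one rendered punctum."""

    id: int
    kind: str  # "gfp", "rfp", or "dual"
    center: tuple[float, float]
    sigma: float
    amplitude: dict[str, float]
    near_mito: bool | None = None  # set for dual puncta only

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        """(n, 2) pixel coordinates of a disk of radius 2*sigma at the centre.

        This nominal footprint stands in for the detected object's pixel set
        when ground-truth edge distances are computed.
        """
        r = int(math.ceil(2 * self.sigma))
        cr, cc = self.center
        rows = np.arange(max(0, int(cr) - r), min(shape[0], int(cr) + r + 1))
        cols = np.arange(max(0, int(cc) - r), min(shape[1], int(cc) + r + 1))
        rr, cc_ = np.meshgrid(rows, cols, indexing="ij")
        keep = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r**2
        return np.column_stack([rr[keep], cc_[keep]])


@dataclass
class TruthMitoSegment:
    """Ground truth for one mitochondrial segment (connected tubule)."""

    id: int
    pixels: np.ndarray  # (n, 2) int coordinates
    potential: float


@dataclass
class GroundTruth:
    """Everything needed to score a detection result against construction."""

    puncta: list[TruthPunctum]
    mito_segments: list[TruthMitoSegment]
    cell_mask: np.ndarray
    expected_n_dual: int
    expected_n_dual_near_mito: int
    valid: bool = True
    rejection_reason: str = "none"

    def dual_puncta(self) -> list[TruthPunctum]:
        return [p for p in self.puncta if p.kind == "dual"]


# ----------------------------------------------------------------------
# geometry helpers


def _ellipse_distance_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
) -> np.ndarray:
    """Normalised squared ellipse coordinate: <= 1 inside the cell."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    cos, sin = math.cos(orientation), math.sin(orientation)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2


def cell_ellipse_mask(spec: SceneSpec, center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of the ground-truth cell ellipse."""
    if center is None:
        center = spec.cell_center or (spec.image_size[0] / 2, spec.image_size[1] / 2)
    field_ = _ellipse_distance_field(spec.image_size, center, spec.cell_axes, spec.cell_orientation)
    return field_ <= 1.0


def _render_gaussian(img: np.ndarray, center: tuple[float, float], sigma: float, amplitude: float) -> None:
    """Add an isotropic Gaussian truncated at 4 sigma, in place."""
    r = int(math.ceil(4 * sigma))
    cr, cc = center
    r0, r1 = max(0, int(cr) - r), min(img.shape[0], int(cr) + r + 1)
    c0, c1 = max(0, int(cc) - r), min(img.shape[1], int(cc) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
    patch = amplitude * np.exp(-d2 / (2 * sigma**2))
    patch[d2 > (4 * sigma) ** 2] = 0.0
    img[r0:r1, c0:c1] += patch


def _draw_mito_segments(
    spec: SceneSpec,
    center: tuple[float, float],
    rng: np.random.Generator,
) -> list[TruthMitoSegment]:
    """Dilated random-walk polylines, mutually separated, inside the cell."""
    shape = spec.image_size
    inner = _ellipse_distance_field(
        shape,
        center,
        (spec.cell_axes[0] - spec.placement_margin_px, spec.cell_axes[1] - spec.placement_margin_px),
        spec.cell_orientation,
    ) <= 1.0
    half_w = max(1, int(round(spec.mito_width_px / 2)))
    sep = 10  # min gap (px) between tubules so segments stay disjoint objects
    occupied = np.zeros(shape, dtype=bool)
    segments: list[TruthMitoSegment] = []
    potentials = spec.mito_potentials
    free = inner.copy()  # walkable region: inner cell minus clearance of placed tubules
    for seg_id in range(spec.mito_n_segments):
        for _ in range(800):
            start = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
            if not free[int(start[0]), int(start[1])]:
                continue
            angle = rng.uniform(0, 2 * math.pi)
            pts = [start]
            pos = np.array(start)
            ok = True
            for _ in range(spec.mito_segment_length_px):
                angle += rng.normal(0, 0.25)
                stepped = False
                for _turn in range(8):  # deflect rather than abort at obstacles
                    cand = pos + np.array([math.sin(angle), math.cos(angle)])
                    r_i, c_i = int(cand[0]), int(cand[1])
                    if 0 <= r_i < shape[0] and 0 <= c_i < shape[1] and free[r_i, c_i]:
                        pos = cand
                        stepped = True
                        break
                    angle += math.pi / 2
                if not stepped:
                    ok = False
                    break
                pts.append(tuple(pos))
            if not ok:
                continue
            skel = np.zeros(shape, dtype=bool)
            for pr, pc in pts:
                skel[int(round(pr)), int(round(pc))] = True
            tube = ndimage.binary_dilation(skel, structure=_disk(half_w))
            clearance = ndimage.binary_dilation(tube, structure=_disk(sep))
            if (clearance & occupied).any():
                continue
            occupied |= tube
            free &= ~ndimage.binary_dilation(clearance, structure=_disk(half_w + 1))
            pix = np.argwhere(tube)
            if potentials is not None:
                pot = float(potentials[seg_id])
            else:
                pot = float(rng.uniform(*spec.mito_potential_range))
            segments.append(TruthMitoSegment(id=seg_id, pixels=pix, potential=pot))
            break
        else:
            raise PlacementError(f"could not place mitochondrial segment {seg_id}")
    return segments


def _disk(radius: int) -> np.ndarray:
    size = 2 * radius + 1
    rr, cc = np.meshgrid(np.arange(size) - radius, np.arange(size) - radius, indexing="ij")
    return rr**2 + cc**2 <= radius**2


def _place_puncta(
    spec: SceneSpec,
    center: tuple[float, float],
    segments: list[TruthMitoSegment],
    rng: np.random.Generator,
) -> list[TruthPunctum]:
    """Sample punctum centres satisfying separation and mito constraints."""
    shape = spec.image_size
    margin = spec.placement_margin_px
    inner = _ellipse_distance_field(
        shape, center, (spec.cell_axes[0] - margin, spec.cell_axes[1] - margin), spec.cell_orientation
    ) <= 1.0
    if not inner.any():
        raise PlacementError("cell too small for the placement margin")
    inner_pts = np.argwhere(inner)

    mito_mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        mito_mask[seg.pixels[:, 0], seg.pixels[:, 1]] = True
    # distance (px) from each pixel to the nearest mitochondrial pixel
    mito_dist = (
        ndimage.distance_transform_edt(~mito_mask) if mito_mask.any() else np.full(shape, np.inf)
    )
    r_gt = math.ceil(2 * spec.puncta_sigma_px)  # nominal footprint radius
    far_min = spec.far_edge_distance_px + r_gt + ASSOCIATION_CUTOFF_PX

    near_ids = spec.near_segment_ids
    near_pool: np.ndarray | None = None
    if segments:
        pool_segs = segments if near_ids is None else [s for s in segments if s.id in near_ids]
        if pool_segs:
            near_pool = np.vstack([s.pixels for s in pool_segs])

    n_near = int(round(spec.frac_near_mito * spec.n_dual))
    if n_near > 0 and near_pool is None:
        raise PlacementError("frac_near_mito > 0 but no mitochondrial segments to attach to")

    placed: list[TruthPunctum] = []
    centers: list[tuple[float, float]] = []
    budget = 2000 * max(1, spec.n_gfp_only + spec.n_rfp_only + spec.n_dual)

    def try_place(kind: str, near: bool | None, pid: int) -> None:
        nonlocal budget
        while budget > 0:
            budget -= 1
            if near:
                idx = rng.integers(len(near_pool))
                cand = (float(near_pool[idx, 0]), float(near_pool[idx, 1]))
                if not inner[int(cand[0]), int(cand[1])]:
                    continue
            else:
                idx = rng.integers(len(inner_pts))
                cand = (
                    float(inner_pts[idx, 0]) + rng.uniform(-0.5, 0.5),
                    float(inner_pts[idx, 1]) + rng.uniform(-0.5, 0.5),
                )
                if near is False and mito_dist[int(cand[0]), int(cand[1])] < far_min:
                    continue
            if any(
                (cand[0] - pr) ** 2 + (cand[1] - pc) ** 2 < spec.puncta_min_sep_px**2
                for pr, pc in centers
            ):
                continue
            amp = {
                ch: spec.puncta_peak_snr * spec.background_noise_sd(ch)
                for ch in ("gfp", "rfp")
            }
            if kind == "gfp":
                amp = {"gfp": amp["gfp"]}
            elif kind == "rfp":
                amp = {"rfp": amp["rfp"]}
            placed.append(
                TruthPunctum(
                    id=pid,
                    kind=kind,
                    center=cand,
                    sigma=spec.puncta_sigma_px,
                    amplitude=amp,
                    near_mito=near if kind == "dual" else None,
                )
            )
            centers.append(cand)
            return
        raise PlacementError("puncta placement retry budget exhausted")

    pid = 0
    for i in range(spec.n_dual):
        try_place("dual", i < n_near, pid)
        pid += 1
    for _ in range(spec.n_gfp_only):
        try_place("gfp", None, pid)
        pid += 1
    for _ in range(spec.n_rfp_only):
        try_place("rfp", None, pid)
        pid += 1
    return placed


# ----------------------------------------------------------------------
# rendering


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if not spec.noise_enabled:
        return img
    out = img
    if spec.poisson_gain > 0:
        out = spec.poisson_gain * rng.poisson(np.clip(out, 0, None) / spec.poisson_gain)
    out = out.astype(float)
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _render(
    spec: SceneSpec,
    center: tuple[float, float],
    puncta: list[TruthPunctum],
    segments: list[TruthMitoSegment],
    rng: np.random.Generator,
    z_index: int = 0,
    timepoint: int = 0,
) -> Scene:
    shape = spec.image_size
    cell = cell_ellipse_mask(spec, center).astype(float)
    soft_cell = (
        ndimage.gaussian_filter(cell, spec.cell_edge_sigma_px) if spec.cell_edge_sigma_px > 0 else cell
    )
    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        base = spec.outside_level + (spec.cytosol_level[ch] - spec.outside_level) * soft_cell
        channels[ch] = base
    for seg in segments:
        channels["mito"][seg.pixels[:, 0], seg.pixels[:, 1]] += spec.mito_base_intensity * seg.potential
    channels["mito"] = ndimage.gaussian_filter(channels["mito"], 1.0)
    for p in puncta:
        for ch, amp in p.amplitude.items():
            _render_gaussian(channels[ch], p.center, p.sigma, amp)
    for ch in CHANNELS:
        channels[ch] = _apply_noise(channels[ch], spec, rng)
    return Scene(
        channels=channels,
        pixel_size_nm=spec.pixel_size_nm,
        z_index=z_index,
        timepoint=timepoint,
    )


def _ground_truth(
    spec: SceneSpec,
    center: tuple[float, float],
    puncta: list[TruthPunctum],
    segments: list[TruthMitoSegment],
    border_margin_px: float = 0.0,
) -> GroundTruth:
    from .associate import min_edge_distance  # shared edge-distance metric

    shape = spec.image_size
    mask = cell_ellipse_mask(spec, center)
    n_dual = sum(p.kind == "dual" for p in puncta)
    n_near = 0
    for p in puncta:
        if p.kind != "dual":
            continue
        fp = p.footprint(shape)
        d = min(
            (min_edge_distance(fp, seg.pixels) for seg in segments),
            default=math.inf,
        )
        near = d <= ASSOCIATION_CUTOFF_PX
        p.near_mito = near
        n_near += near
    valid = True
    reason = "none"
    if border_margin_px >= 0 and mask.any():
        pix = np.argwhere(mask)
        m = border_margin_px
        if (
            pix[:, 0].min() <= m
            or pix[:, 1].min() <= m
            or pix[:, 0].max() >= shape[0] - 1 - m
            or pix[:, 1].max() >= shape[1] - 1 - m
        ):
            valid = False
            reason = "touches_border"
    return GroundTruth(
        puncta=puncta,
        mito_segments=segments,
        cell_mask=mask,
        expected_n_dual=n_dual,
        expected_n_dual_near_mito=n_near,
        valid=valid,
        rejection_reason=reason,
    )


def simulate_scene(spec: SceneSpec) -> tuple[GroundTruth, Scene]:
    """Render one scene and its ground truth.

    Dual puncta are rendered at identical coordinates in the GFP and mRFP
    channels; the mitochondrial channel intensity of each segment equals the
    base intensity times that segment's potential multiplier; noise is
    applied last.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.cell_center or (spec.image_size[0] / 2, spec.image_size[1] / 2)
    segments = (
        _draw_mito_segments(spec, center, rng) if spec.mito_n_segments > 0 else []
    )
    puncta = _place_puncta(spec, center, segments, rng)
    scene = _render(spec, center, puncta, segments, rng)
    truth = _ground_truth(spec, center, puncta, segments)
    return truth, scene


def simulate_timelapse(spec: TimelapseSpec) -> tuple[list[GroundTruth], list[list[Scene]]]:
    """Render a drifting time series of Z-stacks.

    Returns one GroundTruth per timepoint and a nested list
    ``movie[t][z]`` of Scenes.  Geometry (cell position, puncta, mitochondria)
    is shared across the Z-slices of a timepoint; noise realisations are
    independent per slice.  A timepoint whose cell comes within
    ``border_margin_px`` of the image border is marked invalid in its ground
    truth — the margin anticipates the mask dilation the segmentation stage
    applies, so ground-truth validity and pipeline border rejection agree.
    """
    rng = np.random.default_rng(spec.scene.seed)
    base_center = spec.scene.cell_center or (
        spec.scene.image_size[0] / 2,
        spec.scene.image_size[1] / 2,
    )
    center = np.array(base_center, dtype=float)
    base = replace(spec.scene, cell_center=tuple(center))
    segments = _draw_mito_segments(base, tuple(center), rng) if base.mito_n_segments > 0 else []
    puncta = _place_puncta(base, tuple(center), segments, rng)

    truths: list[GroundTruth] = []
    movie: list[list[Scene]] = []
    for t in range(spec.n_timepoints):
        if t > 0:
            shift = np.array(spec.drift_px_per_frame, dtype=float)
            center = center + shift
            for seg in segments:
                seg.pixels = seg.pixels + np.round(shift).astype(int)
            for p in puncta:
                jitter = (
                    rng.normal(0, spec.puncta_motion_px, size=2)
                    if spec.puncta_motion_px > 0
                    else np.zeros(2)
                )
                p.center = (p.center[0] + shift[0] + jitter[0], p.center[1] + shift[1] + jitter[1])
        shape = spec.scene.image_size
        kept_segments = [
            TruthMitoSegment(
                id=s.id,
                pixels=s.pixels[
                    (s.pixels[:, 0] >= 0)
                    & (s.pixels[:, 0] < shape[0])
                    & (s.pixels[:, 1] >= 0)
                    & (s.pixels[:, 1] < shape[1])
                ],
                potential=s.potential,
            )
            for s in segments
        ]
        frame_spec = replace(spec.scene, cell_center=(float(center[0]), float(center[1])))
        import copy

        truth = _ground_truth(
            frame_spec,
            tuple(center),
            copy.deepcopy(puncta),
            kept_segments,
            border_margin_px=spec.border_margin_px,
        )
        truths.append(truth)
        stack = [
            _render(frame_spec, tuple(center), puncta, kept_segments, rng, z_index=z, timepoint=t)
            for z in range(spec.n_zslices)
        ]
        movie.append(stack)
    return truths, movie
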