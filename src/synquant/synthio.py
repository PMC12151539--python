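"""Seeded synthetic images and traces with exact ground truth.

Every input class consumed by the analysis modules can be emulated here:

- two-channel eye-territory images with a controllable true overlap
  fraction (`gen_territory_image`);
- 3D stacks of blobby glial cells with engulfed tracer puncta in two
  tracer channels (`gen_engulfment_stack`);
- pre/post synaptic punctum fields with a controllable paired fraction
  (`gen_puncta_stack`);
- electrophysiology: EPSC staircases from serial fiber recruitment
  (`gen_epsc_staircase`), Poisson mEPSC trains (`gen_mepsc_trace`), and
  paired-pulse trials (`gen_paired_pulse`).

Ground truths are computed from the generated geometry or event lists
*before* blur and noise are applied, never re-estimated from the rendered
data.  Identical seed and parameters give bit-identical outputs: each
generator owns a single RNG stream derived from the seed and a fixed
per-component offset, so regenerating one component never perturbs
another.

Default image noise is Poisson shot noise on the signal plus additive
Gaussian read noise; both are configurable through :class:`NoiseModel`.
Distances and volumes are always in micrometres (anisotropic voxels are
first-class), never in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgseg import MultiChannelStack, VoxelGrid
from .segregation import DEFAULT_THRESHOLDS, PlanarImage

__all__ = [
    "NoiseModel",
    "TerritoryTruth",
    "EngulfmentTruth",
    "PunctaTruth",
    "EphysTruth",
    "Trace",
    "ResponseCurve",
    "gen_territory_image",
    "gen_engulfment_stack",
    "gen_puncta_stack",
    "gen_epsc_staircase",
    "gen_mepsc_trace",
    "gen_paired_pulse",
]

# Fixed per-component offsets: a single global seed expands into
# independent substreams, so regenerating one component is reproducible
# without touching the others.
_STREAMS = {
    "territory": 11,
    "engulfment": 23,
    "puncta": 37,
    "epsc": 53,
    "mepsc": 71,
    "paired_pulse": 89,
}


def _rng(component: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[component], int(seed)])


@dataclass
class NoiseModel:
    """Detector model: baseline offset + Poisson shot noise + read noise.

    ``offset`` is a constant baseline added to the signal before noise
    (so the read-noise floor is not half-rectified by the detector's
    non-negativity); ``poisson_scale`` is the expected photon count per
    intensity unit (0 disables shot noise); ``gaussian_sd`` is the
    read-noise standard deviation in intensity units.
    """

    gaussian_sd: float = 2.0
    poisson_scale: float = 2.0
    offset: float = 5.0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=np.float64) + self.offset
        if self.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


NOISELESS = NoiseModel(gaussian_sd=0.0, poisson_scale=0.0, offset=0.0)


# --------------------------------------------------------------------------
# Territory images
# --------------------------------------------------------------------------

@dataclass
class TerritoryTruth:
    """Ground truth for one synthetic territory image."""

    overlap_fraction_at: dict[float, float]
    contra_mask: np.ndarray
    ipsi_mask: np.ndarray
    overlap_target: float

    @property
    def overlap_fraction(self) -> float:
        """Intersection-over-ROI of the geometric truth masks."""
        return self._mask_overlap

    _mask_overlap: float = 0.0


_TERRITORY_AMPLITUDE = 100.0
_TERRITORY_OFFSET = 10.0


def gen_territory_image(
    shape_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.4,
    overlap_target: float = 0.3,
    noise_sd: float = 5.0,
    seed: int = 0,
    edge_sigma_px: float = 0.7,
) -> tuple[PlanarImage, TerritoryTruth]:
    """Render a two-channel dLGN-like image with known territory overlap.

    The dLGN ROI is an ellipse; the two eye territories are drawn as
    complementary bands with a smoothed random boundary, sized so that
    their intersection-over-ROI equals ``overlap_target`` (each territory
    covers the fraction ``(1 + overlap_target) / 2`` of the ROI, so the
    intersection covers ``overlap_target``).  Channels are rendered at a
    constant signal amplitude over a constant background offset with
    additive Gaussian noise of ``noise_sd``; a signal-free corner region
    provides the background mask.
    """
    h, w = shape_px
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64x64")
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must lie in [0, 1]")
    rng = _rng("territory", seed)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    roi = ((yy - cy) / (0.36 * h)) ** 2 + ((xx - cx) / (0.40 * w)) ** 2 <= 1.0

    # Background box in the top-left corner, outside the ellipse.
    bh, bw = max(8, h // 10), max(8, w // 10)
    background = np.zeros((h, w), dtype=bool)
    background[2 : 2 + bh, 2 : 2 + bw] = True
    background &= ~roi

    # Smoothed random boundary: order ROI pixels by x plus a smooth jitter
    # field and cut at quantiles, so the intersection fraction is exact to
    # within a pixel.
    jitter = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=w / 16.0)
    jitter *= (0.08 * w) / max(jitter.std(), 1e-9)
    key = xx.astype(float) + jitter
    keys_roi = key[roi]
    f = (1.0 + overlap_target) / 2.0
    q_hi = np.quantile(keys_roi, f)
    q_lo = np.quantile(keys_roi, 1.0 - f)
    contra_mask = roi & (key <= q_hi)
    ipsi_mask = roi & (key >= q_lo)

    n_roi = int(roi.sum())
    mask_overlap = float((contra_mask & ipsi_mask).sum()) / n_roi

    def render(mask: np.ndarray) -> np.ndarray:
        sig = _TERRITORY_AMPLITUDE * ndimage.gaussian_filter(
            mask.astype(float), sigma=edge_sigma_px
        )
        img = sig + _TERRITORY_OFFSET
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    clean_c = _TERRITORY_AMPLITUDE * ndimage.gaussian_filter(contra_mask.astype(float), edge_sigma_px)
    clean_i = _TERRITORY_AMPLITUDE * ndimage.gaussian_filter(ipsi_mask.astype(float), edge_sigma_px)
    norm_c = clean_c / max(clean_c[roi].max(), 1e-9)
    norm_i = clean_i / max(clean_i[roi].max(), 1e-9)
    overlap_at = {
        float(t): float(((norm_c[roi] >= t) & (norm_i[roi] >= t)).sum()) / n_roi
        for t in DEFAULT_THRESHOLDS
    }

    image = PlanarImage(
        contra=render(contra_mask),
        ipsi=render(ipsi_mask),
        pixel_size_um=pixel_size_um,
        dlgn_mask=roi,
        background_mask=background,
    )
    truth = TerritoryTruth(overlap_at, contra_mask, ipsi_mask, overlap_target)
    truth._mask_overlap = mask_overlap
    return image, truth


# --------------------------------------------------------------------------
# Engulfment stacks
# --------------------------------------------------------------------------

@dataclass
class EngulfmentTruth:
    """Ground truth for a synthetic engulfment stack."""

    cell_labels: np.ndarray
    cell_volume_um3: dict[int, float]
    engulfed_volume_um3: dict[tuple[int, str], float]
    punctum_centers_um: dict[str, np.ndarray] = field(default_factory=dict)

    def engulfed(self, cell_id: int, channel: str) -> float:
        return self.engulfed_volume_um3.get((cell_id, channel), 0.0)


_CELL_AMPLITUDE = 100.0
_PUNCTUM_AMPLITUDE = 100.0


def _paint_ball(
    target: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    voxel_size_um: tuple[float, ...],
    value: float,
) -> int:
    """Set voxels whose centres lie within ``radius_um`` of ``center_um``.

    Returns the number of voxels painted.  ``center_um`` is in physical
    (z, y, x) coordinates; voxel (k, j, i) has centre ((k+0.5)dz, ...).
    """
    vsz = np.asarray(voxel_size_um)
    lo = np.maximum(0, np.floor((center_um - radius_um) / vsz - 0.5).astype(int))
    hi = np.minimum(target.shape, np.ceil((center_um + radius_um) / vsz + 0.5).astype(int))
    if np.any(lo >= hi):
        return 0
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    dist2 = sum(
        ((g + 0.5) * vsz[ax] - center_um[ax]) ** 2 for ax, g in enumerate(grids)
    )
    sel = dist2 <= radius_um**2
    sub = target[tuple(slice(a, b) for a, b in zip(lo, hi))]
    sub[sel] = value
    return int(sel.sum())


def gen_engulfment_stack(
    shape_px: tuple[int, int, int] = (64, 256, 256),
    voxel_size_um: tuple[float, float, float] = (0.4, 0.2, 0.2),
    n_cells: int = 5,
    puncta_per_cell: dict[str, int] | None = None,
    punctum_radius_um: float = 0.8,
    outside_puncta_density: float = 5e-4,
    psf_sigma_um: float = 0.1,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    cell_channel: str = "cells",
    sphere_radius_um: tuple[float, float] = (2.0, 6.0),
    spheres_per_cell: tuple[int, int] = (5, 15),
    max_cell_extent_um: float = 7.0,
) -> tuple[MultiChannelStack, EngulfmentTruth]:
    """Render a glial-engulfment stack with analytic ground truth.

    Cells are unions of 5-15 spheres (radius 2-6 um) jittered around a
    soma centre, capped at ``max_cell_extent_um`` radial extent, and placed
    without touching (centre separation > 2x extent + 1 um; an error is
    raised after 1000 failed placement attempts).  Tracer puncta of radius
    ``punctum_radius_um`` are placed fully inside designated cells
    (engulfed; analytic sphere volume recorded per cell and channel) and as
    background neuropil puncta outside every cell at
    ``outside_puncta_density`` per um^3.  All channels are blurred with a
    Gaussian PSF and corrupted by ``noise_model``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if puncta_per_cell is None:
        puncta_per_cell = {"ch_R": 3, "ch_L": 3}
    noise_model = NoiseModel() if noise_model is None else noise_model
    rng = _rng("engulfment", seed)
    vsz = np.asarray(voxel_size_um, dtype=float)
    extent_um = np.asarray(shape_px) * vsz  # (z, y, x) physical extent

    # --- place soma centres (non-touching cells) ---
    margin = max_cell_extent_um + 0.5
    if np.any(extent_um <= 2 * margin):
        raise ValueError("stack too small for the requested cell geometry")
    min_sep = 2 * max_cell_extent_um + 1.0
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                f"could not place {n_cells} non-touching cells in 1000 attempts"
            )
        c = rng.uniform(margin, extent_um - margin)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)

    # --- render cell label grid from sphere unions ---
    labels = np.zeros(shape_px, dtype=np.int32)
    for cid, soma in enumerate(centers, start=1):
        n_sph = int(rng.integers(spheres_per_cell[0], spheres_per_cell[1] + 1))
        # Soma sphere first, then jittered process spheres.
        _paint_ball(labels, soma, min(sphere_radius_um[1], max_cell_extent_um * 0.6),
                    voxel_size_um, cid)
        for _ in range(n_sph - 1):
            offset = rng.normal(0.0, 2.0, size=3)
            r = float(rng.uniform(*sphere_radius_um))
            # Cap radial extent so cells stay within the placement envelope.
            reach = np.linalg.norm(offset) + r
            if reach > max_cell_extent_um:
                scale = max_cell_extent_um / reach
                offset = offset * scale
                r = r * scale
            if r >= min(vsz):
                _paint_ball(labels, soma + offset, r, voxel_size_um, cid)

    voxel_volume = float(np.prod(vsz))
    counts = np.bincount(labels.ravel(), minlength=n_cells + 1)
    cell_volume = {cid: float(counts[cid]) * voxel_volume for cid in range(1, n_cells + 1)}

    # --- engulfed puncta: fully inside cells ---
    sphere_vol = 4.0 / 3.0 * np.pi * punctum_radius_um**3
    engulfed: dict[tuple[int, str], float] = {}
    centers_by_channel: dict[str, list[np.ndarray]] = {c: [] for c in puncta_per_cell}
    inside_depth = ndimage.distance_transform_edt(labels > 0, sampling=vsz)
    for cid in range(1, n_cells + 1):
        deep = np.argwhere((labels == cid) & (inside_depth > punctum_radius_um + 0.1))
        if deep.size == 0 and any(n > 0 for n in puncta_per_cell.values()):
            raise RuntimeError(f"cell {cid} too thin to host engulfed puncta")
        placed_cell: list[np.ndarray] = []
        for channel, n_puncta in puncta_per_cell.items():
            engulfed[(cid, channel)] = 0.0
            for _ in range(n_puncta):
                for _try in range(200):
                    vox = deep[rng.integers(len(deep))]
                    # Sub-voxel jitter keeps voxelized sphere volumes
                    # unbiased against the analytic truth.
                    c = (vox + rng.uniform(0.0, 1.0, size=3)) * vsz
                    if all(
                        np.linalg.norm(c - o) >= 2 * punctum_radius_um + 0.2
                        for o in placed_cell
                    ):
                        break
                else:
                    raise RuntimeError(
                        f"could not place punctum inside cell {cid}"
                    )
                placed_cell.append(c)
                centers_by_channel[channel].append(c)
                engulfed[(cid, channel)] += sphere_vol

    # --- background neuropil puncta: fully outside every cell ---
    outside_dist = ndimage.distance_transform_edt(labels == 0, sampling=vsz)
    free = np.argwhere(outside_dist > punctum_radius_um + 0.5)
    outside_volume = voxel_volume * len(free)
    for channel in puncta_per_cell:
        n_out = int(rng.poisson(outside_puncta_density * outside_volume))
        for _ in range(n_out):
            vox = free[rng.integers(len(free))]
            centers_by_channel[channel].append((vox + rng.uniform(0.0, 1.0, size=3)) * vsz)

    # --- render channels ---
    sigma_vox = tuple(psf_sigma_um / v for v in vsz)

    def finish(img: np.ndarray) -> np.ndarray:
        if psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        return noise_model.apply(img, rng)

    channels: dict[str, VoxelGrid] = {}
    cell_img = np.where(labels > 0, _CELL_AMPLITUDE, 0.0)
    channels[cell_channel] = VoxelGrid(finish(cell_img), voxel_size_um, cell_channel)
    for channel, pts in centers_by_channel.items():
        img = np.zeros(shape_px, dtype=np.float64)
        for c in pts:
            _paint_ball(img, np.asarray(c), punctum_radius_um, voxel_size_um,
                        _PUNCTUM_AMPLITUDE)
        channels[channel] = VoxelGrid(finish(img), voxel_size_um, channel)

    truth = EngulfmentTruth(
        cell_labels=labels,
        cell_volume_um3=cell_volume,
        engulfed_volume_um3=engulfed,
        punctum_centers_um={c: np.array(v).reshape(-1, 3) for c, v in centers_by_channel.items()},
    )
    return MultiChannelStack(channels), truth


# --------------------------------------------------------------------------
# Synaptic punctum fields
# --------------------------------------------------------------------------

@dataclass
class PunctaTruth:
    """Ground truth for a pre/post punctum field (centres in um, (x,y,z))."""

    pre_centers: np.ndarray
    post_centers: np.ndarray
    paired_flags: np.ndarray

    @property
    def n_true_pairs(self) -> int:
        return int(self.paired_flags.sum())


def _uniform_points(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_dist: float = 0.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample points with mutual and exclusion-zone constraints."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "rejection sampling failed: requested density too high for "
                "the separation constraints"
            )
        p = rng.uniform(lo, hi)
        if pts and min(np.linalg.norm(p - q) for q in pts) < min_sep:
            continue
        if avoid is not None and len(avoid) and (
            np.min(np.linalg.norm(avoid - p, axis=1)) < avoid_dist
        ):
            continue
        pts.append(p)
    return np.array(pts).reshape(-1, 3)


def gen_puncta_stack(
    shape_px: tuple[int, int, int] = (16, 256, 256),
    voxel_size_um: tuple[float, float, float] = (0.25, 0.1, 0.1),
    n_pre: int = 120,
    n_post: int = 120,
    paired_fraction: float = 0.5,
    pair_distance_um: float = 0.15,
    pairing_threshold_um: float = 0.3,
    punctum_dims_um: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 0.85), (0.4, 0.8)),
    psf_sigma_um: float = 0.08,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    min_separation_um: float = 1.0,
) -> tuple[MultiChannelStack, PunctaTruth]:
    """Render a pre/post synaptic punctum field with known pairing.

    Post-puncta are split into a paired set, each placed at
    ``pair_distance_um`` from a distinct pre-punctum in a random
    orientation, and an unpaired set rejection-sampled to lie at least
    ``2 * pairing_threshold_um`` from every pre-punctum, so the truth
    pairing is unambiguous under the downstream center-distance criterion.
    ``punctum_dims_um`` gives the (xy, z) ellipsoid *diameters* for the
    pre and post channels.  Channels are named ``"pre"`` and ``"post"``.
    """
    if paired_fraction > 0 and pair_distance_um >= pairing_threshold_um:
        raise ValueError("pair_distance_um must be below the pairing threshold")
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must lie in [0, 1]")
    noise_model = NoiseModel() if noise_model is None else noise_model
    rng = _rng("puncta", seed)
    vsz = np.asarray(voxel_size_um, dtype=float)
    extent = np.asarray(shape_px) * vsz
    margin = 1.0
    lo, hi = np.full(3, margin), extent - margin
    if np.any(lo >= hi):
        raise ValueError("stack too small for the 1 um placement margin")

    pre = _uniform_points(rng, n_pre, lo, hi, min_separation_um)

    n_paired = int(round(paired_fraction * n_post))
    if n_paired > n_pre:
        raise ValueError("paired posts cannot exceed the number of pre-puncta")
    partners = rng.choice(n_pre, size=n_paired, replace=False)
    paired_posts = []
    for k in partners:
        for _ in range(100):
            v = rng.standard_normal(3)
            v *= pair_distance_um / np.linalg.norm(v)
            p = pre[k] + v
            if np.all(p > lo) and np.all(p < hi):
                break
        paired_posts.append(p)
    paired_posts = np.array(paired_posts).reshape(-1, 3)

    unpaired_posts = _uniform_points(
        rng, n_post - n_paired, lo, hi, min_separation_um * 0.8,
        avoid=pre, avoid_dist=2.0 * pairing_threshold_um,
    )
    post = np.concatenate([paired_posts, unpaired_posts], axis=0)
    flags = np.zeros(n_post, dtype=bool)
    flags[:n_paired] = True

    def render(centers_zyx: np.ndarray, dims: tuple[float, float]) -> np.ndarray:
        # Gaussian blobs whose FWHM is ~0.8x the stated ellipsoid diameter,
        # i.e. the stated size is the visible extent of the punctum.
        sigma_um = np.array([dims[1], dims[0], dims[0]]) / 3.0
        img = np.zeros(shape_px, dtype=np.float64)
        sigma_vox = sigma_um / vsz
        half = np.ceil(4 * sigma_vox).astype(int)
        for c in centers_zyx:
            cv = c / vsz - 0.5
            i0 = np.maximum(0, np.floor(cv - half).astype(int))
            i1 = np.minimum(shape_px, np.ceil(cv + half + 1).astype(int))
            grids = np.ogrid[tuple(slice(a, b) for a, b in zip(i0, i1))]
            d2 = sum(((g - cv[ax]) / sigma_vox[ax]) ** 2 for ax, g in enumerate(grids))
            img[tuple(slice(a, b) for a, b in zip(i0, i1))] += 100.0 * np.exp(-0.5 * d2)
        if psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=tuple(psf_sigma_um / v for v in vsz))
        return noise_model.apply(img, rng)

    channels = {
        "pre": VoxelGrid(render(pre, punctum_dims_um[0]), voxel_size_um, "pre"),
        "post": VoxelGrid(render(post, punctum_dims_um[1]), voxel_size_um, "post"),
    }

    def to_xyz(a: np.ndarray) -> np.ndarray:
        return a[:, ::-1].copy() if len(a) else a.reshape(0, 3)

    truth = PunctaTruth(to_xyz(pre), to_xyz(post), flags)
    return MultiChannelStack(channels), truth


# --------------------------------------------------------------------------
# Electrophysiology
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """A current-clamp/voltage-clamp sweep (pA vs uniformly sampled time)."""

    samples_pA: np.ndarray
    sampling_hz: float
    holding_mV: float = -70.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples_pA)) / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples_pA) / self.sampling_hz


@dataclass
class ResponseCurve:
    """Stimulus -> peak EPSC amplitude series, polarity-folded to >= 0 nA."""

    points: list[tuple[float, float]]  # (stimulus_uA, peak_amplitude_nA)
    polarity: str = "inward"

    def __post_init__(self) -> None:
        stims = [s for s, _ in self.points]
        if any(b <= a for a, b in zip(stims, stims[1:])):
            raise ValueError("stimuli must be strictly increasing")

    @property
    def stimuli_uA(self) -> np.ndarray:
        return np.array([s for s, _ in self.points])

    @property
    def amplitudes_nA(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


@dataclass
class EphysTruth:
    """Ground truth shared by the electrophysiology generators."""

    n_inputs: int = 0
    step_amplitudes_nA: list[float] = field(default_factory=list)
    recruitment_thresholds_uA: list[float] = field(default_factory=list)
    mepsc_times_s: list[float] = field(default_factory=list)
    mepsc_amplitudes_pA: list[float] = field(default_factory=list)
    ppr_true: dict[int, float] = field(default_factory=dict)
    stim_times_s: dict[int, tuple[float, float]] = field(default_factory=dict)


def gen_epsc_staircase(
    n_inputs: int,
    step_amplitudes_nA: list[float] | None = None,
    stim_range_uA: tuple[float, float] = (0.0, 100.0),
    stim_step_uA: float = 0.5,
    noise_sd_nA: float = 0.02,
    seed: int = 0,
) -> tuple[ResponseCurve, EphysTruth]:
    """Simulate serial fiber recruitment as an EPSC staircase.

    Each input has a recruitment threshold drawn uniformly within
    ``stim_range_uA`` (redrawn until pairwise gaps exceed two stimulus
    steps, so every recruitment is resolvable on the stimulus grid) and a
    positive step amplitude.  The peak amplitude at stimulus ``s`` is the
    sum of step amplitudes of inputs with threshold <= s, plus Gaussian
    noise; the plateau is reached at the maximum stimulus.
    """
    if stim_step_uA <= 0:
        raise ValueError("stim_step_uA must be positive")
    if n_inputs < 0:
        raise ValueError("n_inputs must be >= 0")
    rng = _rng("epsc", seed)
    if step_amplitudes_nA is None:
        step_amplitudes_nA = list(rng.uniform(0.2, 1.2, size=n_inputs))
    if len(step_amplitudes_nA) != n_inputs:
        raise ValueError("need one step amplitude per input")
    if any(a <= 0 for a in step_amplitudes_nA):
        raise ValueError("step amplitudes must be positive")

    lo, hi = stim_range_uA
    span = hi - lo
    thresholds = np.array([])
    if n_inputs > 0:
        for _ in range(1000):
            thresholds = np.sort(rng.uniform(lo + 0.05 * span, hi - 0.05 * span, n_inputs))
            if n_inputs == 1 or np.min(np.diff(thresholds)) >= 2 * stim_step_uA:
                break
        else:
            raise RuntimeError("could not draw well-separated recruitment thresholds")

    stimuli = np.arange(lo, hi + 0.5 * stim_step_uA, stim_step_uA)
    steps = np.asarray(step_amplitudes_nA)
    amps = np.array([steps[thresholds <= s].sum() for s in stimuli])
    if noise_sd_nA > 0:
        amps = amps + rng.normal(0.0, noise_sd_nA, size=amps.shape)
    curve = ResponseCurve(list(zip(stimuli.tolist(), amps.tolist())))
    truth = EphysTruth(
        n_inputs=n_inputs,
        step_amplitudes_nA=[float(a) for a in steps],
        recruitment_thresholds_uA=[float(t) for t in thresholds],
    )
    return curve, truth


def _biexp_kernel(
    times_s: np.ndarray, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """Unit-peak biexponential transient (0 before t=0)."""
    if tau_rise_s >= tau_decay_s:
        raise ValueError("tau_rise must be below tau_decay")
    t = np.clip(times_s, 0.0, None)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    k[times_s < 0] = 0.0
    t_peak = (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
        * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return k / peak


def gen_mepsc_trace(
    duration_s: float = 180.0,
    rate_hz: float = 1.0,
    amplitude_range_pA: tuple[float, float] = (-40.0, -10.0),
    kinetics_ms: tuple[float, float] = (0.5, 4.0),
    noise_sd_pA: float = 1.5,
    sampling_hz: float = 20000.0,
    seed: int = 0,
) -> tuple[Trace, EphysTruth]:
    """Simulate a voltage-clamp mEPSC recording.

    Events follow a homogeneous Poisson process at ``rate_hz``; each event
    is a negative biexponential transient with rise/decay constants
    ``kinetics_ms`` and a peak amplitude drawn uniformly from
    ``amplitude_range_pA`` (negative = inward).  The truth records exact
    event times and peak amplitudes; Gaussian noise of ``noise_sd_pA`` is
    added on top.
    """
    if rate_hz < 0:
        raise ValueError("rate_hz must be >= 0")
    tau_r, tau_d = (k / 1000.0 for k in kinetics_ms)
    if tau_r >= tau_d:
        raise ValueError("tau_rise must be below tau_decay")
    rng = _rng("mepsc", seed)
    n_samples = int(round(duration_s * sampling_hz))
    trace = np.zeros(n_samples, dtype=np.float64)

    n_events = int(rng.poisson(rate_hz * duration_s))
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    amps = rng.uniform(amplitude_range_pA[0], amplitude_range_pA[1], size=n_events)
    if amps.size and np.any(amps >= 0):
        raise ValueError("generated mEPSC amplitudes must be negative (inward)")

    kern_len = int(round((8 * tau_d) * sampling_hz))
    kern = _biexp_kernel(np.arange(kern_len) / sampling_hz, tau_r, tau_d)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * sampling_hz))
        i1 = min(n_samples, i0 + kern_len)
        if i0 < n_samples:
            trace[i0:i1] += a * kern[: i1 - i0]
    if noise_sd_pA > 0:
        trace += rng.normal(0.0, noise_sd_pA, size=n_samples)

    truth = EphysTruth(
        mepsc_times_s=[float(t) for t in times],
        mepsc_amplitudes_pA=[float(a) for a in amps],
    )
    return Trace(trace, sampling_hz), truth


PPR_INTERVALS_MS: tuple[int, ...] = (50, 150, 250, 500, 1000)


def gen_paired_pulse(
    first_amp_nA: float = 1.0,
    ppr_by_interval: dict[int, float] | None = None,
    kinetics_ms: tuple[float, float] = (1.0, 20.0),
    noise_sd_pA: float = 5.0,
    sampling_hz: float = 20000.0,
    seed: int = 0,
    t_first_s: float = 0.1,
) -> tuple[dict[int, Trace], EphysTruth]:
    """Simulate paired-pulse trials at the standard inter-stimulus intervals.

    For each interval a trace contains two inward EPSC transients; the
    second kernel's own peak is ``ppr * first_amp`` so the intended ratio
    is exact by construction (the raw second peak additionally rides on the
    decay tail of the first response, which the analysis must remove).
    """
    if ppr_by_interval is None:
        ppr_by_interval = {ms: 0.7 for ms in PPR_INTERVALS_MS}
    if first_amp_nA <= 0:
        raise ValueError("first_amp_nA must be positive")
    tau_r, tau_d = (k / 1000.0 for k in kinetics_ms)
    if tau_r >= tau_d:
        raise ValueError("tau_rise must be below tau_decay")
    rng = _rng("paired_pulse", seed)

    traces: dict[int, Trace] = {}
    truth = EphysTruth(ppr_true={int(k): float(v) for k, v in ppr_by_interval.items()})
    amp_pA = first_amp_nA * 1000.0
    for interval_ms, ppr in ppr_by_interval.items():
        interval_s = interval_ms / 1000.0
        dur = t_first_s + interval_s + 0.4
        n = int(round(dur * sampling_hz))
        t = np.arange(n) / sampling_hz
        sweep = -amp_pA * _biexp_kernel(t - t_first_s, tau_r, tau_d)
        sweep += -ppr * amp_pA * _biexp_kernel(t - t_first_s - interval_s, tau_r, tau_d)
        if noise_sd_pA > 0:
            sweep = sweep + rng.normal(0.0, noise_sd_pA, size=n)
        traces[int(interval_ms)] = Trace(sweep, sampling_hz)
        truth.stim_times_s[int(interval_ms)] = (t_first_s, t_first_s + interval_s)
    return traces, truth
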