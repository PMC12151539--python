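"""Classical 2D/3D segmentation primitives for fluorescence stacks.

This module provides the low-level image operations the analysis pipelines
are built on: morphological background subtraction, histogram thresholding
(Otsu, manual, or log-histogram inflection), connected-component labeling,
voxel-count object filtering, and anisotropic ellipsoidal spot detection.

All physical quantities are in micrometres.  Image arrays are ordered
``(z, y, x)`` for 3D data and ``(y, x)`` for 2D data; voxel sizes follow the
same axis order.  The physical centre of voxel ``(k, j, i)`` is
``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)`` and all reported spot
positions are physical ``(x, y, z)`` coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelGrid",
    "MultiChannelStack",
    "Spot",
    "SpotSet",
    "SegParams",
    "subtract_background",
    "smooth",
    "threshold",
    "label_components",
    "filter_objects",
    "object_sizes",
    "detect_spots",
]

_AXIS_NAMES = {3: ("z", "y", "x"), 2: ("y", "x")}


@dataclass
class VoxelGrid:
    """A single intensity channel with physical voxel geometry.

    Parameters
    ----------
    data
        Non-negative scalar intensities, ``(z, y, x)`` or ``(y, x)``.
    voxel_size_um
        Edge lengths of one voxel per axis, same order as ``data`` axes.
    channel_name
        Free-form label (e.g. ``"iba1"``, ``"ctb647"``).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, ...]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if self.data.ndim not in (2, 3):
            raise ValueError("VoxelGrid data must be 2D or 3D")
        if len(self.voxel_size_um) != self.data.ndim:
            raise ValueError("voxel_size_um length must match data.ndim")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data, self.voxel_size_um, self.channel_name)


@dataclass
class MultiChannelStack:
    """Named channels sharing one voxel grid, plus optional ROI masks."""

    channels: dict[str, VoxelGrid]
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.channels.values()}
        sizes = {g.voxel_size_um for g in self.channels.values()}
        if len(shapes) > 1 or len(sizes) > 1:
            raise ValueError("all channels must share shape and voxel size")

    @property
    def voxel_size_um(self) -> tuple[float, ...]:
        return next(iter(self.channels.values())).voxel_size_um

    def __getitem__(self, name: str) -> VoxelGrid:
        return self.channels[name]


@dataclass
class Spot:
    """One detected ellipsoidal punctum (physical coordinates)."""

    center_um: tuple[float, float, float]  # (x, y, z); z = 0 for 2D images
    radii_um: tuple[float, float]  # (rxy, rz)
    total_intensity: float
    quality: float


@dataclass
class SpotSet:
    spots: list[Spot]

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    @property
    def centers_um(self) -> np.ndarray:
        """(N, 3) array of (x, y, z) centres in micrometres."""
        if not self.spots:
            return np.zeros((0, 3))
        return np.array([s.center_um for s in self.spots], dtype=float)


@dataclass
class SegParams:
    """Bundle of segmentation parameters used by the pipelines.

    Defaults mirror the engulfment workflow: a 1 um background-subtraction
    ball, 0.1 um smoothing grain, objects larger than 10 voxels kept.
    """

    ball_radius_um: float = 1.0
    smoothing_grain_um: float = 0.1
    min_voxels: int = 10
    max_voxels: int = 10**9
    connectivity: int = 26
    threshold_mode: str = "otsu"
    manual_value: float | None = None

    def __post_init__(self) -> None:
        if self.min_voxels >= self.max_voxels:
            raise ValueError("min_voxels must be < max_voxels")


def _radius_voxels(radius_um: float, voxel_size_um: tuple[float, ...]) -> tuple[int, ...]:
    names = _AXIS_NAMES[len(voxel_size_um)]
    out = []
    for name, dv in zip(names, voxel_size_um):
        r = radius_um / dv
        if r < 1.0:
            raise ValueError(
                f"ball radius {radius_um} um is smaller than one voxel "
                f"({dv} um) along axis {name!r}"
            )
        out.append(int(round(r)))
    return tuple(out)


def _ellipsoid_footprint(radii_vox: tuple[int, ...]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii_vox)]
    dist2 = sum((g / max(r, 1e-9)) ** 2 for g, r in zip(grids, radii_vox))
    return dist2 <= 1.0


def subtract_background(grid: VoxelGrid, ball_radius_um: float) -> VoxelGrid:
    """Rolling-ball style background subtraction (white top-hat).

    A flat ellipsoidal structuring element with physical radius
    ``ball_radius_um`` in every axis (converted per-axis to voxels) is used
    for a morphological opening; the opening is subtracted from the image.
    Structures broader than the ball (slow background) are removed, features
    smaller than the ball (puncta, processes) survive.
    """
    radii_vox = _radius_voxels(ball_radius_um, grid.voxel_size_um)
    footprint = _ellipsoid_footprint(radii_vox)
    opened = ndimage.grey_opening(grid.data, footprint=footprint, mode="nearest")
    return grid.with_data(np.clip(grid.data - opened, 0.0, None))


def smooth(grid: VoxelGrid, grain_um: float) -> VoxelGrid:
    """Gaussian smoothing with sigma = grain / 2 per axis (in voxels).

    The "grain" is the physical feature scale below which intensity
    variation is treated as noise; sigma = grain / 2 is the classical
    analogue of surface-rendering smoothing at that grain.
    """
    if grain_um <= 0:
        return grid.with_data(grid.data.copy())
    sigma = tuple((grain_um / 2.0) / dv for dv in grid.voxel_size_um)
    return grid.with_data(ndimage.gaussian_filter(grid.data, sigma=sigma))


def _inflection_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold at the point of maximum curvature of the descending
    log-histogram (the "highest inflection" manual-thresholding rule).

    The histogram of intensities is log-transformed and lightly smoothed;
    on the descending limb right of the background mode, the bin where the
    second derivative of the log-counts is largest (the elbow between the
    background bulk and the signal tail) gives the threshold.
    """
    counts, edges = np.histogram(values, bins=n_bins)
    log_counts = np.log10(counts.astype(float) + 1.0)
    log_counts = ndimage.gaussian_filter1d(log_counts, sigma=2.0)
    mode = int(np.argmax(log_counts))
    if mode >= n_bins - 3:
        return float(edges[-2])
    curv = np.gradient(np.gradient(log_counts))
    idx = mode + 1 + int(np.argmax(curv[mode + 1 :]))
    return float(0.5 * (edges[idx] + edges[idx + 1]))


def threshold(
    grid: VoxelGrid,
    mode: str = "otsu",
    manual_value: float | None = None,
) -> np.ndarray:
    """Binarize an intensity grid; the mask is 1 where intensity >= cutoff.

    ``mode``:

    - ``"otsu"``: maximal between-class variance on the intensity histogram;
    - ``"manual"``: the given ``manual_value``;
    - ``"inflection"``: maximum curvature of the descending log-histogram.

    A constant image under Otsu yields an empty mask with a warning.
    """
    data = grid.data
    if mode == "manual":
        if manual_value is None:
            raise ValueError("manual mode requires manual_value")
        t = float(manual_value)
    elif mode == "otsu":
        if np.ptp(data) == 0:
            warnings.warn(
                "Otsu threshold on a constant image; returning empty mask",
                stacklevel=2,
            )
            return np.zeros(data.shape, dtype=bool)
        t = float(threshold_otsu(data))
        # threshold_otsu returns the lower bin edge of the upper class;
        # the >= convention below keeps the upper class selected.
        return data > t
    elif mode == "inflection":
        if np.ptp(data) == 0:
            warnings.warn(
                "inflection threshold on a constant image; returning empty mask",
                stacklevel=2,
            )
            return np.zeros(data.shape, dtype=bool)
        t = _inflection_threshold(data.ravel())
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return data >= t


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    valid = {3: {6: 1, 18: 2, 26: 3}, 2: {4: 1, 8: 2}}
    try:
        rank = valid[ndim][connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity {connectivity} invalid for {ndim}D data"
        ) from None
    return ndimage.generate_binary_structure(ndim, rank)


def label_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label maximal connected sets of 1-voxels; 0 is background.

    ``connectivity`` is 6/18/26 for 3D masks, 4/8 for 2D masks.  For 2D
    inputs ``connectivity=26`` is accepted as an alias of 8 (and 6 of 4) so
    a single pipeline default works in both dimensions.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2 and connectivity in (6, 26):
        connectivity = {6: 4, 26: 8}[connectivity]
    labels, _ = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    return labels


def object_sizes(labels: np.ndarray) -> dict[int, int]:
    """Voxel count per positive label."""
    counts = np.bincount(labels.ravel())
    return {i: int(c) for i, c in enumerate(counts) if i > 0 and c > 0}


def filter_objects(labels: np.ndarray, min_voxels: int, max_voxels: int) -> np.ndarray:
    """Keep objects strictly bigger than ``min_voxels`` and strictly smaller
    than ``max_voxels``; survivors are relabeled contiguously from 1 in
    original label order."""
    if min_voxels <= 0 or max_voxels <= 0:
        raise ValueError("voxel bounds must be positive")
    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.size, dtype=np.int64)
    nxt = 1
    for lbl in range(1, counts.size):
        if min_voxels < counts[lbl] < max_voxels:
            keep[lbl] = nxt
            nxt += 1
    return keep[labels]


def _log_response(grid: VoxelGrid, radii_um: tuple[float, float]) -> np.ndarray:
    """Negative scale-normalized Laplacian-of-Gaussian matched to an
    ellipsoid with half-axes (rxy, rxy, rz); bright blobs give positive
    peaks at their centres."""
    rxy, rz = radii_um
    ndim = grid.data.ndim
    if ndim == 3:
        sig_um = (rz, rxy, rxy)
    else:
        sig_um = (rxy, rxy)
    # For a blob of radius r the LoG response peaks at sigma = r / sqrt(ndim).
    sigma = tuple((s / np.sqrt(ndim)) / dv for s, dv in zip(sig_um, grid.voxel_size_um))
    mean_sig_um = float(np.mean([s / np.sqrt(ndim) for s in sig_um]))
    return -(mean_sig_um**2) * ndimage.gaussian_laplace(grid.data, sigma=sigma)


def _parabolic_offset(y_minus: float, y0: float, y_plus: float) -> float:
    denom = y_minus - 2.0 * y0 + y_plus
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (y_minus - y_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_spots(
    grid: VoxelGrid,
    spot_radii_um: tuple[float, float],
    background_subtract: bool = False,
    quality_threshold: float | None = None,
) -> SpotSet:
    """Detect bright ellipsoidal puncta by anisotropic LoG filtering.

    The image is filtered with a Laplacian-of-Gaussian whose per-axis sigma
    is matched to the requested ellipsoid half-axes ``(rxy, rz)``; local
    maxima of the (negated, scale-normalized) response above
    ``quality_threshold`` become candidate spots.  Non-maximum suppression
    forbids two spots closer than ``max(rxy, rz)`` (physical distance); ties
    in response are broken by lower (z, y, x) index.  Centres are refined to
    sub-voxel precision by a per-axis parabolic fit and reported in
    micrometres.

    When ``quality_threshold`` is None, the default is
    ``max(0.25 * max_response, 5 * sigma_noise)`` where ``sigma_noise`` is
    a robust (median-absolute-deviation) estimate of the response noise
    floor — a calibration on the synthetic fields; see docs/methods.md.
    """
    rxy, rz = (float(r) for r in spot_radii_um)
    if rxy <= 0 or rz <= 0:
        raise ValueError("spot radii must be positive")
    ndim = grid.data.ndim
    axis_r = (rz, rxy, rxy) if ndim == 3 else (rxy, rxy)
    for name, r, dv in zip(_AXIS_NAMES[ndim], axis_r, grid.voxel_size_um):
        if r < dv:
            raise ValueError(
                f"spot radius {r} um below voxel size {dv} um on axis {name!r}"
            )

    work = grid
    if background_subtract:
        work = subtract_background(grid, 2.0 * max(rxy, rz))
    resp = _log_response(work, (rxy, rz))
    max_resp = float(resp.max(initial=0.0))
    if max_resp <= 0:
        return SpotSet([])
    if quality_threshold is None:
        med = float(np.median(resp))
        sigma = 1.4826 * float(np.median(np.abs(resp - med)))
        thr = max(0.25 * max_resp, 5.0 * sigma)
    else:
        thr = float(quality_threshold)

    local_max = resp == ndimage.maximum_filter(resp, size=3, mode="nearest")
    cand = np.argwhere(local_max & (resp >= thr) & (resp > 0))
    if cand.size == 0:
        return SpotSet([])
    qualities = resp[tuple(cand.T)]
    # Sort by response (desc), ties by lower (z, y, x).
    order = np.lexsort(tuple(cand[:, d] for d in reversed(range(ndim))) + (-qualities,))
    cand = cand[order]
    qualities = qualities[order]

    vsz = np.asarray(grid.voxel_size_um)
    min_sep = max(rxy, rz)
    phys = (cand + 0.5) * vsz
    from scipy.spatial import cKDTree

    tree = cKDTree(phys)
    suppressed = np.zeros(len(cand), dtype=bool)
    accepted_idx: list[int] = []
    for i in range(len(cand)):
        if suppressed[i]:
            continue
        accepted_idx.append(i)
        for j in tree.query_ball_point(phys[i], min_sep):
            if j != i:
                suppressed[j] = True

    spots: list[Spot] = []
    shape = grid.data.shape
    for i in accepted_idx:
        idx = cand[i]
        # Sub-voxel refinement per axis on the LoG response.
        center_vox = idx.astype(float)
        for ax in range(ndim):
            if 0 < idx[ax] < shape[ax] - 1:
                lo = tuple(idx[a] - (1 if a == ax else 0) for a in range(ndim))
                hi = tuple(idx[a] + (1 if a == ax else 0) for a in range(ndim))
                center_vox[ax] += _parabolic_offset(
                    float(resp[lo]), float(resp[tuple(idx)]), float(resp[hi])
                )
        center_phys = (center_vox + 0.5) * vsz  # axis order (z, y, x) / (y, x)
        if ndim == 3:
            center_xyz = (float(center_phys[2]), float(center_phys[1]), float(center_phys[0]))
        else:
            center_xyz = (float(center_phys[1]), float(center_phys[0]), 0.0)
        total = _ellipsoid_sum(grid, idx, (rxy, rz))
        spots.append(Spot(center_xyz, (rxy, rz), total, float(qualities[i])))
    return SpotSet(spots)


def _ellipsoid_sum(grid: VoxelGrid, idx: np.ndarray, radii_um: tuple[float, float]) -> float:
    rxy, rz = radii_um
    ndim = grid.data.ndim
    axis_r = (rz, rxy, rxy) if ndim == 3 else (rxy, rxy)
    vsz = grid.voxel_size_um
    slices = []
    for ax in range(ndim):
        half = max(1, int(np.ceil(axis_r[ax] / vsz[ax])))
        slices.append(slice(max(0, idx[ax] - half), min(grid.data.shape[ax], idx[ax] + half + 1)))
    sub = grid.data[tuple(slices)]
    grids = np.ogrid[tuple(slices)]
    dist2 = sum(
        (((g - idx[ax]) * vsz[ax]) / axis_r[ax]) ** 2 for ax, g in enumerate(grids)
    )
    return float(sub[dist2 <= 1.0].sum())
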