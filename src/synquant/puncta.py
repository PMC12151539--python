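"""Punctum-level analytics: activity density, synapse pairing, cell counts.

Three related quantifications share the punctum abstraction:

- *activity density*: summed intensity of segmented active-caspase-3
  objects normalized to dLGN area (intensity mode), or object count per
  analyzed volume (count mode, used with the 10-2000 voxel object filter);
- *synapse pairing*: a postsynaptic (Homer1) punctum is a synapse if its
  centre lies within 300 nm of any presynaptic (SV2) punctum centre —
  post-centric, non-exclusive, each post counted at most once;
- *cell density*: spot counts per unit area/volume (RGC, relay neuron and
  granule-cell densities), including the geometric-mean composite used to
  isolate neuronal nuclei from a DAPI channel and a NeuN mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .imgseg import MultiChannelStack, SpotSet, VoxelGrid, detect_spots

__all__ = [
    "ActivityDensity",
    "SynapseCount",
    "PairingParams",
    "activity_density",
    "pair_synapses",
    "synapse_density_pipeline",
    "cell_density",
    "geometric_mean_composite",
]


@dataclass
class ActivityDensity:
    total_intensity: float
    roi_measure: float  # um^2 (intensity mode) or um^3 (count mode)
    density: float
    mode: str
    n_objects: int = 0


@dataclass
class SynapseCount:
    n_pre: int
    n_post: int
    n_pairs: int
    analyzed_volume_um3: float

    def __post_init__(self) -> None:
        if self.n_pairs > self.n_post:
            raise ValueError("n_pairs cannot exceed n_post")

    @property
    def synapse_density(self) -> float:
        return self.n_pairs / self.analyzed_volume_um3


@dataclass
class PairingParams:
    """Synapse-pairing parameters (defaults follow the reference protocol:
    300 nm centre-to-centre cutoff; SV2 spots 500 nm XY / 850 nm Z, Homer1
    spots 400 nm XY / 800 nm Z; sizes are ellipsoid diameters)."""

    d_max_um: float = 0.3
    pre_spot_dims_um: tuple[float, float] = (0.5, 0.85)
    post_spot_dims_um: tuple[float, float] = (0.4, 0.8)
    quality_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.d_max_um <= 0:
            raise ValueError("d_max_um must be positive")


def activity_density(
    objects: np.ndarray,
    raw: VoxelGrid,
    roi: np.ndarray,
    mode: str = "intensity_per_area",
) -> ActivityDensity:
    """Density of segmented activity objects within an ROI.

    ``intensity_per_area``: raw intensity summed over retained object
    voxels inside the ROI, divided by the ROI area in um^2 (the z extent
    is collapsed: a 3D ROI contributes the area of its 2D footprint).
    ``objects_per_volume``: number of distinct objects intersecting the
    ROI divided by the analyzed ROI volume in um^3.
    """
    objects = np.asarray(objects)
    roi = np.asarray(roi, dtype=bool)
    if objects.shape != raw.data.shape or roi.shape != raw.data.shape:
        raise ValueError("objects, raw and roi must share one grid")
    if not roi.any():
        raise ValueError("empty ROI")

    inside = (objects > 0) & roi
    obj_ids = np.unique(objects[inside])
    obj_ids = obj_ids[obj_ids > 0]
    vsz = raw.voxel_size_um

    if mode == "intensity_per_area":
        if raw.data.ndim == 3:
            footprint = roi.any(axis=0)
            area = float(footprint.sum()) * vsz[-1] * vsz[-2]
        else:
            area = float(roi.sum()) * vsz[-1] * vsz[-2]
        total = float(raw.data[inside].sum())
        return ActivityDensity(total, area, total / area, mode, len(obj_ids))
    if mode == "objects_per_volume":
        volume = float(roi.sum()) * float(np.prod(vsz))
        n = int(len(obj_ids))
        return ActivityDensity(float(raw.data[inside].sum()), volume, n / volume,
                               mode, n)
    raise ValueError(f"unknown mode {mode!r}")


def pair_synapses(
    pre: SpotSet | np.ndarray,
    post: SpotSet | np.ndarray,
    params: PairingParams | None = None,
    analyzed_volume_um3: float = float("nan"),
) -> SynapseCount:
    """Count post-puncta lying within ``d_max`` of any pre-punctum.

    Distance is Euclidean centre-to-centre in physical micrometres
    (anisotropy is already absorbed into the coordinates) and the cutoff
    is strict (< d_max; ties at exactly d_max are excluded).  Many post
    per pre are allowed; each post is counted at most once.  Inputs may be
    :class:`SpotSet` or raw (N, 3) centre arrays in (x, y, z) um.
    """
    params = params or PairingParams()
    pre_xyz = pre.centers_um if isinstance(pre, SpotSet) else np.asarray(pre, float).reshape(-1, 3)
    post_xyz = post.centers_um if isinstance(post, SpotSet) else np.asarray(post, float).reshape(-1, 3)
    n_pre, n_post = len(pre_xyz), len(post_xyz)
    if n_pre == 0 or n_post == 0:
        return SynapseCount(n_pre, n_post, 0, analyzed_volume_um3)
    tree = cKDTree(pre_xyz)
    dists, _ = tree.query(post_xyz, k=1)
    n_pairs = int((dists < params.d_max_um).sum())
    return SynapseCount(n_pre, n_post, n_pairs, analyzed_volume_um3)


@dataclass
class TrimSpec:
    """Z-window (um, in physical coordinates) and optional xy exclusion mask
    (True = excluded, e.g. blood-vessel gaps) applied before detection."""

    z_min_um: float = 0.0
    z_max_um: float = float("inf")
    exclude_xy: np.ndarray | None = None


def synapse_density_pipeline(
    stack: MultiChannelStack,
    channels: tuple[str, str] = ("pre", "post"),
    params: PairingParams | None = None,
    trim: TrimSpec | None = None,
) -> SynapseCount:
    """Detect pre/post puncta in a stack, pair them, return the density.

    The stack is trimmed to the requested z-window (an error if the window
    is thicker than the stack), spots are detected per channel with the
    pairing spot dimensions, and post-puncta within ``d_max`` of a
    pre-punctum are counted as synapses.  The analyzed volume is the
    trimmed (and exclusion-cropped) voxel volume, so densities pooled
    across fields are ratios of totals.
    """
    params = params or PairingParams()
    trim = trim or TrimSpec()
    pre_grid = stack[channels[0]]
    post_grid = stack[channels[1]]
    dz = pre_grid.voxel_size_um[0]
    nz = pre_grid.shape[0]
    stack_depth = nz * dz
    z_hi = min(trim.z_max_um, stack_depth)
    if trim.z_max_um != float("inf") and trim.z_max_um - trim.z_min_um > stack_depth + 1e-9:
        raise ValueError("trim window is thicker than the stack")
    k0 = int(np.floor(trim.z_min_um / dz))
    k1 = int(np.ceil(z_hi / dz))
    if k1 <= k0:
        raise ValueError("empty trim window")

    def trimmed(grid: VoxelGrid) -> VoxelGrid:
        data = grid.data[k0:k1]
        if trim.exclude_xy is not None:
            data = data.copy()
            data[:, np.asarray(trim.exclude_xy, bool)] = 0.0
        return VoxelGrid(data, grid.voxel_size_um, grid.channel_name)

    def radii(dims: tuple[float, float]) -> tuple[float, float]:
        return dims[0] / 2.0, dims[1] / 2.0

    pre_spots = detect_spots(trimmed(pre_grid), radii(params.pre_spot_dims_um),
                             quality_threshold=params.quality_threshold)
    post_spots = detect_spots(trimmed(post_grid), radii(params.post_spot_dims_um),
                              quality_threshold=params.quality_threshold)
    # Shift detected z back into the full-stack frame.
    z_off = k0 * dz
    for s in list(pre_spots) + list(post_spots):
        x, y, z = s.center_um
        s.center_um = (x, y, z + z_off)

    vsz = pre_grid.voxel_size_um
    n_vox = (k1 - k0) * pre_grid.shape[1] * pre_grid.shape[2]
    if trim.exclude_xy is not None:
        n_vox = (k1 - k0) * int((~np.asarray(trim.exclude_xy, bool)).sum())
    volume = float(n_vox) * float(np.prod(vsz))
    return pair_synapses(pre_spots, post_spots, params, analyzed_volume_um3=volume)


def geometric_mean_composite(a: VoxelGrid, b: VoxelGrid) -> VoxelGrid:
    """Voxel-wise geometric mean sqrt(a * b); zero wherever either input is
    zero.  Used to combine a DAPI channel with a NeuN mask (or segmented
    NeuN image) so that only neuronal nuclei survive spot finding."""
    if a.data.shape != b.data.shape:
        raise ValueError("grids are not aligned")
    return a.with_data(np.sqrt(np.clip(a.data, 0, None) * np.clip(b.data, 0, None)))


def cell_density(
    spots: SpotSet | int,
    region_measure: float,
    per: float = 1.0,
) -> float:
    """Cell count divided by the region measure (area in um^2 or volume in
    um^3).  ``spots`` may be a detected SpotSet or a manual count; ``per``
    rescales the result (e.g. ``per=100.0`` for counts per 100 um^2)."""
    if region_measure <= 0:
        raise ValueError("region measure must be positive")
    n = len(spots) if isinstance(spots, SpotSet) else int(spots)
    return n / region_measure * per
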