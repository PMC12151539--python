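"""Per-cell engulfed-tracer quantification and activation metrics.

Microglia (or astrocytes) are segmented into a 3D label map; eye-specific
tracer channels (e.g. CTB-AF555 for the left eye, CTB-AF647 for the right)
are binarized into masks.  For each cell, the engulfed volume per tracer
channel is the number of tracer voxels lying on that cell's label times the
voxel volume — the voxel-wise reading of "fully enclosed" synaptic
material.  The per-cell right/left engulfment ratio isolates substrate
preference (surgery- and labeling-related confounds cancel); cells with a
zero denominator are censored rather than assigned a pseudocount, matching
a log-scale display that can represent neither 0 nor infinity.

CD68 activation metrics (lysosomal volume fraction and relative intensity
per cell) are computed the same way from a CD68 mask and raw channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgseg import VoxelGrid

__all__ = [
    "CellEngulfment",
    "EngulfmentRatio",
    "ActivationMetrics",
    "engulfed_volumes",
    "engulfment_ratio",
    "activation_metrics",
    "cohort_compare",
]


@dataclass
class CellEngulfment:
    """Engulfment summary for one segmented cell."""

    cell_id: int
    cell_volume_um3: float
    engulfed_um3: dict[str, float]

    @property
    def engulfed_fraction(self) -> dict[str, float]:
        return {c: v / self.cell_volume_um3 for c, v in self.engulfed_um3.items()}


@dataclass
class EngulfmentRatio:
    """Right/left engulfed-volume ratio for one cell (log-displayable)."""

    cell_id: int
    ratio: float | None
    censored: bool = False
    reason: str = ""


@dataclass
class ActivationMetrics:
    """CD68-based activation readout for one cell."""

    cell_id: int
    cd68_volume_fraction: float
    cd68_relative_intensity: float  # summed CD68 intensity / cell volume (a.u./um^3)


def _boundary_labels(cells: np.ndarray) -> set[int]:
    faces = [cells[0], cells[-1], cells[:, 0], cells[:, -1]]
    if cells.ndim == 3:
        faces += [cells[:, :, 0], cells[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def engulfed_volumes(
    cells: np.ndarray,
    tracer_masks: dict[str, np.ndarray],
    voxel_size_um: tuple[float, ...],
    exclude_boundary: bool = True,
    roi_mask: np.ndarray | None = None,
    enclosure: str = "voxel",
) -> list[CellEngulfment]:
    """Per-cell engulfed tracer volume for each channel.

    With the default ``enclosure="voxel"`` rule, ``engulfed_um3[c]``
    counts voxels where the channel's tracer mask is 1 AND the cell label
    matches, times the voxel volume.  The stricter ``enclosure="object"``
    rule credits a tracer connected component to a cell only when every
    voxel of that component lies on the cell's label (100% enclosed).
    Cells touching the stack boundary are excluded by default (their soma
    and processes are not fully contained in the stack); if ``roi_mask``
    is given, only cells whose centroid lies inside it are retained.
    """
    if enclosure not in ("voxel", "object"):
        raise ValueError(f"unknown enclosure rule {enclosure!r}")
    cells = np.asarray(cells)
    for name, m in tracer_masks.items():
        if np.asarray(m).shape != cells.shape:
            raise ValueError(f"tracer mask {name!r} shape differs from cell grid")
    if enclosure == "object":
        from .imgseg import label_components

        filtered = {}
        for name, m in tracer_masks.items():
            comp = label_components(np.asarray(m).astype(bool))
            keep = np.zeros(comp.shape, dtype=bool)
            for oid in range(1, int(comp.max()) + 1):
                owners = np.unique(cells[comp == oid])
                if len(owners) == 1 and owners[0] > 0:
                    keep |= comp == oid
            filtered[name] = keep
        tracer_masks = filtered
    voxel_volume = float(np.prod(voxel_size_um))
    n_labels = int(cells.max())
    if n_labels == 0:
        return []

    excluded = _boundary_labels(cells) if exclude_boundary else set()
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        idx = np.argwhere(cells > 0)
        labs = cells[cells > 0]
        for cid in range(1, n_labels + 1):
            pts = idx[labs == cid]
            if len(pts) == 0:
                continue
            centroid = np.round(pts.mean(axis=0)).astype(int)
            if not roi_mask[tuple(centroid)]:
                excluded.add(cid)

    cell_counts = np.bincount(cells.ravel(), minlength=n_labels + 1)
    per_channel = {}
    for name, m in tracer_masks.items():
        mask = np.asarray(m).astype(bool)
        per_channel[name] = np.bincount(cells[mask].ravel(), minlength=n_labels + 1)

    out: list[CellEngulfment] = []
    for cid in range(1, n_labels + 1):
        if cid in excluded or cell_counts[cid] == 0:
            continue
        engulfed = {
            name: float(per_channel[name][cid]) * voxel_volume for name in tracer_masks
        }
        out.append(
            CellEngulfment(cid, float(cell_counts[cid]) * voxel_volume, engulfed)
        )
    return out


def engulfment_ratio(
    ce: CellEngulfment,
    right_channel: str,
    left_channel: str,
    zero_rule: str = "censor",
) -> EngulfmentRatio:
    """Right-eye / left-eye engulfed-volume ratio for one cell.

    ``zero_rule`` governs zero denominators (and, symmetrically, zero
    numerators, which a log-scale display equally cannot show):

    - ``"censor"`` (default): mark the cell censored and return no ratio;
    - ``"nan"``: return NaN without the censored flag bookkeeping.
    """
    right = ce.engulfed_um3[right_channel]
    left = ce.engulfed_um3[left_channel]
    if left <= 0 or right <= 0:
        if zero_rule == "censor":
            which = "denominator" if left <= 0 else "numerator"
            return EngulfmentRatio(ce.cell_id, None, censored=True,
                                   reason=f"zero {which}")
        if zero_rule == "nan":
            return EngulfmentRatio(ce.cell_id, float("nan"))
        raise ValueError(f"unknown zero_rule {zero_rule!r}")
    return EngulfmentRatio(ce.cell_id, right / left)


def activation_metrics(
    cells: np.ndarray,
    cd68: VoxelGrid,
    cd68_mask: np.ndarray,
    exclude_boundary: bool = True,
) -> list[ActivationMetrics]:
    """Per-cell CD68 volume fraction and relative intensity.

    The volume fraction is the fraction of the cell's voxels positive in
    the CD68 mask; the relative intensity is the summed raw CD68 signal
    within the cell divided by the cell volume in um^3.
    """
    cells = np.asarray(cells)
    if cd68.data.shape != cells.shape or np.asarray(cd68_mask).shape != cells.shape:
        raise ValueError("grids are not aligned")
    mask = np.asarray(cd68_mask).astype(bool)
    n_labels = int(cells.max())
    voxel_volume = cd68.voxel_volume_um3
    excluded = _boundary_labels(cells) if exclude_boundary else set()

    cell_counts = np.bincount(cells.ravel(), minlength=n_labels + 1)
    pos_counts = np.bincount(cells[mask].ravel(), minlength=n_labels + 1)
    intensity = np.zeros(n_labels + 1)
    np.add.at(intensity, cells.ravel(), cd68.data.ravel())

    out = []
    for cid in range(1, n_labels + 1):
        if cid in excluded or cell_counts[cid] == 0:
            continue
        vol = float(cell_counts[cid]) * voxel_volume
        out.append(
            ActivationMetrics(
                cid,
                float(pos_counts[cid]) / float(cell_counts[cid]),
                float(intensity[cid]) / vol,
            )
        )
    return out


@dataclass
class CohortSummary:
    """Per-cell and per-animal views of a grouped engulfment comparison."""

    per_cell: dict[str, np.ndarray]
    per_animal: dict[str, np.ndarray]
    result: "object" = None  # stats.ComparisonResult


def cohort_compare(
    values_by_group: dict[str, list[tuple[str, float]]],
    by_animal: bool = False,
    test: str | None = None,
) -> CohortSummary:
    """Compare engulfment readouts between >= 2 groups.

    ``values_by_group`` maps group name to a list of ``(animal_id, value)``
    per cell.  The per-cell comparison uses all cells; ``by_animal=True``
    averages cells within each animal first.  Dispatch goes to
    :func:`synquant.stats.compare` — ``test="mannwhitney"`` matches the
    engulfment-ratio analyses, ``test="t"`` the volume analyses, and
    ``test=None`` uses the normality-based automatic rule.
    """
    from . import stats as _stats

    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    per_cell: dict[str, np.ndarray] = {}
    per_animal: dict[str, np.ndarray] = {}
    for group, rows in values_by_group.items():
        if len(rows) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 cells")
        vals = np.array([v for _, v in rows], dtype=float)
        per_cell[group] = vals
        animals: dict[str, list[float]] = {}
        for animal, v in rows:
            animals.setdefault(animal, []).append(float(v))
        per_animal[group] = np.array([np.mean(v) for v in animals.values()])

    data = per_animal if by_animal else per_cell
    for group, vals in data.items():
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 units")
    design = "unpaired" if len(data) == 2 else "multi"
    result = _stats.compare(list(data.values()), design=design, rule=test or "auto")
    return CohortSummary(per_cell, per_animal, result)
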