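"""Eye-specific segregation analysis of two-channel dLGN images.

During development, retinal inputs from the two eyes sort into
non-overlapping territories in the dorsal lateral geniculate nucleus
(dLGN).  Segregation is quantified from two-channel tracer images
(contralateral vs ipsilateral eye) as the *percentage overlap*: after
background subtraction and per-channel normalization to [0, 1], a pixel is
"real" in a channel if its normalized value is >= a cutoff threshold, and
the overlap at that threshold is the fraction of dLGN pixels real in both
channels.  The statistic is swept over an increasing threshold series
(default 0.1, 0.125, ..., 0.25) so that genuine overlap, which survives
high cutoffs, is distinguished from background noise, which does not.

Per animal, several sections are pooled as a ratio of totals (total
both-channel pixels over total dLGN pixels across sections), not as a mean
of per-section ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgseg import VoxelGrid, threshold as _threshold

__all__ = [
    "PlanarImage",
    "OverlapProfile",
    "DEFAULT_THRESHOLDS",
    "ALT_THRESHOLDS",
    "normalize_channels",
    "overlap_profile",
    "otsu_overlap",
]

#: Seven-threshold series used for the P10 CTB analysis.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.1, 0.125, 0.15, 0.175, 0.2, 0.225, 0.25)
#: Alternate series used for the P8 AAV-tracer analysis.
ALT_THRESHOLDS: tuple[float, ...] = (0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2)


@dataclass
class PlanarImage:
    """One dLGN section: two tracer channels plus hand-drawn masks.

    ``dlgn_mask`` outlines the dLGN; ``background_mask`` marks a
    signal-free thalamic region used to estimate the background level.
    The two masks must be disjoint and the dLGN mask non-empty.
    """

    contra: np.ndarray
    ipsi: np.ndarray
    pixel_size_um: float
    dlgn_mask: np.ndarray
    background_mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.contra = np.asarray(self.contra, dtype=np.float64)
        self.ipsi = np.asarray(self.ipsi, dtype=np.float64)
        self.dlgn_mask = np.asarray(self.dlgn_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.contra.shape != self.ipsi.shape:
            raise ValueError("channel shapes differ")
        if self.dlgn_mask.shape != self.contra.shape:
            raise ValueError("mask shape differs from channels")
        if not self.dlgn_mask.any():
            raise ValueError("dlgn_mask is empty")
        if (self.dlgn_mask & self.background_mask).any():
            raise ValueError("dlgn_mask and background_mask overlap")


@dataclass
class OverlapProfile:
    """Percentage overlap per threshold for one animal (pooled sections)."""

    thresholds: tuple[float, ...]
    percent_overlap: tuple[float, ...]
    n_sections: int
    per_section: list[tuple[float, ...]] = field(default_factory=list)

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.thresholds, self.percent_overlap))


def normalize_channels(image: PlanarImage) -> PlanarImage:
    """Background-subtract and normalize both channels to [0, 1].

    Per channel: the mean intensity over the background region is
    subtracted, negative values are clipped to zero, and the result is
    divided by the per-channel maximum over the dLGN mask.  A channel that
    is flat (zero everywhere in the dLGN after subtraction) is degenerate
    and raises.
    """
    if not image.background_mask.any():
        raise ValueError("background_mask is empty")
    out = []
    for name, chan in (("contra", image.contra), ("ipsi", image.ipsi)):
        bg = float(chan[image.background_mask].mean())
        shifted = np.clip(chan - bg, 0.0, None)
        peak = float(shifted[image.dlgn_mask].max())
        if peak <= 0:
            raise ValueError(f"degenerate {name} channel: no signal above background")
        out.append(shifted / peak)
    return PlanarImage(
        out[0], out[1], image.pixel_size_um, image.dlgn_mask,
        image.background_mask, normalized=True,
    )


def overlap_profile(
    images: list[PlanarImage],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> OverlapProfile:
    """Pooled percentage overlap across sections at each threshold.

    For threshold ``t``, percent overlap =
    ``100 * sum_sections |{dLGN pixels with both channels >= t}| /
    sum_sections |dLGN pixels|`` — a single ratio of totals.  Per-section
    ratios are also recorded for QC but are not the headline statistic.
    """
    if not images:
        raise ValueError("need at least one section image")
    thresholds = tuple(float(t) for t in thresholds)
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    for img in images:
        if not img.normalized:
            raise ValueError("images must be normalized (normalize_channels)")

    both = np.zeros(len(thresholds), dtype=np.int64)
    total = 0
    per_section = []
    for img in images:
        m = img.dlgn_mask
        c = img.contra[m]
        i = img.ipsi[m]
        n = int(m.sum())
        counts = [int(((c >= t) & (i >= t)).sum()) for t in thresholds]
        both += counts
        total += n
        per_section.append(tuple(100.0 * k / n for k in counts))
    percent = tuple(100.0 * b / total for b in both)
    return OverlapProfile(thresholds, percent, len(images), per_section)


def otsu_overlap(image: PlanarImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel Otsu binarization within the dLGN and their AND.

    Renders the thresholded-territory display: each normalized channel is
    Otsu-binarized on its dLGN histogram; the overlap mask is the logical
    AND of the two channel masks.  Returns (contra, ipsi, overlap) masks.
    """
    if not image.normalized:
        raise ValueError("image must be normalized first")
    masks = []
    m = image.dlgn_mask
    for chan in (image.contra, image.ipsi):
        vals = chan[m]
        if np.ptp(vals) == 0:
            mask = np.zeros(chan.shape, dtype=bool)
        else:
            # Otsu on dLGN pixels only, applied within the dLGN mask.
            grid = VoxelGrid(vals[None, :], (1.0, 1.0))
            sel = _threshold(grid, "otsu")[0]
            mask = np.zeros(chan.shape, dtype=bool)
            mask[m] = sel
        masks.append(mask)
    contra_mask, ipsi_mask = masks
    return contra_mask, ipsi_mask, contra_mask & ipsi_mask


def auto_dlgn_mask(contra: np.ndarray, ipsi: np.ndarray) -> np.ndarray:
    """Convenience auto-mask (largest Otsu component of the summed
    channels, closed and filled).  Non-canonical: the reference analysis
    uses hand-drawn dLGN and background masks; use this only for quick
    looks, never for the headline statistic."""
    from scipy import ndimage

    total = np.asarray(contra, float) + np.asarray(ipsi, float)
    grid = VoxelGrid(total, (1.0, 1.0))
    mask = _threshold(grid, "otsu")
    mask = ndimage.binary_closing(mask, iterations=3)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(total.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return ndimage.binary_fill_holes(labels == int(np.argmax(sizes)))
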