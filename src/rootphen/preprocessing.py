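"""Binary tissue mask and region of interest (ROI).

The foreground of the binary mask is the *cell interior* (the light phase of
the stained section); cell walls are background.  The ROI is what remains of
the image after masking the non-tissue peridermal edge region and the
objects that touch the image border.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .config import PipelineConfig
from .imgio import ImageRecord

log = logging.getLogger("rootphen")

# 8-connectivity throughout, matching the labelling default of the R imaging
# toolbox this workflow descends from.
_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class BinaryMask:
    """Boolean mask, True = cell-interior foreground."""

    pixels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiMask:
    """Boolean mask of the region of interest (True = inside ROI)."""

    pixels: np.ndarray

    @property
    def innerpixarea(self) -> int:
        return int(self.pixels.sum())

    @property
    def imagetotalpix(self) -> int:
        return int(self.pixels.size)


def _disc(brush_size: int) -> np.ndarray:
    # brush sizes are diameters; effective radius = size // 2
    return morphology.disk(max(1, brush_size // 2))


def binarize(img: ImageRecord, cfg: PipelineConfig) -> BinaryMask:
    """Gaussian blur, Otsu threshold, two opening cycles, hole filling.

    Foreground is chosen as the Otsu class with the higher mean intensity
    (cell interiors are bright after staining), so inverted scans are
    corrected automatically.  A constant image has no Otsu threshold and
    yields an all-false mask with a warning rather than an exception.
    """
    smoothed = filters.gaussian(img.pixels, sigma=cfg.gaussian_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return BinaryMask(np.zeros(img.pixels.shape, dtype=bool))
    t = filters.threshold_otsu(smoothed)
    fg = smoothed > t
    # polarity check: foreground must be the brighter class
    if fg.any() and (~fg).any() and smoothed[fg].mean() < smoothed[~fg].mean():
        fg = ~fg
    fg = morphology.opening(fg, _disc(cfg.opening_radius_1))
    fg = morphology.opening(fg, _disc(cfg.opening_radius_2))
    fg = ndi.binary_fill_holes(fg)
    log.info("binarize: %d foreground px of %d", int(fg.sum()), fg.size)
    return BinaryMask(fg)


def mask_peridermal_edge(
    mask: BinaryMask, cfg: PipelineConfig
) -> tuple[BinaryMask, RoiMask]:
    """Remove the irregular non-tissue region at the left (peridermal) margin.

    Only the first ``edge_fraction`` of the image width is searched.  A high
    opening (brush ``edge_opening_radius``) followed by hole filling isolates
    the large non-tissue area; everything that survives this opening within
    the strip is taken as non-tissue, removed from the working mask and
    excluded from the ROI.  Pixels at x >= edge_fraction*width are never
    touched.
    """
    h, w = mask.shape
    ncols = int(np.ceil(cfg.edge_fraction * w))
    strip = np.zeros_like(mask.pixels)
    strip[:, :ncols] = mask.pixels[:, :ncols]
    opened = morphology.opening(strip, _disc(cfg.edge_opening_radius))
    void = ndi.binary_fill_holes(opened)
    void[:, ncols:] = False
    removed = void.copy()
    cleaned = mask.pixels & ~void
    if void.any():
        # merge the removed area with the incomplete objects it cuts:
        # opening shaves slivers off adjacent foreground, which would
        # otherwise survive as spurious tiny objects at the margin
        labels, _ = ndi.label(cleaned, structure=_STRUCT8)
        near_void = ndi.binary_dilation(void, structure=_STRUCT8)
        touching = np.unique(labels[near_void & (labels > 0)])
        in_strip = np.ones(labels.max() + 1, dtype=bool)
        beyond = np.unique(labels[:, ncols:])
        in_strip[beyond[beyond > 0]] = False
        drop = np.isin(labels, [t for t in touching if t > 0 and in_strip[t]])
        removed |= drop
        cleaned &= ~drop
    roi = RoiMask(~removed)
    log.info(
        "peridermal edge: removed %d px within first %d columns", int(removed.sum()), ncols
    )
    return BinaryMask(cleaned), roi


def remove_border_objects(mask: BinaryMask) -> tuple[BinaryMask, BinaryMask, int]:
    """Partition foreground into interior objects and border-touching objects.

    A connected component (8-connected) with at least one pixel on any image
    edge is an "edge-touching cell"; such objects are incomplete and must not
    enter size statistics.  Returns ``(interior, border, n_border)``.
    """
    labels, n = ndi.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        empty = BinaryMask(np.zeros_like(mask.pixels))
        return empty, BinaryMask(np.zeros_like(mask.pixels)), 0
    edge_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    edge_labels = edge_labels[edge_labels > 0]
    on_border = np.isin(labels, edge_labels) & mask.pixels
    interior = mask.pixels & ~on_border
    log.info("border objects: %d removed, %d px", len(edge_labels), int(on_border.sum()))
    return BinaryMask(interior), BinaryMask(on_border), int(len(edge_labels))
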