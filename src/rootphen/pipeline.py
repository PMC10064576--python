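"""End-to-end per-image processing: mask, segment, profile, filter, type.

``process_image`` runs every stage on one micrograph and returns an
:class:`ImageResult` holding the final object table (master-table columns),
the label image, masks, the ring set and the stage-by-stage removal log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .filtering import FilterLog, iterate_filtering
from .imgio import ImageRecord
from .preprocessing import BinaryMask, RoiMask, binarize, mask_peridermal_edge, remove_border_objects
from .rings import RingSet, assign_ring_zone, detect_rings
from .schema import MASTER_COLUMNS
from .segmentation import LabelImage, cell_wall_count, compute_features, watershed_cells
from .tissue import classify_tissue

log = logging.getLogger("rootphen")


@dataclass
class ImageResult:
    """Everything the pipeline derived from one micrograph."""

    dataname: str
    table: pd.DataFrame  # final per-image table, master columns
    labels: LabelImage
    binary: BinaryMask
    roi: RoiMask
    rings: RingSet
    filter_log: FilterLog
    n_watershed: int
    n_border: int
    imagetotalpix: int
    innerpixarea: int
    cellwallcount: int
    intercellcount: int

    @property
    def n_cells(self) -> int:
        return int(self.table["order"].notna().sum())


def _finalize_table(table: pd.DataFrame, result_meta: dict) -> pd.DataFrame:
    """Broadcast image-level values and order columns to the master schema."""
    table = table.copy()
    if table.empty:
        # an image with zero surviving cells still contributes its accounting
        table = pd.DataFrame([{c: np.nan for c in MASTER_COLUMNS}])
    for key, val in result_meta.items():
        table[key] = val
    for col in MASTER_COLUMNS:
        if col not in table:
            table[col] = np.nan
    return table[MASTER_COLUMNS]


def process_image(img: ImageRecord, cfg: PipelineConfig) -> ImageResult:
    """Run the full single-image pipeline.

    Stages: binarise; mask the peridermal non-tissue edge; drop
    border-touching objects; watershed-segment; extract features; detect
    cambium rings and assign ring zones; iterate the artifact/intercellular
    filter; type the surviving cells VT/SP; account pixels.
    """
    log.info("processing %s (%dx%d)", img.dataname, img.width, img.height)
    binary = binarize(img, cfg)
    cleaned, roi0 = mask_peridermal_edge(binary, cfg)
    interior, border, n_border = remove_border_objects(cleaned)
    roi = RoiMask(roi0.pixels & ~border.pixels)

    labels = watershed_cells(interior)
    table = compute_features(labels, cfg)
    n_watershed = len(table)

    rings = detect_rings(table, cfg)
    table = assign_ring_zone(table, rings)

    table, flog = iterate_filtering(table, cfg)
    table = classify_tissue(table, cfg)

    wallcount = cell_wall_count(binary, roi)
    intercell = int(round(flog.intercell_area))
    meta = {
        "Imagetotalpix": roi.imagetotalpix,
        "Innerpixarea": roi.innerpixarea,
        "Cellwallcount": wallcount,
        "Intercellcount": intercell,
        "Dataname": img.dataname,
    }
    final = _finalize_table(table, meta)
    log.info(
        "%s: %d objects after watershed, %d final cells, %d rings",
        img.dataname,
        n_watershed,
        int(final["order"].notna().sum()),
        rings.nmdeep,
    )
    return ImageResult(
        dataname=img.dataname,
        table=final,
        labels=labels,
        binary=binary,
        roi=roi,
        rings=rings,
        filter_log=flog,
        n_watershed=n_watershed,
        n_border=n_border,
        imagetotalpix=roi.imagetotalpix,
        innerpixarea=roi.innerpixarea,
        cellwallcount=wallcount,
        intercellcount=intercell,
    )
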