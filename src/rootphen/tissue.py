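"""Final 2-cluster tissue typing: vascular tissue (VT) vs storage parenchyma (SP).

After intercellular spaces and artifacts are gone, the surviving objects are
cells of two biological tissue types: small-celled vascular tissue around
the cambium rings and large-celled storage parenchyma between them.  A
2-cluster k-means on the morphological features separates them; the
smaller-celled cluster is VT, the larger SP, so
mean(diameter | VT) < mean(diameter | SP) always holds after relabelling.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import PipelineConfig
from .filtering import kmeans_sized

TISSUE_NAMES = {1: "VT", 2: "SP"}


def classify_tissue(cells: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Label every surviving cell VT or SP via size-ordered 2-means."""
    cells = cells.copy()
    if len(cells) < 2:
        warnings.warn("fewer than two cells; labelling all as VT")
        cells["Cluster_zw"] = "VT"
        return cells
    labels = kmeans_sized(cells, 2, cfg)
    cells["Cluster_zw"] = [TISSUE_NAMES[int(l)] for l in labels]
    return cells
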