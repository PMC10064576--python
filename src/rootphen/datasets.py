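"""Small bundled reference datasets.

``example_validation_counts`` ships the published manual-versus-automated
cell-count validation of a ten-genotype beet storage-root study (one
reference micrograph per genotype): the object count straight after
watershed segmentation, the final cell count after filtering, the percentage
of objects removed, and the manually counted ground truth.
"""

from __future__ import annotations

import pandas as pd

_VALIDATION_ROWS = [
    # genotype, watershed_count, final_count, removed_pct, ground_truth
    (1, 2688, 2615, 3, 2562),
    (2, 1722, 1517, 12, 1586),
    (3, 610, 450, 26, 295),
    (4, 755, 571, 24, 322),
    (5, 3203, 2990, 7, 2911),
    (6, 2075, 1914, 8, 1454),
    (7, 3488, 3332, 4, 3106),
    (8, 1282, 1138, 11, 1047),
    (9, 1850, 1641, 11, 1403),
    (10, 737, 622, 16, 414),
]


def example_validation_counts() -> pd.DataFrame:
    """Ten paired manual/automated cell counts for validation examples."""
    return pd.DataFrame(
        _VALIDATION_ROWS,
        columns=["genotype", "watershed_count", "final_count", "removed_pct", "ground_truth"],
    )
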