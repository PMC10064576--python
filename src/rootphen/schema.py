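"""Column schemas of the object table and the final master table."""

from __future__ import annotations

DIAMETER_COL = "Meandiameterµm"

#: per-object morphometric columns extracted from the label image
SHAPE_COLUMNS = [
    "s.area",
    "s.perimeter",
    "s.radius.mean",
    "s.radius.sd",
    "s.radius.max",
    "s.radius.min",
    "m.cx",
    "m.cy",
    "m.majoraxis",
    "m.eccentricity",
    "m.theta",
]

#: morphological features used for clustering: everything from the shape set
#: except the object's position (and, handled separately, its ring zone)
CLUSTER_FEATURES = [
    c for c in SHAPE_COLUMNS if c not in ("m.cx", "m.cy")
]

#: exact column set (and order) of the per-image/master table
MASTER_COLUMNS = [
    "order",
    *SHAPE_COLUMNS,
    DIAMETER_COL,
    "Diameter_log",
    "Q1",
    "Q3",
    "IQR",
    "nmbpeak",
    "nmdeep",
    "Cluster_drei",
    "Cluster_zw",
    "Imagetotalpix",
    "Innerpixarea",
    "Cellwallcount",
    "Intercellcount",
    "Dataname",
]

#: sentinel stored in Diameter_log for degenerate zero-diameter objects
LOG_DIAMETER_SENTINEL = -999.0
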