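"""Discrimination of real cells from intercellular spaces and artifacts.

Three complementary strategies, iterated to a fixed point:

1. a size threshold from the (possibly bimodal) histogram of log10 cell
   diameter drops sub-cellular debris;
2. a nearest-neighbour diameter-outlier test removes objects much smaller
   than their immediate neighbourhood (intercellular voids sit between large
   cells and are always smaller than them);
3. a 3-cluster k-means on the morphological features, run per inter-ring
   zone, followed by a majority rule: a cluster-1 (smallest) object whose
   gated neighbours are predominantly cluster-3 (largest) is an
   intercellular space.

All quantiles use linear interpolation (type 7).  Neighbour distances are
gated with the literal ``Q2 + 1.5*IQR`` fence (a Q3-based fence is available
behind ``cfg.median_distance_fence``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .schema import CLUSTER_FEATURES, DIAMETER_COL

log = logging.getLogger("rootphen")

#: minimum objects per ring zone for a zone-local 3-cluster k-means;
#: smaller zones fall back to the global clustering
MIN_ZONE_SIZE = 10


@dataclass
class NeighborStats:
    """Gated nearest-neighbour set of one focal object."""

    focal: int
    neighbor_ids: np.ndarray
    distances: np.ndarray
    dist_q2: float
    dist_iqr: float


@dataclass
class MajorityDecision:
    """Bookkeeping of the cluster-majority rule around one focal object."""

    focal: int
    SUM: float
    MEAN: float
    MAX: float
    is_intercellular: bool


@dataclass
class FilterLog:
    """Stage-by-stage removal log across filtering passes."""

    records: list[dict] = field(default_factory=list)

    def add(self, n_pass: int, stage: str, ids, areas) -> None:
        for i, a in zip(ids, areas):
            self.records.append(
                {"pass": n_pass, "stage": stage, "order": int(i), "s.area": float(a)}
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["pass", "stage", "order", "s.area"])

    @property
    def intercell_area(self) -> float:
        """Summed pixel area of objects removed as intercellular spaces."""
        return float(
            sum(r["s.area"] for r in self.records if r["stage"] in ("diameter_outlier", "majority_rule"))
        )

    @property
    def n_removed(self) -> int:
        return len(self.records)


def quantile_fences(values: np.ndarray) -> tuple[float, float, float, float]:
    """(Q1, Q2, Q3, IQR) with linear (type-7) interpolation."""
    q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(q2), float(q3), float(q3 - q1)


def small_object_threshold(diam_log: np.ndarray, cfg: PipelineConfig) -> float:
    """Log10-diameter cut-off from the histogram of object sizes.

    The frequency histogram (bin width 0.05 in log10 µm) of all object
    diameters is scanned for its two highest local maxima; the threshold is
    the centre of the minimum-count bin strictly between them.  A unimodal
    histogram yields the fallback (0.5, ~3 µm); valleys above
    ``max_log_threshold`` are capped at it (0.8) so viable cells are not
    dropped.
    """
    diam_log = np.asarray(diam_log, dtype=float)
    diam_log = diam_log[np.isfinite(diam_log)]
    if diam_log.size == 0:
        return cfg.fallback_log_threshold
    lo, hi = diam_log.min(), diam_log.max()
    if hi - lo < 0.1:
        return cfg.fallback_log_threshold
    bins = np.arange(lo, hi + 0.05, 0.05)
    counts, edges = np.histogram(diam_log, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    # local maxima of the histogram (plateau-tolerant at the ends)
    n = len(counts)
    is_max = np.zeros(n, dtype=bool)
    for i in range(n):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n - 1 else -1
        is_max[i] = counts[i] > left and counts[i] >= right
    modes = np.nonzero(is_max)[0]
    if len(modes) < 2:
        return cfg.fallback_log_threshold
    top2 = modes[np.argsort(counts[modes])][-2:]
    i, j = int(min(top2)), int(max(top2))
    if j - i < 2:
        return cfg.fallback_log_threshold
    between = counts[i + 1 : j]
    valley = centres[i + 1 + int(np.argmin(between))]
    return float(min(valley, cfg.max_log_threshold))


def gated_neighbors(cells: pd.DataFrame, cfg: PipelineConfig) -> list[NeighborStats]:
    """k nearest neighbours per object, gated by the distance IQR fence.

    Neighbours are found with a k-d tree on (m.cx, m.cy); among the (at most)
    ``k_neighbors`` nearest, those with a distance above ``Q2 + 1.5*IQR`` of
    the focal object's neighbour distances are not considered direct
    neighbours.  Fewer than two objects yield an empty list.
    """
    n = len(cells)
    if n < 2:
        return []
    ids = cells["order"].to_numpy(dtype=int)
    xy = cells[["m.cx", "m.cy"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    k = min(cfg.k_neighbors, n - 1)
    dist, idx = tree.query(xy, k=k + 1)
    out: list[NeighborStats] = []
    for row in range(n):
        d = dist[row][1:]
        nb = idx[row][1:]
        q1, q2, q3, iqr = quantile_fences(d)
        fence = (q2 if cfg.median_distance_fence else q3) + 1.5 * iqr
        keep = d <= fence
        out.append(
            NeighborStats(
                focal=int(ids[row]),
                neighbor_ids=ids[nb[keep]],
                distances=d[keep],
                dist_q2=q2,
                dist_iqr=iqr,
            )
        )
    return out


def diameter_outlier_pass(
    cells: pd.DataFrame, nbrs: list[NeighborStats]
) -> tuple[pd.DataFrame, list[int]]:
    """Remove objects whose log-diameter is a low outlier in its neighbourhood.

    For each focal object, Q1 and IQR are computed over the log10 diameters
    of the focal object together with its gated neighbours; the focal object
    is removed when its value falls below ``Q1 - 1.5*IQR`` (a probable
    intercellular space).  The neighbourhood quantiles are recorded in the
    ``Q1``/``Q3``/``IQR`` columns of the surviving table.
    """
    cells = cells.copy()
    dlog = cells.set_index("order")["Diameter_log"]
    removed: list[int] = []
    q1s, q3s, iqrs = {}, {}, {}
    for st in nbrs:
        pool = np.concatenate([[dlog[st.focal]], dlog.loc[st.neighbor_ids].to_numpy()])
        q1, _, q3, iqr = quantile_fences(pool)
        q1s[st.focal], q3s[st.focal], iqrs[st.focal] = q1, q3, iqr
        if dlog[st.focal] < q1 - 1.5 * iqr:
            removed.append(st.focal)
    cells["Q1"] = cells["order"].map(q1s)
    cells["Q3"] = cells["order"].map(q3s)
    cells["IQR"] = cells["order"].map(iqrs)
    kept = cells[~cells["order"].isin(removed)].reset_index(drop=True)
    return kept, removed


def kmeans_sized(
    features: pd.DataFrame, n_clusters: int, cfg: PipelineConfig
) -> np.ndarray:
    """Z-scored k-means with labels re-ordered by ascending mean diameter.

    Clusters only the morphological columns (never position or ring zone);
    every column is centred and scaled (sd with n-1 denominator) before
    clustering with ``kmeans_nstart`` random restarts.  Raw k-means labels
    are arbitrary, so clusters are renumbered by their mean ``Meandiameterµm``
    so that 1 is always the smallest-celled cluster and ``n_clusters`` the
    largest; a (pathological) tie on the means is broken by cardinality,
    the larger cluster taking the smaller label.
    """
    if len(features) < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} objects for {n_clusters}-cluster k-means, "
            f"got {len(features)}"
        )
    x = features[CLUSTER_FEATURES].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if len(x) > 1 else np.ones(x.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    km = KMeans(
        n_clusters=n_clusters,
        n_init=cfg.kmeans_nstart,
        max_iter=cfg.kmeans_max_iter,
        init="random",
        random_state=cfg.random_seed,
    )
    with warnings.catch_warnings():
        # duplicate rows can collapse clusters; the size-ordered relabelling
        # below copes, so silence the solver's complaint
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", category=ConvergenceWarning)
        raw = km.fit_predict(z)
    diam = features[DIAMETER_COL].to_numpy(dtype=float)
    stats = []
    for c in range(n_clusters):
        sel = raw == c
        stats.append((diam[sel].mean() if sel.any() else np.inf, -int(sel.sum()), c))
    order = [c for _, _, c in sorted(stats)]
    remap = np.empty(n_clusters, dtype=int)
    for newlab, c in enumerate(order, start=1):
        remap[c] = newlab
    return remap[raw]


def majority_decision(focal: int, neighbor_labels: np.ndarray) -> MajorityDecision:
    """Apply the SUM/MEAN/MAX majority rule around one cluster-1 object.

    ``MAX`` is the sum obtained if every neighbour were cluster 3; the focal
    object is an intercellular space when ``SUM >= MAX - MEAN`` (which
    subsumes the all-neighbours-cluster-3 case).
    """
    lab = np.asarray(neighbor_labels, dtype=float)
    s, m = float(lab.sum()), float(lab.mean())
    mx = 3.0 * len(lab)
    return MajorityDecision(focal=focal, SUM=s, MEAN=m, MAX=mx, is_intercellular=s >= mx - m)


def majority_rule_pass(
    cells: pd.DataFrame, nbrs: list[NeighborStats], labels3: np.ndarray
) -> tuple[pd.DataFrame, list[int]]:
    """Remove cluster-1 objects surrounded by a majority of cluster-3 cells.

    ``labels3`` must be size-ordered (1 = smallest).  Only cluster-1 objects
    are candidates; either all gated neighbours are cluster 3, or the
    SUM >= MAX - MEAN criterion holds.  Objects with no gated neighbours are
    kept (no evidence).
    """
    cells = cells.copy()
    cells["Cluster_drei"] = np.asarray(labels3, dtype=int)
    lab = cells.set_index("order")["Cluster_drei"]
    removed: list[int] = []
    for st in nbrs:
        if st.focal not in lab.index or lab[st.focal] != 1:
            continue
        nb = [i for i in st.neighbor_ids if i in lab.index]
        if not nb:
            continue
        nlab = lab.loc[nb].to_numpy()
        if (nlab == 3).all() or majority_decision(st.focal, nlab).is_intercellular:
            removed.append(st.focal)
    kept = cells[~cells["order"].isin(removed)].reset_index(drop=True)
    return kept, removed


def _cluster3_by_zone(cells: pd.DataFrame, cfg: PipelineConfig) -> np.ndarray:
    """3-cluster labels, computed per inter-ring zone when zones are large enough."""
    labels = np.full(len(cells), 2, dtype=int)
    glob = kmeans_sized(cells, 3, cfg) if len(cells) >= 3 else None
    if glob is not None:
        labels = glob.copy()
    zones = cells["ring_zone"] if "ring_zone" in cells else pd.Series(1, index=cells.index)
    for _, idx in cells.groupby(zones.values).groups.items():
        pos = cells.index.get_indexer(idx)
        if len(pos) >= MIN_ZONE_SIZE:
            labels[pos] = kmeans_sized(cells.iloc[pos], 3, cfg)
    return labels


def iterate_filtering(
    cells: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, FilterLog]:
    """Run all filtering stages repeatedly until a pass removes nothing.

    Each pass: small-object threshold, neighbour gating, diameter-outlier
    removal, per-zone 3-cluster k-means, majority rule.  The kept set
    shrinks weakly each pass, so termination is guaranteed.  Returns the
    surviving table (with ``Cluster_drei`` and quantile columns) and the
    removal log, whose ``intercell_area`` is the ``Intercellcount`` total.
    """
    flog = FilterLog()
    table = cells.reset_index(drop=True).copy()
    for col in ("Q1", "Q3", "IQR"):
        if col not in table:
            table[col] = np.nan
    if "Cluster_drei" not in table:
        table["Cluster_drei"] = 0
    n_pass = 0
    while True:
        n_pass += 1
        n_before = len(table)
        if n_before == 0:
            warnings.warn("all objects removed during filtering")
            break
        # 1. size threshold (sub-cellular debris / artifacts)
        thr = small_object_threshold(table["Diameter_log"].to_numpy(), cfg)
        small = table["Diameter_log"] < thr
        if small.any():
            drop = table[small]
            flog.add(n_pass, "small_object", drop["order"], drop["s.area"])
            table = table[~small].reset_index(drop=True)
        if len(table) < 2:
            break
        # 2. neighbour gating + diameter-outlier removal
        nbrs = gated_neighbors(table, cfg)
        table, removed = diameter_outlier_pass(table, nbrs)
        if removed:
            areas = cells.set_index("order").loc[removed, "s.area"]
            flog.add(n_pass, "diameter_outlier", removed, areas)
            nbrs = gated_neighbors(table, cfg) if len(table) >= 2 else []
        # 3. per-zone 3-cluster k-means + majority rule
        if len(table) >= 3 and nbrs:
            labels3 = _cluster3_by_zone(table, cfg)
            table, removed = majority_rule_pass(table, nbrs, labels3)
            if removed:
                areas = cells.set_index("order").loc[removed, "s.area"]
                flog.add(n_pass, "majority_rule", removed, areas)
        if len(table) == n_before:
            break
    log.info(
        "filtering: %d passes, %d removed (%d as intercellular)",
        n_pass,
        flog.n_removed,
        sum(1 for r in flog.records if r["stage"] != "small_object"),
    )
    return table.reset_index(drop=True), flog
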