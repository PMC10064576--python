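"""Master table assembly, phenotype summaries, validation and similarity.

Per-image object tables are concatenated into a master table carrying the
image-level pixel accounting; genotype summaries aggregate per-image
phenotypes (cell counts, diameters, ring counts, wall fraction, cluster
shares); validation regresses automated on manual counts; genotype
similarity uses a permutation-normalised Earth Mover's Distance on
per-image feature summaries, clustered hierarchically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .schema import DIAMETER_COL, MASTER_COLUMNS

log = logging.getLogger("rootphen")


def assemble_master(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-image tables into the master table.

    Every input must already carry the full master column set (object rows
    plus broadcast image-level values).  An image with zero surviving cells
    contributes a single all-NaN object row holding only the image-level
    columns, so its pixel accounting is not lost.
    """
    if not tables:
        raise ValueError("no per-image tables to assemble")
    for t in tables:
        missing = [c for c in MASTER_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"per-image table is missing master columns: {missing}")
    frames = [t[MASTER_COLUMNS] for t in tables]
    return pd.concat(frames, ignore_index=True)


@dataclass
class GenotypeSummary:
    genotype: str
    n_images: int
    n_cells_mean: float
    n_cells_sd: float
    max_diam_mean: float
    max_diam_sd: float
    mean_diam_mean: float
    mean_diam_sd: float
    n_rings_mean: float
    n_rings_sd: float
    wall_fraction_mean: float
    wall_fraction_sd: float
    vt_cell_share_pct: float
    vt_area_share_pct: float
    vt_mean_diam: float
    sp_mean_diam: float

    def to_row(self) -> dict:
        return {
            "Genotype": self.genotype,
            "Number of cells": self.n_cells_mean,
            "Number of cells SD": self.n_cells_sd,
            "Max cell diameter [µm]": self.max_diam_mean,
            "Max cell diameter SD": self.max_diam_sd,
            "Mean cell diameter [µm]": self.mean_diam_mean,
            "Mean cell diameter SD": self.mean_diam_sd,
            "Number of cambium rings": self.n_rings_mean,
            "Number of cambium rings SD": self.n_rings_sd,
            "Amount of cell wall material [% of ROI pixels]": self.wall_fraction_mean,
            "Amount of cell wall material SD": self.wall_fraction_sd,
            "VT share of cells [%]": self.vt_cell_share_pct,
            "VT share of area [%]": self.vt_area_share_pct,
            "Mean diameter VT [µm]": self.vt_mean_diam,
            "Mean diameter SP [µm]": self.sp_mean_diam,
        }


def _per_image_stats(master: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, g in master.groupby("Dataname", sort=True):
        cells = g[g["order"].notna()]
        vt = cells[cells["Cluster_zw"] == "VT"]
        sp = cells[cells["Cluster_zw"] == "SP"]
        area = cells["s.area"].sum()
        rows.append(
            {
                "Dataname": name,
                "n_cells": len(cells),
                "max_diam": cells[DIAMETER_COL].max() if len(cells) else np.nan,
                "mean_diam": cells[DIAMETER_COL].mean() if len(cells) else np.nan,
                "n_rings": g["nmdeep"].iloc[0],
                "wall_fraction": g["Cellwallcount"].iloc[0] / g["Innerpixarea"].iloc[0],
                "vt_cell_share": 100.0 * len(vt) / len(cells) if len(cells) else np.nan,
                "vt_area_share": 100.0 * vt["s.area"].sum() / area if area else np.nan,
                "vt_mean_diam": vt[DIAMETER_COL].mean() if len(vt) else np.nan,
                "sp_mean_diam": sp[DIAMETER_COL].mean() if len(sp) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_genotypes(
    master: pd.DataFrame, mapping: dict[str, str]
) -> list[GenotypeSummary]:
    """Aggregate per-image phenotypes to mean +/- sd per genotype.

    ``mapping`` maps every Dataname to its genotype; an unmapped image is an
    error.  Cluster shares and per-cluster diameters are computed per image
    and then averaged across the images of a genotype.
    """
    per_img = _per_image_stats(master)
    unmapped = [n for n in per_img["Dataname"] if n not in mapping]
    if unmapped:
        raise ValueError(f"images without genotype mapping: {unmapped}")
    per_img["genotype"] = [mapping[n] for n in per_img["Dataname"]]
    out = []
    for geno, g in per_img.groupby("genotype", sort=True):
        def ms(col: str) -> tuple[float, float]:
            v = g[col].to_numpy(dtype=float)
            return float(np.nanmean(v)), float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0

        out.append(
            GenotypeSummary(
                genotype=str(geno),
                n_images=len(g),
                n_cells_mean=ms("n_cells")[0],
                n_cells_sd=ms("n_cells")[1],
                max_diam_mean=ms("max_diam")[0],
                max_diam_sd=ms("max_diam")[1],
                mean_diam_mean=ms("mean_diam")[0],
                mean_diam_sd=ms("mean_diam")[1],
                n_rings_mean=ms("n_rings")[0],
                n_rings_sd=ms("n_rings")[1],
                wall_fraction_mean=ms("wall_fraction")[0],
                wall_fraction_sd=ms("wall_fraction")[1],
                vt_cell_share_pct=ms("vt_cell_share")[0],
                vt_area_share_pct=ms("vt_area_share")[0],
                vt_mean_diam=ms("vt_mean_diam")[0],
                sp_mean_diam=ms("sp_mean_diam")[0],
            )
        )
    return out


def summaries_to_frame(summaries: list[GenotypeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def validate_counts(auto: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination of regressing automated on manual counts."""
    auto = np.asarray(auto, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if auto.shape != truth.shape:
        raise ValueError(f"length mismatch: {auto.shape} vs {truth.shape}")
    if len(auto) < 3:
        raise ValueError("need at least 3 paired counts")
    res = stats.linregress(truth, auto)
    return float(res.rvalue**2)


def size_kde(
    diameters: np.ndarray, cfg: PipelineConfig, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of cell diameter with an absolute bandwidth (µm).

    The curve integrates to one; the bandwidth is ``cfg.kde_bandwidth``
    micrometres, independent of the sample spread.
    """
    d = np.asarray(diameters, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 diameters for a density estimate")
    sd = d.std(ddof=1)
    if sd == 0:
        sd = 1.0
    kde = stats.gaussian_kde(d, bw_method=cfg.kde_bandwidth / sd)
    if grid is None:
        pad = 4 * cfg.kde_bandwidth
        grid = np.linspace(d.min() - pad, d.max() + pad, 512)
    return grid, kde(grid)


# ---------------------------------------------------------------------------
# Earth Mover's Distance similarity between genotypes
# ---------------------------------------------------------------------------

_EMD_EXCLUDE = {"order", "m.cx", "m.cy", "Q1", "Q3", "IQR", "Dataname"}


def image_feature_vectors(master: pd.DataFrame) -> pd.DataFrame:
    """Per-image summary vector: mean, sd, max, min of each retained variable."""
    rows = []
    for name, g in master.groupby("Dataname", sort=True):
        cells = g[g["order"].notna()].copy()
        if "Cluster_zw" in cells:
            cells["Cluster_zw"] = cells["Cluster_zw"].map({"VT": 1, "SP": 2})
        feats: dict[str, float] = {"Dataname": name}
        for col in cells.columns:
            if col in _EMD_EXCLUDE or not np.issubdtype(cells[col].dtype, np.number):
                continue
            v = cells[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            feats[f"{col}.mean"] = float(v.mean())
            feats[f"{col}.sd"] = float(v.std(ddof=1)) if v.size > 1 else 0.0
            feats[f"{col}.max"] = float(v.max())
            feats[f"{col}.min"] = float(v.min())
        rows.append(feats)
    return pd.DataFrame(rows)


def _emd(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import wasserstein_distance_nd

    return float(wasserstein_distance_nd(a, b))


def emd_distance_matrix(
    vectors: pd.DataFrame,
    groups: dict[str, str],
    cfg: PipelineConfig,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise permutation-normalised EMD between genotype feature clouds.

    Feature columns are z-scored across images, each group's images (at most
    ``cfg.emd_n``, subsampled when larger) form a point cloud, and the raw
    EMD between two clouds is divided by the median EMD of
    ``cfg.emd_permutations`` random re-partitions of the pooled cloud, so a
    score near or below one is indistinguishable from noise.
    """
    names = vectors["Dataname"].tolist()
    unmapped = [n for n in names if n not in groups]
    if unmapped:
        raise ValueError(f"images without genotype mapping: {unmapped}")
    labels = sorted({groups[n] for n in names})
    if len(labels) < 2:
        raise ValueError("need at least two genotypes for a similarity analysis")
    x = vectors.drop(columns=["Dataname"]).to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    rng = np.random.default_rng(cfg.random_seed)
    cloud = {
        lab: z[[i for i, n in enumerate(names) if groups[n] == lab]] for lab in labels
    }
    for lab, arr in cloud.items():
        if len(arr) > cfg.emd_n:
            sel = rng.choice(len(arr), size=cfg.emd_n, replace=False)
            cloud[lab] = arr[np.sort(sel)]
    k = len(labels)
    dmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cloud[labels[i]], cloud[labels[j]]
            raw = _emd(a, b)
            pooled = np.vstack([a, b])
            na = len(a)
            perms = []
            for _ in range(cfg.emd_permutations):
                perm = rng.permutation(len(pooled))
                perms.append(_emd(pooled[perm[:na]], pooled[perm[na:]]))
            med = float(np.median(perms))
            dmat[i, j] = dmat[j, i] = raw / med if med > 0 else 0.0
    return dmat, labels


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def emd_dendrogram(
    master: pd.DataFrame, groups: dict[str, str], cfg: PipelineConfig
) -> tuple[str, np.ndarray, list[str]]:
    """Average-linkage dendrogram over the EMD genotype distances.

    Returns the Newick string, the pairwise distance matrix and the genotype
    label order.
    """
    vectors = image_feature_vectors(master)
    dmat, labels = emd_distance_matrix(vectors, groups, cfg)
    link = hierarchy.linkage(squareform(dmat, checks=False), method="average")
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, labels) + ";"
    return newick, dmat, labels


def plot_dendrogram(dmat: np.ndarray, labels: list[str], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    link = hierarchy.linkage(squareform(dmat, checks=False), method="average")
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(labels) + 1))
    hierarchy.dendrogram(link, labels=labels, orientation="left", ax=ax)
    ax.set_xlabel("EMD score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kde(master: pd.DataFrame, groups: dict[str, str], cfg: PipelineConfig, path) -> None:
    """Per-genotype Gaussian KDE of cell diameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    cells = master[master["order"].notna()]
    for geno in sorted({groups[n] for n in cells["Dataname"].unique()}):
        sel = cells["Dataname"].map(groups) == geno
        d = cells.loc[sel, DIAMETER_COL].to_numpy(dtype=float)
        if len(d) < 2:
            continue
        grid, dens = size_kde(d, cfg)
        ax.plot(grid, dens, label=str(geno))
    ax.set_xlabel("cell diameter [µm]")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
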