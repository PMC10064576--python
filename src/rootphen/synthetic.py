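"""Synthetic ring-structured storage-root tissue with full ground truth.

The generator emulates the features of a transverse-section mosaic that the
pipeline relies on: dark cell walls around light interiors, alternating
bands of small-celled (cambium-ring / vascular) and large-celled
(parenchyma) zones along x, intercellular voids at junctions between large
cells, sub-resolution specks (artifacts), an irregular bright non-tissue
region at the left margin, and objects truncated by the image border.

Geometry comes from a multiplicatively weighted Voronoi tessellation: seed
points are laid out on a jittered hexagonal sweep whose local pitch follows
a smooth raised-cosine band profile of the target cell diameter; each seed
carries a weight (half its target diameter) and every pixel is assigned to
the seed minimising ``distance / weight``.  Intercellular voids are planted
as low-weight seeds at triple junctions between large cells, so they render
smaller than all of their neighbours — the property the filtering stage
exploits.  Walls are drawn along region boundaries.  Every seed is recorded
with its true class, so each pipeline stage can be scored against the
plant.

Images are rendered at 0.4 µm/px (a 20x-objective class pixel pitch) so
that the smallest vascular cells span enough pixels to survive the
fixed-size morphological openings of the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from skimage import morphology, segmentation

from .config import PipelineConfig
from .imgio import ImageRecord

#: pixel pitch of rendered synthetic mosaics (µm per px)
SYNTHETIC_UM_PER_PX = 0.4


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic tissue mosaic.

    Defaults describe the study conditions the pipeline targets: a
    five-ring mosaic with 12 µm vascular and 35 µm parenchyma cells, 5% of
    the large-cell junctions voided by ~16 µm intercellular spaces, sparse
    artifact specks and an irregular non-tissue margin on the left.
    """

    width: int = 2800
    height: int = 500
    n_ring_bands: int = 5
    band_centers: tuple[float, ...] | None = None
    small_cell_diam_um: float = 12.0
    small_cell_sd_um: float = 1.5
    large_cell_diam_um: float = 35.0
    large_cell_sd_um: float = 4.0
    void_diam_um: float = 16.0
    wall_thickness: int = 3
    intercellular_rate: float = 0.05
    artifact_rate: float = 0.1
    edge_void: bool = True
    seed: int = 0
    um_per_px: float = SYNTHETIC_UM_PER_PX
    band_halfwidth_frac: float = 0.22

    def __post_init__(self) -> None:
        if self.band_centers is None and self.n_ring_bands > 0:
            lo, hi = 0.15 * self.width, 0.85 * self.width
            self.band_centers = tuple(np.linspace(lo, hi, self.n_ring_bands))
        elif self.band_centers is None:
            self.band_centers = ()
        centers = np.asarray(self.band_centers, dtype=float)
        if len(centers) != self.n_ring_bands:
            self.n_ring_bands = len(centers)
        if len(centers) > 1:
            spacing = np.diff(centers)
            if (spacing <= 0).any():
                raise ValueError("band_centers must be strictly increasing")
            max_diam_px = self.large_cell_diam_um / self.um_per_px
            if spacing.min() < 2 * max_diam_px:
                raise ValueError(
                    f"band spacing {spacing.min():.0f} px < twice the largest cell "
                    f"diameter ({2 * max_diam_px:.0f} px)"
                )
        if (centers < 0).any() or (centers >= self.width).any():
            raise ValueError("band_centers must lie within [0, width)")
        for r in (self.intercellular_rate, self.artifact_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def expected_cell_count(spec: SyntheticSpec) -> float:
    """Analytic estimate of the number of cells a spec will generate.

    Columns are spaced ``0.87*s(x)`` apart and carry ``height/s(x)`` cells,
    so the cell density per unit x is ``height / (0.87 * s(x)**2)``.
    """
    x = np.linspace(0, spec.width, 512)
    s = _target_diameter_px(x, spec)
    return float(np.trapezoid(spec.height / (0.87 * s**2), x))


def recommended_config(spec: SyntheticSpec, seed: int = 0) -> PipelineConfig:
    """Pipeline configuration matched to the synthetic rendering scale.

    Uses the generator's pixel pitch, and scales the ring-profile window to
    the sample density of the scaled-down mosaic: the default window of 150
    consecutive cells corresponds to roughly a third of an inter-ring period
    on a full-size mosaic with a few thousand cells, so the window is set to
    a third of the expected samples per planted period (~40 cells for the
    default spec).
    """
    periods = max(1, spec.n_ring_bands)
    w = int(round(expected_cell_count(spec) / periods / 3.0))
    return PipelineConfig(
        um_per_px=spec.um_per_px,
        ring_window_w=max(10, w),
        random_seed=seed,
    )


@dataclass
class SyntheticGroundTruth:
    """Per-object truth for a generated mosaic."""

    label_map: np.ndarray
    object_class: dict[int, str]  # cell_VT | cell_SP | intercellular | artifact
    true_diameter_um: dict[int, float]
    band_centers: np.ndarray
    wall_pixel_count: int
    edge_void_mask: np.ndarray | None = None

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.object_class.values():
            out[c] = out.get(c, 0) + 1
        return out


def _band_profile(x: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Raised-cosine band weight in [0, 1]; 1 = centre of a small-cell band."""
    b = np.zeros_like(np.asarray(x, dtype=float))
    centers = np.asarray(spec.band_centers, dtype=float)
    if len(centers) == 0:
        return b
    spacing = np.diff(centers).min() if len(centers) > 1 else 0.5 * spec.width
    h = spec.band_halfwidth_frac * spacing
    for c in centers:
        u = (x - c) / h
        mask = np.abs(u) < 1
        bump = np.zeros_like(b)
        bump[mask] = np.cos(np.pi * u[mask] / 2) ** 2
        b = np.maximum(b, bump)
    return b


def _target_diameter_px(x: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    b = _band_profile(x, spec)
    d_um = spec.large_cell_diam_um - (spec.large_cell_diam_um - spec.small_cell_diam_um) * b
    return d_um / spec.um_per_px


def _edge_boundary(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """x-extent of the irregular non-tissue region for every row y."""
    y = np.arange(spec.height)
    base = 0.020 * spec.width
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.004, 0.010, size=3) * spec.width
    e = base + sum(
        a * np.sin(2 * np.pi * y / spec.height * f + p)
        for a, f, p in zip(amp, (1.3, 2.7, 4.1), phase)
    )
    return np.clip(e, 2, 0.045 * spec.width)


def _weighted_labels(
    points: np.ndarray, weights: np.ndarray, w: int, h: int, k: int = 8
) -> np.ndarray:
    """Pixel-wise multiplicatively weighted Voronoi assignment.

    Each pixel goes to the seed minimising ``distance / weight``; larger
    weights claim proportionally more territory.  Restricting the argmin to
    the k nearest seeds of each pixel is exact in practice because weights
    vary smoothly relative to seed spacing.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    k = min(k, len(points))
    dist, idx = cKDTree(points).query(grid, k=k)
    if k == 1:
        return (idx + 1).astype(np.int32).reshape(h, w)
    scaled = dist / weights[idx]
    choice = np.argmin(scaled, axis=1)
    lab = idx[np.arange(len(idx)), choice] + 1
    return lab.astype(np.int32).reshape(h, w)


def generate_tissue(spec: SyntheticSpec) -> tuple[ImageRecord, SyntheticGroundTruth]:
    """Render one synthetic mosaic and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height

    # --- seed points on a jittered hexagonal sweep with band-graded pitch ---
    pts: list[tuple[float, float]] = []
    classes: list[str] = []
    radii: list[float] = []
    band_w: list[float] = []
    x = 1.0
    col = 0
    sd_small = spec.small_cell_sd_um / spec.um_per_px
    sd_large = spec.large_cell_sd_um / spec.um_per_px
    while x < w + spec.large_cell_diam_um / spec.um_per_px:
        b = float(_band_profile(np.array([x]), spec)[0])
        s = float(_target_diameter_px(np.array([x]), spec)[0])
        sd = sd_large + (sd_small - sd_large) * b
        s_col = max(4.0, s + float(rng.normal(0, sd)))
        y0 = (col % 2) * s_col / 2 + rng.uniform(0, s_col)
        ys = np.arange(y0 - s_col, h + s_col, s_col)
        for y in ys:
            xj = x + float(rng.normal(0, 0.12 * s_col))
            yj = y + float(rng.normal(0, 0.12 * s_col))
            pts.append((xj, yj))
            classes.append("cell_VT" if b > 0.5 else "cell_SP")
            radii.append(s_col / 2)
            band_w.append(b)
        x += 0.87 * s_col
        col += 1
    pts_arr = np.asarray(pts, dtype=float)
    radii_arr = np.asarray(radii, dtype=float)

    # --- irregular non-tissue margin: drop seeds inside it ---
    edge_x = _edge_boundary(spec, rng) if spec.edge_void else None
    if edge_x is not None:
        yy_idx = np.clip(np.round(pts_arr[:, 1]).astype(int), 0, h - 1)
        keep = pts_arr[:, 0] > edge_x[yy_idx] + 2.0
        pts_arr = pts_arr[keep]
        radii_arr = radii_arr[keep]
        classes = [c for c, kp in zip(classes, keep) if kp]
        band_w = [b for b, kp in zip(band_w, keep) if kp]

    # --- intercellular voids at triple junctions between large cells ---
    void_pts: list[tuple[float, float]] = []
    if spec.intercellular_rate > 0 and len(pts_arr) >= 4:
        vor = Voronoi(pts_arr)
        vert_regions: dict[int, set[int]] = {}
        for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
            for v in verts:
                if v >= 0:
                    vert_regions.setdefault(v, set()).update((int(p1), int(p2)))
        margin = spec.large_cell_diam_um / spec.um_per_px
        tree = cKDTree(pts_arr)
        band_arr = np.asarray(band_w)
        eligible = []
        for v in sorted(vert_regions):
            regs = vert_regions[v]
            if len(regs) < 3:
                continue
            vx, vy = vor.vertices[v]
            if not (margin < vx < w - margin and margin < vy < h - margin):
                continue
            # voids occur between fully grown parenchyma cells (which are
            # always larger than the void itself), i.e. in the parenchyma
            # proper, away from the small-celled ring bands
            near = tree.query_ball_point([vx, vy], r=1.2 * margin)
            if near and all(band_arr[p] < 0.3 for p in near):
                eligible.append((float(vx), float(vy)))
        if eligible:
            n_voids = int(round(spec.intercellular_rate * len(eligible)))
            # a minimum mutual separation: two voids sharing a wall would
            # physically be one larger void
            order = rng.permutation(len(eligible))
            chosen: list[tuple[float, float]] = []
            for i in order:
                p = eligible[i]
                if len(chosen) >= n_voids:
                    break
                if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > margin**2 for q in chosen):
                    chosen.append(p)
            void_pts = sorted(chosen)
    void_weight = spec.void_diam_um / spec.um_per_px / 2
    all_pts = np.vstack([pts_arr, np.asarray(void_pts, dtype=float).reshape(-1, 2)])
    all_weights = np.concatenate([radii_arr, np.full(len(void_pts), void_weight)])
    classes = classes + ["intercellular"] * len(void_pts)

    # --- rasterise: weighted tessellation, walls on region boundaries ---
    labels = _weighted_labels(all_pts, all_weights, w, h)
    wall = segmentation.find_boundaries(labels, mode="thick", connectivity=2)
    grow = (spec.wall_thickness - 1) // 2
    if grow > 0:
        wall = morphology.dilation(wall, morphology.disk(grow))

    image = np.where(wall, 0.15, 0.85)
    label_map = np.where(wall, 0, labels)

    # --- non-tissue margin rendering ---
    edge_mask = None
    if edge_x is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        edge_mask = xx < edge_x[:, None]
        rim = morphology.dilation(edge_mask, morphology.disk(spec.wall_thickness)) & ~edge_mask
        image[rim] = 0.15
        label_map[rim] = 0
        image[edge_mask] = 0.92
        label_map[edge_mask] = 0
        wall = wall & ~edge_mask & ~rim

    wall_pixel_count = int(wall.sum())

    # --- artifact specks: sub-opening-scale bright dots on walls ---
    object_class = {i + 1: c for i, c in enumerate(classes)}
    n_specks = int(round(spec.artifact_rate * (w * h) / 1e4))
    wall_ys, wall_xs = np.nonzero(wall)
    next_id = len(all_pts) + 1
    for _ in range(n_specks):
        if len(wall_ys) == 0:
            break
        j = int(rng.integers(len(wall_ys)))
        cy, cx = int(wall_ys[j]), int(wall_xs[j])
        r = int(rng.integers(1, 4))
        dsk = morphology.disk(r).astype(bool)
        y0, x0 = cy - r, cx - r
        y1, x1 = y0 + dsk.shape[0], x0 + dsk.shape[1]
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            continue
        image[y0:y1, x0:x1][dsk] = 0.9
        label_map[y0:y1, x0:x1][dsk] = next_id
        object_class[next_id] = "artifact"
        next_id += 1

    image = np.clip(image + rng.normal(0, 0.04, size=image.shape), 0.0, 1.0)

    areas = np.bincount(label_map.ravel(), minlength=next_id)
    true_diameter = {
        i: float(2.0 * np.sqrt(areas[i] / np.pi) * spec.um_per_px)
        for i in object_class
        if i < len(areas) and areas[i] > 0
    }
    truth = SyntheticGroundTruth(
        label_map=label_map,
        object_class=object_class,
        true_diameter_um=true_diameter,
        band_centers=np.asarray(spec.band_centers, dtype=float),
        wall_pixel_count=wall_pixel_count,
        edge_void_mask=edge_mask,
    )
    return ImageRecord(dataname=f"synthetic_seed{spec.seed}.tif", pixels=image), truth


# ---------------------------------------------------------------------------
# recovery scoring against ground truth
# ---------------------------------------------------------------------------

def match_objects(labels: np.ndarray, truth: SyntheticGroundTruth) -> dict[int, int]:
    """Map each segmented object id to the planted object it mostly overlaps.

    Majority vote over the truth label under each object's pixels; objects
    lying mostly on walls/background map to 0.
    """
    obj = labels.ravel()
    tru = truth.label_map.ravel()
    sel = obj > 0
    obj, tru = obj[sel], tru[sel]
    n_t = int(truth.label_map.max()) + 1
    pair = obj.astype(np.int64) * n_t + tru
    counts = np.bincount(pair)
    best: dict[int, tuple[int, int]] = {}
    for p in np.nonzero(counts)[0]:
        o, t = divmod(int(p), n_t)
        c = int(counts[p])
        if o not in best or c > best[o][0]:
            best[o] = (c, t)
    return {o: t for o, (_, t) in best.items()}


def filtering_recovery(
    initial_ids: np.ndarray,
    final_ids: np.ndarray,
    mapping: dict[int, int],
    truth: SyntheticGroundTruth,
) -> dict[str, float]:
    """Score the filtering stages against the planted classes.

    A planted object counts as *present* if any initial segmented object maps
    to it, and as *surviving* if any final object does.  Returns the void
    removal rate and the true-cell false-removal rate (both fractions).
    """

    def planted(ids: np.ndarray) -> set[int]:
        return {mapping.get(int(i), 0) for i in np.asarray(ids)} - {0}

    present = planted(initial_ids)
    surviving = planted(final_ids)
    voids = {t for t in present if truth.object_class.get(t) == "intercellular"}
    cells = {t for t in present if truth.object_class.get(t, "").startswith("cell")}
    return {
        "n_voids_present": len(voids),
        "n_cells_present": len(cells),
        "void_removal_rate": (
            len(voids - surviving) / len(voids) if voids else float("nan")
        ),
        "cell_false_removal_rate": (
            len(cells - surviving) / len(cells) if cells else float("nan")
        ),
    }


def tissue_agreement(
    final_table, labels: np.ndarray, truth: SyntheticGroundTruth
) -> float:
    """Fraction of surviving cells whose VT/SP call matches the planted class."""
    mapping = match_objects(labels, truth)
    hits = total = 0
    for _, row in final_table.iterrows():
        t = mapping.get(int(row["order"]), 0)
        cls = truth.object_class.get(t)
        if cls not in ("cell_VT", "cell_SP"):
            continue
        total += 1
        if ("VT" if cls == "cell_VT" else "SP") == row["Cluster_zw"]:
            hits += 1
    return hits / total if total else float("nan")
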