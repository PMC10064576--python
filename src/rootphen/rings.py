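"""Cambium-ring detection from the cell-diameter profile.

Beet storage roots alternate bands of small-celled vascular tissue (around
the cambium rings) and large-celled storage parenchyma.  Plotting cell
diameter against distance from the periderm (left margin) therefore gives an
oscillating profile: valleys mark cambium rings, peaks mark the centres of
the parenchyma bands.  Rings are numbered 1.. from the left (outermost)
inwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import PipelineConfig

log = logging.getLogger("rootphen")


@dataclass
class RingSet:
    """Ordered peak (parenchyma) and valley (cambium ring) x-positions."""

    valley_x: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_x: np.ndarray = field(default_factory=lambda: np.array([]))
    smoothed_profile: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x", "diameter_smoothed"])
    )

    @property
    def nmdeep(self) -> int:
        return int(len(self.valley_x))

    @property
    def nmbpeak(self) -> int:
        return int(len(self.peak_x))


def _window_extrema(y: np.ndarray, w: int) -> np.ndarray:
    """Indices i that are the maximum of the centred window of width ``w``.

    A candidate must strictly exceed every sample to its left within the
    window (leftmost tie wins) and be >= every sample to its right; indices
    whose window would be truncated by the series ends are excluded, so a
    monotone profile yields no extrema.
    """
    n = len(y)
    half = max(1, w // 2)
    out = []
    for i in range(half, n - half):
        left = y[i - half : i]
        right = y[i + 1 : i + half + 1]
        if (y[i] > left).all() and (y[i] >= right).all():
            out.append(i)
    return np.asarray(out, dtype=int)


def _enforce_alternation(
    peaks: np.ndarray, valleys: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of same-type extrema so peaks and valleys interleave."""
    events = [(int(i), "p") for i in peaks] + [(int(i), "v") for i in valleys]
    events.sort()
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = (y[idx] > y[prev_idx]) if kind == "p" else (y[idx] < y[prev_idx])
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    p = np.array([i for i, k in kept if k == "p"], dtype=int)
    v = np.array([i for i, k in kept if k == "v"], dtype=int)
    return p, v


def detect_rings(cells: pd.DataFrame, cfg: PipelineConfig) -> RingSet:
    """Locate parenchyma peaks and cambium-ring valleys along x.

    Cells are sorted by their centre-of-mass x; the diameter series is
    smoothed with a loess-type local regression (span ``cfg.ring_span``);
    local maxima of the smoothed series within a sliding window of
    ``cfg.ring_window_w`` samples are peaks, and maxima of the negated
    series are valleys.  Fewer than ``2 * ring_window_w`` cells yield an
    empty :class:`RingSet` with a warning.
    """
    if len(cells) < 2 * cfg.ring_window_w:
        warnings.warn(
            f"only {len(cells)} cells; need >= {2 * cfg.ring_window_w} for ring "
            "detection, returning empty RingSet"
        )
        return RingSet()
    srt = cells.sort_values("m.cx", kind="mergesort")
    x = srt["m.cx"].to_numpy(dtype=float)
    d = srt["Meandiameterµm"].to_numpy(dtype=float)
    sm = lowess(d, x, frac=cfg.ring_span, return_sorted=False)
    # an (almost) flat profile has no biologically meaningful extrema;
    # guard against numerical jitter of the smoother
    if np.ptp(sm) <= 1e-9 * max(1.0, float(np.abs(sm).max())):
        return RingSet(smoothed_profile=pd.DataFrame({"x": x, "diameter_smoothed": sm}))
    peaks_i = _window_extrema(sm, cfg.ring_window_w)
    valleys_i = _window_extrema(-sm, cfg.ring_window_w)
    peaks_i, valleys_i = _enforce_alternation(peaks_i, valleys_i, x, sm)
    profile = pd.DataFrame({"x": x, "diameter_smoothed": sm})
    rings = RingSet(
        valley_x=x[valleys_i] if len(valleys_i) else np.array([]),
        peak_x=x[peaks_i] if len(peaks_i) else np.array([]),
        smoothed_profile=profile,
    )
    log.info("rings: %d valleys (cambium rings), %d peaks", rings.nmdeep, rings.nmbpeak)
    return rings


def assign_ring_zone(cells: pd.DataFrame, rings: RingSet) -> pd.DataFrame:
    """Assign each cell the index of the inter-ring zone it lies in.

    ``ring_zone = 1 + number of valleys strictly left of the cell's m.cx``;
    with no detected valleys every cell is in zone 1.  Also broadcasts the
    image-level ``nmbpeak``/``nmdeep`` counts onto the table.
    """
    cells = cells.copy()
    cx = cells["m.cx"].to_numpy(dtype=float)
    if rings.nmdeep:
        zone = 1 + np.searchsorted(np.sort(rings.valley_x), cx, side="left")
    else:
        zone = np.ones(len(cells), dtype=int)
    cells["ring_zone"] = zone.astype(int)
    cells["nmbpeak"] = rings.nmbpeak
    cells["nmdeep"] = rings.nmdeep
    return cells


def plot_profile(rings: RingSet, cells: pd.DataFrame, path) -> None:
    """Diameter-vs-x scatter with the smoothed profile, valleys and peaks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.scatter(cells["m.cx"], cells["Meandiameterµm"], s=3, alpha=0.3, color="gray")
    if len(rings.smoothed_profile):
        ax.plot(rings.smoothed_profile["x"], rings.smoothed_profile["diameter_smoothed"], "k-")
    for v in rings.valley_x:
        ax.axvline(v, color="red", ls="--", lw=1)
    for p in rings.peak_x:
        ax.plot([p], [cells["Meandiameterµm"].max() * 0.95], "bo", ms=4)
    ax.set_xlabel("distance from left margin [px]")
    ax.set_ylabel("cell diameter [µm]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
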