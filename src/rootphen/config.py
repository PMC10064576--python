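"""Pipeline configuration.

Every numeric parameter of the workflow lives in :class:`PipelineConfig` so a
run is fully described by one small YAML file.  Defaults are the values the
workflow was calibrated with on FCA-stained beet storage-root mosaics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates an invariant."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the phenotyping pipeline.

    Attributes
    ----------
    gaussian_sigma
        Standard deviation of the Gaussian smoothing applied before Otsu
        thresholding (dimensionless, in pixels).
    opening_radius_1, opening_radius_2
        Brush *sizes* (diameters, px) of the two morphological opening
        cycles applied to the binary mask; the effective disc radius is
        ``size // 2``, following the brush convention of the R imaging
        toolbox this workflow descends from.
    edge_fraction
        Fraction of the image width, measured from the left margin, that is
        searched for the non-tissue peridermal edge region.
    edge_opening_radius
        Brush size (px) of the high opening used to isolate the peridermal
        edge region.
    um_per_px
        Pixel pitch of the micrographs in micrometres per pixel.
    ring_window_w
        Width, in profile samples (cells), of the sliding window used for
        peak/valley detection on the smoothed diameter profile.
    ring_span
        Span fraction of the loess-type smoother applied to the
        diameter-versus-x profile.
    k_neighbors
        Maximum number of nearest neighbours consulted per object.
    fallback_log_threshold
        Small-object threshold in log10 µm used when the diameter histogram
        is not bimodal (0.5, i.e. ~3 µm).
    max_log_threshold
        Upper cap on the histogram-valley threshold (0.8) so that viable
        cells are never dropped.
    kmeans_nstart, kmeans_max_iter
        Restart count and iteration cap of every k-means clustering.
    kde_bandwidth
        Gaussian kernel bandwidth (µm) of the cell-size density estimate.
    emd_permutations, emd_n
        Number of label permutations used to normalise the Earth Mover's
        Distance score, and the subsample size per group.
    random_seed
        Seed for every stochastic component (k-means restarts, EMD
        permutations and subsampling).
    median_distance_fence
        If True (default) the neighbour-distance gate uses the literal
        ``Q2 + 1.5*IQR`` fence; if False the conventional Q3-based fence.
    """

    gaussian_sigma: float = 2.0
    opening_radius_1: int = 18
    opening_radius_2: int = 21
    edge_fraction: float = 0.05
    edge_opening_radius: int = 50
    um_per_px: float = 1.015228
    ring_window_w: int = 150
    ring_span: float = 0.2
    k_neighbors: int = 6
    fallback_log_threshold: float = 0.5
    max_log_threshold: float = 0.8
    kmeans_nstart: int = 25
    kmeans_max_iter: int = 1000
    kde_bandwidth: float = 1.0
    emd_permutations: int = 100
    emd_n: int = 40
    random_seed: int = 0
    median_distance_fence: bool = True

    def __post_init__(self) -> None:
        positive = [
            "gaussian_sigma", "opening_radius_1", "opening_radius_2",
            "edge_opening_radius", "um_per_px", "ring_window_w", "ring_span",
            "k_neighbors", "kmeans_nstart", "kmeans_max_iter",
            "kde_bandwidth", "emd_permutations", "emd_n",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if not 0 < self.edge_fraction < 1:
            raise ConfigError(f"edge_fraction must lie in (0, 1), got {self.edge_fraction!r}")
        if self.fallback_log_threshold > self.max_log_threshold:
            raise ConfigError(
                "fallback_log_threshold must not exceed max_log_threshold "
                f"({self.fallback_log_threshold} > {self.max_log_threshold})"
            )

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _coerce(mapping: Mapping[str, Any]) -> PipelineConfig:
    unknown = set(mapping) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**mapping)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key/value file.

    Missing keys take their defaults; an empty file (or ``None``) yields the
    default configuration.  Malformed YAML raises :class:`ConfigError` naming
    the offending line; invariant violations raise :class:`ConfigError`
    naming the field.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse config file {path}{line}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a key: value mapping")
    return _coerce(data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write ``cfg`` as YAML such that ``load_config(dump_config(cfg)) == cfg``."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
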