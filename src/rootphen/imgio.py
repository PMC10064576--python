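"""Raster input, table output and overlay rendering.

Micrographs arrive as TIFF (PNG also accepted), one tissue mosaic per file,
with the periderm oriented at the left image margin.  Images are collapsed
to grayscale and rescaled to [0, 1] so that downstream thresholding is
independent of bit depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("rootphen")

# ITU-R 601 luminance weights; the staining colour channels are deliberately
# collapsed (colour carries stain chemistry, not the geometry used here).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """A grayscale micrograph normalised to [0, 1].

    ``dataname`` is the source file basename and ends up in the master
    table's ``Dataname`` column.
    """

    dataname: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D grayscale array")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to float64 luminance, rescaled to [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        # constant image: map into [0,1] without inventing contrast
        arr = np.clip(arr, 0.0, 1.0) if hi <= 1.0 else np.ones_like(arr)
    return arr


def read_image(path: str | Path) -> ImageRecord:
    """Read a TIFF/PNG micrograph into a normalised :class:`ImageRecord`."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"image {path} has zero area")
    return ImageRecord(dataname=path.name, pixels=to_grayscale(arr))


def from_array(arr: np.ndarray, dataname: str = "array") -> ImageRecord:
    """Wrap an in-memory array (any dtype, 2-D or RGB) as an ImageRecord."""
    return ImageRecord(dataname=dataname, pixels=to_grayscale(arr))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0,1] float or uint8 array as TIFF/PNG."""
    path = Path(path)
    arr = pixels
    if arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=np.float64), 0.0, 1.0)
        arr = np.round(arr * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialise an object/master table as UTF-8 CSV with full precision."""
    table.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def save_label_overlay(path: str | Path, image: np.ndarray, labels: np.ndarray) -> None:
    """PNG overlay of a label image on the micrograph (one colour per object)."""
    from skimage.color import label2rgb

    rgb = label2rgb(labels, image=image, bg_label=0, alpha=0.4)
    write_image(path, rgb if rgb.ndim == 2 else (rgb * 255).astype(np.uint8))


def save_tissue_overlay(
    path: str | Path,
    image: np.ndarray,
    labels: np.ndarray,
    table: pd.DataFrame,
) -> None:
    """Colour surviving cells by tissue class: VT green, SP blue."""
    rgb = np.stack([image, image, image], axis=-1)
    if len(table):
        vt = set(table.loc[table["Cluster_zw"] == "VT", "order"].astype(int))
        sp = set(table.loc[table["Cluster_zw"] == "SP", "order"].astype(int))
        flat = labels.ravel()
        colour = np.zeros(labels.max() + 1, dtype=np.uint8)  # 0 none, 1 VT, 2 SP
        for i in vt:
            colour[i] = 1
        for i in sp:
            colour[i] = 2
        cls = colour[flat].reshape(labels.shape)
        green = cls == 1
        blue = cls == 2
        rgb[green] = 0.5 * rgb[green] + 0.5 * np.array([0.0, 0.8, 0.0])
        rgb[blue] = 0.5 * rgb[blue] + 0.5 * np.array([0.0, 0.2, 0.9])
    write_image(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
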