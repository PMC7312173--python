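"""Slide raster IO, tiling and region quality control.

TIFF is the on-disk interchange format: 8/16-bit grayscale for channels
(values are promoted to float in memory but never rescaled), 32-bit signed
integer for label maps.  Per-nucleus tables travel as CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .types import (QC_BLURRY, QC_NO_CELLS, QC_OK, Channel, FastAxis, QCMask,
                    SlideImage)

log = logging.getLogger(__name__)


def read_slide(path, channel: Channel, pixel_size: float | None = None,
               fast_axis: FastAxis = "rows") -> SlideImage:
    """Load a single-channel grayscale TIFF as a :class:`SlideImage`.

    8/16-bit integer data is promoted to float64 with values preserved
    exactly (an 8-bit value of 200 stays 200).  Multi-channel / RGB files
    are rejected; pass each channel as its own grayscale file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)  # raises on truncated/corrupt files
    if arr.ndim != 2:
        raise ValueError(
            f"{path} has shape {arr.shape}; expected a 2D single-channel grayscale "
            "image — split channels into separate files")
    if pixel_size is None:
        pixel_size = _pixel_size_from_tiff(path)
        if pixel_size is None:
            raise ValueError(
                f"{path} carries no resolution metadata; pass pixel_size "
                "explicitly (CLI: --pixel-size UM_PER_PX)")
    return SlideImage(arr.astype(np.float64), channel=channel,
                      pixel_size=pixel_size, fast_axis=fast_axis)


def _pixel_size_from_tiff(path) -> float | None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        px_per_unit = num / den
        if getattr(unit.value, "name", str(unit.value)) in ("CENTIMETER", "3"):
            return 1e4 / px_per_unit
        return None


def write_slide(path, image: SlideImage, dtype=np.uint16) -> None:
    """Write a slide channel as TIFF with resolution metadata.

    Float rasters are rounded into the target integer dtype; values must
    already fit its range (no rescaling is applied).
    """
    arr = image.pixels
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.round(arr), info.min, info.max).astype(dtype)
    else:
        arr = arr.astype(dtype)
    px_per_cm = 1e4 / image.pixel_size
    tifffile.imwrite(path, arr, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- tiling -----------------------------------------------------------------

def _tile_starts(n: int, tile: int, step: int) -> list[int]:
    if tile >= n:
        return [0]
    starts = list(range(0, n - tile + 1, step))
    if starts[-1] + tile < n:
        starts.append(n - tile)
    return starts


def tile_iterator(image: SlideImage, tile: int = 2048, overlap: int = 128
                  ) -> Iterator[tuple[np.ndarray, tuple[int, int]]]:
    """Yield ``(tile_pixels, (row_offset, col_offset))`` covering the raster.

    Tiles step by ``tile - overlap``; the last tile in each axis is shifted
    back so the union covers every pixel.  A tile larger than the image
    yields the whole image once.  Requires ``tile > 2 * overlap``.
    """
    if tile <= 2 * overlap:
        raise ValueError(f"tile ({tile}) must exceed 2 * overlap ({overlap})")
    h, w = image.shape
    step = tile - overlap
    for r0 in _tile_starts(h, tile, step):
        for c0 in _tile_starts(w, tile, step):
            yield image.pixels[r0:min(r0 + tile, h), c0:min(c0 + tile, w)], (r0, c0)


def stitch_tiles(tiles, shape: tuple[int, int]) -> np.ndarray:
    """Reassemble ``tile_iterator`` output; overlapping pixels are rewritten
    with identical values, so the result reproduces the original exactly."""
    out = np.zeros(shape)
    for t, (r0, c0) in tiles:
        out[r0:r0 + t.shape[0], c0:c0 + t.shape[1]] = t
    return out


# -- quality control --------------------------------------------------------

def focus_metric(pixels: np.ndarray) -> float:
    """Per-tile focus score: variance of the Laplacian normalized by the
    squared mean intensity (unitless, falls sharply with defocus blur)."""
    m = float(pixels.mean())
    if m <= 0:
        return 0.0
    lap = ndimage.laplace(pixels.astype(float))
    return float(lap.var() / (m * m))


def qc_mask(image: SlideImage, labels: np.ndarray | None = None,
            centroids: np.ndarray | None = None,
            tile: int = 512,
            density_threshold: float = 10.0,
            focus_threshold: float = 0.0) -> QCMask:
    """Flag unusable tiles: too few nuclei (``no_cells``) or out of focus
    (``blurry``).

    Density uses either a label map or an (n, 2) array of centroid pixel
    coordinates; threshold is nuclei per mm^2.  Focus tiles are scored with
    :func:`focus_metric` and compared against ``focus_threshold``
    (0 disables the blur check).  Tiles failing both checks report
    ``no_cells``.
    """
    h, w = image.shape
    nt_r = -(-h // tile)
    nt_c = -(-w // tile)
    reasons = np.full((nt_r, nt_c), QC_OK, dtype=np.int8)

    counts = np.zeros((nt_r, nt_c))
    if centroids is None and labels is not None:
        cents = ndimage.center_of_mass(labels > 0, labels, np.unique(labels[labels > 0]))
        centroids = np.array(cents).reshape(-1, 2)
    if centroids is not None and len(centroids):
        i = np.clip(centroids[:, 0].astype(int) // tile, 0, nt_r - 1)
        j = np.clip(centroids[:, 1].astype(int) // tile, 0, nt_c - 1)
        np.add.at(counts, (i, j), 1)

    for i in range(nt_r):
        for j in range(nt_c):
            block = image.pixels[i * tile:(i + 1) * tile, j * tile:(j + 1) * tile]
            area_mm2 = block.size * (image.pixel_size * 1e-3) ** 2
            if counts[i, j] / area_mm2 < density_threshold:
                reasons[i, j] = QC_NO_CELLS
            elif focus_threshold > 0 and focus_metric(block) < focus_threshold:
                reasons[i, j] = QC_BLURRY
    n_bad = int((reasons != QC_OK).sum())
    if n_bad:
        log.info("qc_mask: %d/%d tiles masked", n_bad, reasons.size)
    return QCMask(reasons=reasons, tile=tile, image_shape=(h, w))
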