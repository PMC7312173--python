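"""Core in-memory data structures shared across the pipeline.

Coordinate convention (used everywhere in this package):

* pixel coordinates are 0-based ``(row, col)``, row-major;
* physical coordinates are ``pixel * pixel_size`` micrometres, measured
  from the slide origin;
* ``fast_axis`` names the image axis along which a single scanner line
  runs.  With ``fast_axis == "rows"`` each scan line is one image row,
  scan lines are stacked along the row index (the slow axis) and stripe
  artifacts show up as anomalous whole rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Channel = Literal["dapi", "gh2ax"]
FastAxis = Literal["rows", "cols"]

#: QC reason codes, stored in :class:`QCMask.reasons`.
QC_OK = 0
QC_NO_CELLS = 1
QC_BLURRY = 2

QC_REASON_NAMES = {QC_OK: "ok", QC_NO_CELLS: "no_cells", QC_BLURRY: "blurry"}


@dataclass
class SlideImage:
    """A single-channel 2D intensity raster with physical metadata.

    Parameters
    ----------
    pixels:
        2D array of finite, non-negative intensities (any numeric dtype;
        processing code promotes to float without rescaling values).
    channel:
        ``"dapi"`` (nuclear DNA stain) or ``"gh2ax"`` (DSB marker).
    pixel_size:
        Pixel pitch in micrometres per pixel (isotropic).
    fast_axis:
        Scan-line orientation, see module docstring.
    origin:
        Physical offset (row_um, col_um) of pixel (0, 0) on the slide.
    """

    pixels: np.ndarray
    channel: Channel = "dapi"
    pixel_size: float = 0.5
    fast_axis: FastAxis = "rows"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"SlideImage requires a 2D raster, got ndim={self.pixels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.channel not in ("dapi", "gh2ax"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.fast_axis not in ("rows", "cols"):
            raise ValueError(f"fast_axis must be 'rows' or 'cols', got {self.fast_axis!r}")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("SlideImage intensities must be finite")
            if self.pixels.size and float(self.pixels.min()) < 0:
                raise ValueError("SlideImage intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def slow_axis(self) -> int:
        """Array axis index of the slow scan direction (0 = rows, 1 = cols)."""
        return 0 if self.fast_axis == "rows" else 1

    def with_pixels(self, pixels: np.ndarray) -> "SlideImage":
        """Copy of this slide with a new raster, same metadata."""
        return replace(self, pixels=pixels)

    def to_physical(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel (row, col) to physical micrometres on the slide."""
        return (np.asarray(rows) * self.pixel_size + self.origin[0],
                np.asarray(cols) * self.pixel_size + self.origin[1])


@dataclass
class QCMask:
    """Per-tile quality-control mask.

    ``reasons`` is a small 2D grid (one entry per tile); entry 0 means the
    tile is usable, non-zero entries carry a reason code (``QC_NO_CELLS``
    or ``QC_BLURRY``).  ``tile`` is the tile edge in pixels used to build
    the grid, so tile (i, j) covers pixel block
    ``[i*tile:(i+1)*tile, j*tile:(j+1)*tile]`` clipped to the image.
    """

    reasons: np.ndarray
    tile: int
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.reasons = np.asarray(self.reasons, dtype=np.int8)
        if self.reasons.ndim != 2:
            raise ValueError("QCMask.reasons must be 2D")

    @property
    def masked(self) -> np.ndarray:
        """Boolean tile grid, True where the tile is discarded."""
        return self.reasons != QC_OK

    def pixel_mask(self) -> np.ndarray:
        """Expand the tile grid to a full-resolution boolean mask."""
        out = np.zeros(self.image_shape, dtype=bool)
        for i in range(self.reasons.shape[0]):
            for j in range(self.reasons.shape[1]):
                if self.reasons[i, j] != QC_OK:
                    out[i * self.tile:(i + 1) * self.tile,
                        j * self.tile:(j + 1) * self.tile] = True
        return out

    def tile_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.clip(np.asarray(row, dtype=int) // self.tile, 0, self.reasons.shape[0] - 1)
        j = np.clip(np.asarray(col, dtype=int) // self.tile, 0, self.reasons.shape[1] - 1)
        return i, j

    def passes(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """True for pixel positions whose tile is not masked."""
        i, j = self.tile_of(row, col)
        return self.reasons[i, j] == QC_OK


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stage random generator.

    A single user-facing seed fans out to independent streams keyed by a
    stable stage name, so adding a stage never perturbs the others.
    """
    h = np.frombuffer(stream.encode(), dtype=np.uint8)
    child = np.random.SeedSequence([seed, *h.tolist()])
    return np.random.default_rng(child)
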