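"""Core containers for B-mode frames and rectangular regions of interest.

Conventions used throughout the package:

* image coordinates are 0-based with ``x`` = column and ``y`` = row,
  rows increasing downward;
* orientations are in degrees, measured from the image horizontal,
  positive counter-clockwise as displayed (a line with positive angle
  rises to the right);
* gray values are 8-bit, 0-255.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

MIN_FRAME_SIZE = 128


class FrameError(ValueError):
    """Raised for frames that violate the container invariants."""


@dataclass(frozen=True)
class Frame:
    """One 8-bit grayscale B-mode image plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of gray values.
    gel_pad_deg
        Wedge angle of the coupling gel pad used for this sweep, degrees.
    frame_index
        Index of the frame within its sweep (probe translation step).
    specimen_id
        Free-text specimen identifier.
    pixel_spacing_mm
        Optional physical pixel size, mm/pixel.
    """

    pixels: np.ndarray
    gel_pad_deg: float = 0.0
    frame_index: int = 0
    specimen_id: str = ""
    pixel_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FrameError("frame pixels must be a 2-D array")
        if px.shape[0] < MIN_FRAME_SIZE or px.shape[1] < MIN_FRAME_SIZE:
            raise FrameError(
                f"frame must be at least {MIN_FRAME_SIZE}x{MIN_FRAME_SIZE} pixels, "
                f"got {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FrameError("gray values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass(frozen=True)
class ROISpec:
    """An (optionally rotated) rectangular region of interest.

    The rectangle is defined by its center (``center_x``, ``center_y``),
    size and orientation; ``orientation_deg`` = 0 means axis-aligned.
    The same size and orientation are reused for every frame of a study,
    only the placement follows the detected epimysium.
    """

    center_x: float
    center_y: float
    width: int
    height: int
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")

    def bounds(self) -> tuple[int, int, int, int]:
        """Integer (row0, row1, col0, col1) slice bounds (axis-aligned only)."""
        if self.orientation_deg % 360 != 0:
            raise ValueError("bounds() is only defined for axis-aligned ROIs")
        row0 = int(round(self.center_y - self.height / 2))
        col0 = int(round(self.center_x - self.width / 2))
        return row0, row0 + self.height, col0, col0 + self.width

    def fits_in(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        half = np.hypot(self.width / 2, self.height / 2)
        if self.orientation_deg % 360 == 0:
            r0, r1, c0, c1 = self.bounds()
            return r0 >= 0 and c0 >= 0 and r1 <= h and c1 <= w
        return (
            self.center_x - half >= 0
            and self.center_y - half >= 0
            and self.center_x + half <= w
            and self.center_y + half <= h
        )

    def recenter(self, center_x: float, center_y: float) -> "ROISpec":
        return replace(self, center_x=center_x, center_y=center_y)


def write_frame(frame: Frame, path: str | os.PathLike) -> None:
    """Write a frame as an 8-bit grayscale TIFF or PNG (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, frame.pixels)


def read_frame(
    path: str | os.PathLike,
    gel_pad_deg: float = 0.0,
    frame_index: int = 0,
    specimen_id: str = "",
) -> Frame:
    """Read an 8-bit grayscale TIFF/PNG into a :class:`Frame`."""
    px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse an incidental RGB save of a gray image
        px = px[..., :3].mean(axis=2)
    return Frame(
        pixels=np.clip(np.round(px), 0, 255).astype(np.uint8),
        gel_pad_deg=gel_pad_deg,
        frame_index=frame_index,
        specimen_id=specimen_id,
    )
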