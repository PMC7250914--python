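"""Single-channel 8-bit micrograph container and image I/O.

Frames are stored row-major with 0-based integer pixel coordinates at
pixel centers.  Both acquisition modes of the dual-camera rig are
represented: ``brightfield`` (dark features on a bright background) and
``fluorescent`` (bright nuclei on a dark background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

MODES = ("brightfield", "fluorescent")


@dataclass
class Micrograph:
    """A single-channel 8-bit image frame with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Intensities in [0, 255].
    mode : {'brightfield', 'fluorescent'}
        Acquisition mode.
    pixel_size_um : float
        Physical size of one pixel in microns; must be positive.
    """

    pixels: np.ndarray
    mode: str = "brightfield"
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D frame, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def write_frame(path: str | Path, frame: Micrograph) -> None:
    """Write an 8-bit grayscale frame as TIFF or PNG, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frame.pixels)
    else:
        iio.imwrite(path, frame.pixels)


def read_frame(path: str | Path, mode: str = "brightfield",
               pixel_size_um: float = 0.25) -> Micrograph:
    """Read an 8-bit grayscale TIFF/PNG frame from disk."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse accidental RGB to the first channel
        px = px[..., 0]
    return Micrograph(px.astype(np.uint8), mode=mode, pixel_size_um=pixel_size_um)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Export a boolean mask as a 0/255 PNG for visual inspection."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
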