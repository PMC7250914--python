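"""Background-subtraction segmentation chain for droplet micrographs.

The chain turns an (image, background) pair into two binary masks:

1. ``subtract_background`` — absolute per-pixel difference, removing
   static features (channel walls, debris, illumination).
2. ``droplet_mask`` — low threshold (default 10/255) on the difference,
   speckle removal, hole filling, keep the largest component: the whole
   droplet footprint.
3. ``cell_mask`` — higher threshold (default 12/255) keeps only the
   droplet edge and the cells; a flood fill seeded at the droplet
   centroid paints the interior while stopping at cells; the fill is
   dilated twice (3x3 square) to scrub speckle, inverted, and the
   border-connected component plus sub-minimum particles are removed,
   leaving one component per cell.
4. ``segment_fluorescent`` — adaptive threshold at 25% of the frame
   maximum for bright nuclei on a dark background.

Thresholds keep pixels strictly above T.  Connected components use
8-connectivity except the flood fill, which uses 4-connectivity so it
cannot leak diagonally through the one-pixel-thin droplet edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as _measure
from skimage import morphology as _morph
from skimage import segmentation as _seg

from .micrograph import Micrograph


class SegmentationError(RuntimeError):
    """Base class for per-frame segmentation failures."""


class NoDropletError(SegmentationError):
    """No connected component large enough to be a droplet."""


class FillError(SegmentationError):
    """The interior flood fill could not find a valid seed."""


class NoSignalError(SegmentationError):
    """Fluorescent frame has no intensity above the noise floor."""


@dataclass
class SegmentationConfig:
    droplet_threshold: int = 10
    edge_threshold: int = 12
    min_particle_area: int = 5
    dilation_iterations: int = 2
    min_droplet_area: int = 500
    fill_seed_search_px: int = 5
    fluorescent_noise_floor: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.droplet_threshold < 255):
            raise ValueError("droplet_threshold must lie in (0, 255)")
        if not (0 < self.edge_threshold < 255):
            raise ValueError("edge_threshold must lie in (0, 255)")
        if self.edge_threshold < self.droplet_threshold:
            raise ValueError("edge_threshold must be >= droplet_threshold")
        if self.min_particle_area < 1:
            raise ValueError("min_particle_area must be >= 1")


_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


def subtract_background(image: Micrograph, background: Micrograph) -> np.ndarray:
    """Absolute difference |image - background| as an 8-bit array.

    The absolute value serves both modes with one rule: brightfield
    features are darker than the background, fluorescent features
    brighter.
    """
    if image.shape != background.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {background.shape}")
    diff = np.abs(image.pixels.astype(np.int16) -
                  background.pixels.astype(np.int16))
    return diff.astype(np.uint8)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    # components with area < min_area are dropped (8-connectivity)
    return _morph.remove_small_objects(mask, max_size=min_area - 1,
                                       connectivity=2)


def droplet_mask(diff: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Whole-droplet footprint from the background-subtracted image."""
    cfg = cfg or SegmentationConfig()
    bw = diff > cfg.droplet_threshold
    bw = _remove_small(bw, cfg.min_particle_area)
    bw = ndi.binary_fill_holes(bw)
    labels = _measure.label(bw, connectivity=2)
    if labels.max() == 0:
        raise NoDropletError("no foreground above the droplet threshold")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < cfg.min_droplet_area:
        raise NoDropletError(
            f"largest component ({areas[best - 1]} px) below the "
            f"droplet-area floor ({cfg.min_droplet_area} px)")
    return labels == best


def _find_fill_seed(free: np.ndarray, centroid: tuple[int, int],
                    radius: int) -> tuple[int, int] | None:
    r0, c0 = centroid
    rows, cols = free.shape
    for d in range(radius + 1):
        for dr in range(-d, d + 1):
            for dc in range(-d, d + 1):
                if max(abs(dr), abs(dc)) != d:
                    continue
                r, c = r0 + dr, c0 + dc
                if 0 <= r < rows and 0 <= c < cols and free[r, c]:
                    return r, c
    return None


def _interior_fill(fill_labels: np.ndarray, droplet: np.ndarray,
                   seed: tuple[int, int] | None) -> np.ndarray:
    """Fill region: seed component, else the largest non-border interior one.

    The fallback covers the case where a cell happens to sit exactly on
    the droplet centroid so no nearby seed exists.
    """
    if seed is not None:
        return fill_labels == fill_labels[seed]
    border = np.unique(np.concatenate([
        fill_labels[0, :], fill_labels[-1, :],
        fill_labels[:, 0], fill_labels[:, -1]]))
    interior = np.bincount(fill_labels[droplet].ravel())
    interior[0] = 0
    for lbl in border:
        if lbl < interior.size:
            interior[lbl] = 0
    if interior.max() == 0:
        raise FillError("no fillable interior region found in the droplet")
    return fill_labels == int(np.argmax(interior))


def cell_mask(diff: np.ndarray, droplet: np.ndarray,
              cfg: SegmentationConfig | None = None) -> np.ndarray:
    """One component per cell strictly inside the droplet.

    Cells touching the dark rim merge with the droplet edge during the
    fill and are removed with the border-connected component — the
    boundary (lensing) effect.
    """
    cfg = cfg or SegmentationConfig()
    if not droplet.any():
        raise ValueError("droplet mask is empty")
    edges = diff > cfg.edge_threshold

    rr, cc = np.nonzero(droplet)
    centroid = (int(round(rr.mean())), int(round(cc.mean())))
    seed = _find_fill_seed(~edges, centroid, cfg.fill_seed_search_px)

    # flood the interior over non-edge pixels (4-connectivity)
    fill_labels = _measure.label(~edges, connectivity=1)
    fill = _interior_fill(fill_labels, droplet, seed)
    fill = ndi.binary_dilation(fill, structure=_STRUCT_3X3,
                               iterations=cfg.dilation_iterations)
    inv = ~fill
    inv = _seg.clear_border(inv)
    inv = _remove_small(inv, cfg.min_particle_area)
    # anything the fill could not reach outside the droplet is not a cell
    return inv & droplet


def count_cells(mask: np.ndarray) -> int:
    """Number of 8-connected components in a cell mask."""
    return int(_measure.label(mask, connectivity=2).max())


def segment_fluorescent(image: Micrograph,
                        cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Adaptive threshold T_f = 0.25 * Imax for fluorescent nuclei."""
    cfg = cfg or SegmentationConfig()
    if image.mode != "fluorescent":
        raise ValueError("segment_fluorescent expects a fluorescent frame")
    imax = int(image.pixels.max())
    if imax < cfg.fluorescent_noise_floor:
        raise NoSignalError(
            f"frame maximum {imax} below noise floor "
            f"{cfg.fluorescent_noise_floor}")
    bw = image.pixels > 0.25 * imax
    return _remove_small(bw, cfg.min_particle_area)
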