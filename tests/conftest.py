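import math

import numpy as np
import pytest

from dropsort.fixtures import NO_NOISE, CellSpec, SceneSpec, render_frame
from dropsort import segment


def ring_scene(n_cells: int, radius: float = 100.0, cell_r: float = 8.0,
               frame: int = 256, noise=NO_NOISE, n_boundary: int = 0,
               axis_ratio: float = 1.0) -> SceneSpec:
    """A droplet with ``n_cells`` cells evenly spaced on an interior ring.

    The ring keeps every interior cell well clear of the rim and of its
    neighbours, so on noise-free frames the segmentation chain should
    recover the exact count.
    """
    center = (frame / 2.0, frame / 2.0)
    cells = []
    rho = radius * 0.55
    for i in range(n_cells):
        phi = 2 * math.pi * i / max(n_cells, 1)
        cells.append(CellSpec(
            (center[0] + rho * math.sin(phi), center[1] + rho * math.cos(phi)),
            cell_r, cell_r / axis_ratio, phi))
    for i in range(n_boundary):
        phi = 2 * math.pi * (i + 0.5) / max(n_boundary, 1)
        rho_b = radius - 2.0
        cells.append(CellSpec(
            (center[0] + rho_b * math.sin(phi), center[1] + rho_b * math.cos(phi)),
            cell_r, cell_r, 0.0, at_boundary=True))
    return SceneSpec(frame_shape=(frame, frame), droplet_center=center,
                     droplet_radius=radius, cells=cells, noise=noise)


def segment_scene(scene: SceneSpec, seed: int = 0):
    """Render + full brightfield chain -> (image, droplet mask, cell mask)."""
    img, bg = render_frame(scene, seed=seed)
    diff = segment.subtract_background(img, bg)
    dmask = segment.droplet_mask(diff)
    cmask = segment.cell_mask(diff, dmask)
    return img, dmask, cmask


def rasterize_ellipse(a: float, b: float, theta: float = 0.0,
                      size: int = 64) -> np.ndarray:
    """Boolean mask of a centred rotated ellipse with semi-axes a >= b."""
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    x = (cc - c) * math.cos(theta) + (rr - c) * math.sin(theta)
    y = -(cc - c) * math.sin(theta) + (rr - c) * math.cos(theta)
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def single_cell_scene():
    return ring_scene(1)
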