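"""Synthetic droplet micrographs and event streams with known ground truth.

The generator emulates the imaging physics of a droplet passing the
detection zone of a microfluidic sorter:

* a dark rim at the droplet--oil interface (refractive-index mismatch),
  rendered as an annulus of configurable width and darkness;
* cells as darkened ellipses of variable eccentricity inside the droplet
  (brightfield), or bright Gaussian nuclei on a dark background
  (fluorescent);
* static background features (illumination gradient, debris) present in
  both the frame and its background reference, so that background
  subtraction removes them;
* Gaussian sensor noise followed by salt-and-pepper speckle;
* Poisson-distributed cell counts per droplet with lambda = CC * V.

Cells flagged ``at_boundary`` overlap the dark rim, reproducing the
boundary (lensing) effect in which rim-touching cells merge with the
droplet outline and are lost to the segmentation chain.

All randomness flows from one explicit seed through splittable
``numpy.random.SeedSequence`` children, so a fixed seed reproduces
frames and streams bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw as _draw

from .micrograph import Micrograph, write_frame
from .stats import encapsulation_rate


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """One cell inside a droplet: an ellipse in pixel coordinates.

    ``intensity_offset`` is the unsigned contrast of the cell against the
    droplet interior; it darkens the cell in brightfield and brightens it
    in fluorescent mode.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float = 0.0
    intensity_offset: float = 40.0
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    @property
    def ellipse_ratio(self) -> float:
        return self.semi_major / self.semi_minor


@dataclass
class NoiseSpec:
    """Sensor noise: Gaussian first, then salt-and-pepper speckle."""

    salt_pepper_fraction: float = 0.001
    gaussian_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.salt_pepper_fraction <= 1.0:
            raise ValueError("salt_pepper_fraction must lie in [0, 1]")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be non-negative")


NO_NOISE = NoiseSpec(0.0, 0.0)


@dataclass
class SceneSpec:
    """Ground-truth description of one synthetic frame."""

    frame_shape: tuple[int, int] = (384, 384)
    droplet_center: tuple[float, float] = (192.0, 192.0)
    droplet_radius: float = 160.0
    rim_width: float = 4.0
    rim_darkness: float = 60.0
    interior_offset: float = 5.0
    cells: list[CellSpec] = field(default_factory=list)
    background_level: float = 180.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    mode: str = "brightfield"
    pixel_size_um: float = 0.25
    border_touching: bool = False

    def __post_init__(self) -> None:
        r0, c0 = self.droplet_center
        r = self.droplet_radius
        rows, cols = self.frame_shape
        if not self.border_touching:
            if (r0 - r < 0 or c0 - r < 0 or r0 + r >= rows or c0 + r >= cols):
                raise ValueError("droplet does not fit inside the frame "
                                 "(set border_touching=True to allow)")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if self.mode not in ("brightfield", "fluorescent"):
            raise ValueError("mode must be 'brightfield' or 'fluorescent'")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _paint_ellipse(img: np.ndarray, cell: CellSpec, delta: float) -> None:
    rr, cc = _draw.ellipse(cell.center[0], cell.center[1],
                           cell.semi_minor, cell.semi_major,
                           shape=img.shape, rotation=cell.orientation)
    img[rr, cc] += delta


def _paint_gaussian(img: np.ndarray, cell: CellSpec, amp: float) -> None:
    # anisotropic Gaussian nucleus; sigma = semi-axis / 2 so the visible
    # blob (above the 25% adaptive threshold) roughly matches the ellipse
    a, b = cell.semi_major / 2.0, cell.semi_minor / 2.0
    half = int(math.ceil(3.0 * cell.semi_major)) + 1
    r0, c0 = cell.center
    rlo, rhi = max(int(r0) - half, 0), min(int(r0) + half + 1, img.shape[0])
    clo, chi = max(int(c0) - half, 0), min(int(c0) + half + 1, img.shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    x = (cc - c0) * ct - (rr - r0) * st
    y = (cc - c0) * st + (rr - r0) * ct
    img[rlo:rhi, clo:chi] += amp * np.exp(-0.5 * ((x / a) ** 2 + (y / b) ** 2))


def _static_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.frame_shape
    bg = np.full((rows, cols), float(spec.background_level))
    if spec.mode == "brightfield":
        # gentle illumination gradient plus a few static debris specks
        gr = np.linspace(-3.0, 3.0, rows)[:, None]
        gc = np.linspace(-2.0, 2.0, cols)[None, :]
        bg += gr + gc
        n_debris = rng.integers(3, 7)
        for _ in range(n_debris):
            r = rng.uniform(0, rows)
            c = rng.uniform(0, cols)
            rad = rng.uniform(1.0, 3.0)
            rr, cc = _draw.disk((r, c), rad, shape=bg.shape)
            bg[rr, cc] -= rng.uniform(20, 50)
    return bg


def render_frame(spec: SceneSpec, seed: int,
                 static_seed: int | None = None) -> tuple[Micrograph, Micrograph]:
    """Render a synthetic (image, background) pair for one droplet.

    The background contains only static features; the image adds the
    droplet rim, interior, cells and noise.  Brightfield cells are darker
    than the droplet interior; fluorescent cells are brighter than the
    dark background.  ``static_seed`` fixes the static features
    independently of the noise so a whole stream can share one
    background reference (it defaults to ``seed``).
    """
    rows, cols = spec.frame_shape
    if 2 * spec.droplet_radius >= min(rows, cols):
        raise ValueError("frame too small to contain the droplet")
    if static_seed is None:
        static_seed = seed
    rng_static = np.random.default_rng(
        np.random.SeedSequence([int(static_seed), 0]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    bg = _static_background(spec, rng_static)
    img = bg.copy()

    if spec.mode == "brightfield":
        # interior disk (slightly brighter from lensing), then dark rim
        rr, cc = _draw.disk(spec.droplet_center,
                            spec.droplet_radius - spec.rim_width,
                            shape=img.shape)
        img[rr, cc] += spec.interior_offset
        rr, cc = _draw.disk(spec.droplet_center, spec.droplet_radius,
                            shape=img.shape)
        rim = np.zeros(img.shape, dtype=bool)
        rim[rr, cc] = True
        rr, cc = _draw.disk(spec.droplet_center,
                            spec.droplet_radius - spec.rim_width,
                            shape=img.shape)
        rim[rr, cc] = False
        img[rim] -= spec.rim_darkness
        for cell in spec.cells:
            _paint_ellipse(img, cell, -float(cell.intensity_offset))
    else:
        for cell in spec.cells:
            _paint_gaussian(img, cell, float(cell.intensity_offset))

    if spec.noise.gaussian_sigma > 0:
        img += rng_noise.normal(0.0, spec.noise.gaussian_sigma, img.shape)
    if spec.noise.salt_pepper_fraction > 0:
        n_sp = int(round(spec.noise.salt_pepper_fraction * img.size))
        idx = rng_noise.choice(img.size, size=n_sp, replace=False)
        vals = rng_noise.choice([0.0, 255.0], size=n_sp)
        img.flat[idx] = vals

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    bg8 = np.clip(np.rint(bg), 0, 255).astype(np.uint8)
    return (Micrograph(img8, mode=spec.mode, pixel_size_um=spec.pixel_size_um),
            Micrograph(bg8, mode=spec.mode, pixel_size_um=spec.pixel_size_um))


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

@dataclass
class StreamSpec:
    """A droplet train: Poisson cell loading at lambda = CC * V."""

    n_droplets: int
    cell_concentration: float          # cells/mL
    mean_volume_pl: float = 155.0
    volume_cv: float = 0.05
    droplet_rate_hz: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be non-negative")
        if self.cell_concentration < 0:
            raise ValueError("cell concentration must be non-negative")
        if self.mean_volume_pl <= 0:
            raise ValueError("mean droplet volume must be positive")
        if self.volume_cv < 0:
            raise ValueError("volume CV must be non-negative")
        if self.droplet_rate_hz <= 0:
            raise ValueError("droplet rate must be positive")


@dataclass
class DropletTruth:
    """Ground truth for one simulated droplet."""

    droplet_id: int
    cell_count: int
    volume_pl: float
    timestamp_s: float
    lam: float


def simulate_stream(spec: StreamSpec) -> list[DropletTruth]:
    """Draw a droplet train with Poisson(lambda_i) cell counts.

    Per-droplet volumes are normal around the mean with the stated CV
    (truncated at 20% of the mean), and lambda_i = CC * V_i, so volume
    variability carries into loading variability.
    """
    ss = np.random.SeedSequence([int(spec.seed)])
    rng_vol, rng_cnt = (np.random.default_rng(s) for s in ss.spawn(2))
    vols = rng_vol.normal(spec.mean_volume_pl,
                          spec.volume_cv * spec.mean_volume_pl,
                          size=spec.n_droplets)
    vols = np.clip(vols, 0.2 * spec.mean_volume_pl, None)
    lams = np.array([encapsulation_rate(spec.cell_concentration, v)
                     for v in vols])
    counts = rng_cnt.poisson(lams)
    dt = 1.0 / spec.droplet_rate_hz
    return [DropletTruth(i, int(counts[i]), float(vols[i]), i * dt,
                         float(lams[i]))
            for i in range(spec.n_droplets)]


# ---------------------------------------------------------------------------
# Stream -> scene geometry
# ---------------------------------------------------------------------------

@dataclass
class FrameGeometry:
    """How a droplet of known volume maps to pixels in a rendered frame.

    Defaults follow the rig the generator emulates: 0.25 um pixels, a
    30 um channel (cylindrical droplets), ~7.5 um cells, a 4 px dark rim.
    """

    frame_shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.25
    channel_height_um: float = 30.0
    rim_width_px: float = 4.0
    rim_darkness: float = 60.0
    interior_offset: float = 5.0
    background_level: float = 180.0
    cell_semi_major_um: float = 3.75
    cell_axis_ratio_range: tuple[float, float] = (1.0, 3.0)
    cell_contrast: float = 40.0
    min_cell_gap_px: float = 4.0
    rim_margin_px: float = 4.0


def radius_px_from_volume(volume_pl: float, geom: FrameGeometry) -> float:
    """Cylinder model: V = pi r^2 h, so r = sqrt(V / (pi h)) (1 pL = 1e3 um^3)."""
    if volume_pl <= 0:
        raise ValueError("volume must be positive")
    r_um = math.sqrt(volume_pl * 1e3 / (math.pi * geom.channel_height_um))
    return r_um / geom.pixel_size_um


def scene_for_droplet(truth: DropletTruth, geom: FrameGeometry | None = None,
                      stream_seed: int = 0, mode: str = "brightfield",
                      noise: NoiseSpec | None = None,
                      n_boundary_cells: int = 0) -> SceneSpec:
    """Build the SceneSpec realising one droplet of a simulated stream.

    Interior cells are placed by rejection sampling with a pairwise
    clearance (``min_cell_gap_px``) and kept clear of the rim, so on
    noise-free frames the segmentation chain can recover the exact count.
    ``n_boundary_cells`` adds extra cells overlapping the rim (lost to
    the boundary effect; they are *not* part of ``truth.cell_count``).
    """
    geom = geom or FrameGeometry()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(stream_seed), 1 + truth.droplet_id]))
    radius = radius_px_from_volume(truth.volume_pl, geom)
    rows, cols = geom.frame_shape
    center = (rows / 2.0, cols / 2.0)
    if 2 * (radius + 2) >= min(rows, cols):
        raise ValueError("droplet too large for the configured frame")

    a_px = geom.cell_semi_major_um / geom.pixel_size_um
    placed: list[CellSpec] = []
    r_inner = radius - geom.rim_width_px - a_px - geom.rim_margin_px
    if truth.cell_count > 0 and r_inner <= a_px:
        raise ValueError("droplet too small to host interior cells")
    for _ in range(truth.cell_count):
        ratio = rng.uniform(*geom.cell_axis_ratio_range)
        cell = None
        for _try in range(500):
            rho = r_inner * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            ctr = (center[0] + rho * math.sin(phi),
                   center[1] + rho * math.cos(phi))
            ok = all(math.hypot(ctr[0] - p.center[0], ctr[1] - p.center[1])
                     >= a_px + p.semi_major + geom.min_cell_gap_px
                     for p in placed)
            if ok:
                cell = CellSpec(ctr, a_px, a_px / ratio,
                                rng.uniform(0, 2 * math.pi),
                                geom.cell_contrast)
                break
        if cell is None:
            raise RuntimeError(
                f"could not place {truth.cell_count} non-overlapping cells "
                f"in droplet {truth.droplet_id}")
        placed.append(cell)
    for _ in range(n_boundary_cells):
        phi = rng.uniform(0, 2 * math.pi)
        rho = radius - geom.rim_width_px / 2.0
        ctr = (center[0] + rho * math.sin(phi), center[1] + rho * math.cos(phi))
        placed.append(CellSpec(ctr, a_px, a_px, 0.0, geom.cell_contrast,
                               at_boundary=True))

    return SceneSpec(frame_shape=geom.frame_shape, droplet_center=center,
                     droplet_radius=radius, rim_width=geom.rim_width_px,
                     rim_darkness=geom.rim_darkness,
                     interior_offset=geom.interior_offset, cells=placed,
                     background_level=geom.background_level,
                     noise=noise if noise is not None else NoiseSpec(),
                     mode=mode, pixel_size_um=geom.pixel_size_um)


# ---------------------------------------------------------------------------
# Auxiliary generators
# ---------------------------------------------------------------------------

def backscatter_trace(droplet_rate_hz: float, duration_s: float,
                      sample_rate_hz: float = 1000.0, baseline: float = 1.0,
                      bump: float = 0.5, bump_width_s: float = 0.05,
                      noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Photodiode-style 1-D trace: square bumps at each droplet transit."""
    if droplet_rate_hz <= 0 or duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("rates and duration must be positive")
    n = int(round(duration_s * sample_rate_hz))
    trace = np.full(n, baseline)
    width = max(int(round(bump_width_s * sample_rate_hz)), 1)
    period = sample_rate_hz / droplet_rate_hz
    t = period / 2.0
    while int(t) + width < n:
        trace[int(t):int(t) + width] += bump
        t += period
    if noise_sigma > 0:
        trace += np.random.default_rng(seed).normal(0, noise_sigma, n)
    return trace


def sample_feature_clouds(n_single: int, n_cluster: int, seed: int = 0,
                          single_area=(60.0, 10.0), single_circ=(1.1, 0.05),
                          cluster_area=(180.0, 30.0), cluster_circ=(1.6, 0.15)):
    """Synthetic (circularity, area) clouds for classifier workflows.

    Emulates fluorescent imaging cytometry of single nuclei versus cell
    clusters: clusters are larger and less circular.  Returns
    ``(X, y)`` with X columns (heywood_circularity, area_um2) and string
    labels 'single'/'cluster'.
    """
    rng = np.random.default_rng(seed)
    a_s = rng.normal(*single_area, size=n_single)
    c_s = rng.normal(*single_circ, size=n_single)
    a_c = rng.normal(*cluster_area, size=n_cluster)
    c_c = rng.normal(*cluster_circ, size=n_cluster)
    area = np.clip(np.concatenate([a_s, a_c]), 1.0, None)
    circ = np.clip(np.concatenate([c_s, c_c]), 1.0, None)
    X = np.column_stack([circ, area])
    y = np.array(["single"] * n_single + ["cluster"] * n_cluster)
    return X, y


# ---------------------------------------------------------------------------
# Manifest / frame I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["droplet_id", "true_cell_count", "true_volume_pL",
                    "timestamp_s"]


def write_manifest(truths: list[DropletTruth], path: str | Path) -> None:
    """Write the stream ground truth as a manifest CSV."""
    df = pd.DataFrame({
        "droplet_id": [t.droplet_id for t in truths],
        "true_cell_count": [t.cell_count for t in truths],
        "true_volume_pL": [t.volume_pl for t in truths],
        "timestamp_s": [t.timestamp_s for t in truths],
    })
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[DropletTruth]:
    df = pd.read_csv(path)
    return [DropletTruth(int(r.droplet_id), int(r.true_cell_count),
                         float(r.true_volume_pL), float(r.timestamp_s),
                         float("nan"))
            for r in df.itertuples()]


def write_stream_frames(truths: list[DropletTruth], out_dir: str | Path,
                        geom: FrameGeometry | None = None, stream_seed: int = 0,
                        noise: NoiseSpec | None = None, fmt: str = "png") -> None:
    """Render every droplet of a stream to disk with a shared background."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = geom or FrameGeometry()
    for i, t in enumerate(truths):
        scene = scene_for_droplet(t, geom, stream_seed=stream_seed, noise=noise)
        img, bg = render_frame(scene, seed=stream_seed + 1 + t.droplet_id,
                               static_seed=stream_seed)
        write_frame(out / f"droplet_{t.droplet_id:06d}.{fmt}", img)
        if i == 0:
            write_frame(out / f"background.{fmt}", bg)
    write_manifest(truths, out / "manifest.csv")
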