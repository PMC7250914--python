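"""Particle descriptors vs closed forms and brute-force pixel oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropsort.features import (droplet_volume, feret_diameters,
                               heywood_circularity, measure_droplet,
                               measure_particles, waddel_disk_diameter)
from dropsort.micrograph import Micrograph

from conftest import rasterize_ellipse, ring_scene, segment_scene

_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])


# ---------------------------------------------------------------------------
# Independent oracles: explicit pixel loops, no shared code with features.py
# ---------------------------------------------------------------------------

def oracle_axis_ratio(mask):
    ys, xs = np.nonzero(mask)
    n = len(ys)
    my, mx = ys.mean(), xs.mean()
    m20 = ((ys - my) ** 2).sum() / n
    m02 = ((xs - mx) ** 2).sum() / n
    m11 = ((ys - my) * (xs - mx)).sum() / n
    tr, det = m20 + m02, m20 * m02 - m11 ** 2
    disc = math.sqrt(max(tr ** 2 / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    if l2 <= 1e-12:
        return math.inf
    return math.sqrt(l1 / l2)


def oracle_feret_max(mask):
    pts = []
    for r, c in np.argwhere(mask):
        for dr, dc in _CORNERS:
            pts.append((r + dr, c + dc))
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            best = max(best, d)
    return best


def random_blob(rng, size=30):
    from scipy import ndimage as ndi

    while True:
        noise = rng.random((size, size))
        smooth = ndi.gaussian_filter(noise, 2.0)
        mask = smooth > np.quantile(smooth, 0.85)
        labels, n = ndi.label(mask)
        if n:
            areas = np.bincount(labels.ravel())[1:]
            return labels == (int(np.argmax(areas)) + 1)


# ---------------------------------------------------------------------------
# Closed-form examples
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_heywood_of_continuous_circle_is_one(self):
        r = 17.3
        assert heywood_circularity(2 * math.pi * r, math.pi * r * r) == \
            pytest.approx(1.0, abs=1e-12)

    def test_waddel_is_equal_area_disk_diameter(self):
        area = 321.0
        assert waddel_disk_diameter(area) == \
            pytest.approx(2 * math.sqrt(area / math.pi), abs=1e-12)

    def test_rectangle_ellipse_ratio_and_feret(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 10:50] = True  # 10 x 40 rectangle
        feats = measure_particles(mask, np.zeros((60, 60), np.uint8), 1.0)
        assert len(feats) == 1
        assert feats[0].ellipse_ratio == pytest.approx(oracle_axis_ratio(mask),
                                                       rel=1e-9)
        # discrete second moments give ratio ~4.02 for a 10x40 rectangle
        assert feats[0].ellipse_ratio == pytest.approx(4.0, rel=0.01)
        assert feats[0].max_feret_um == \
            pytest.approx(math.hypot(10, 40), abs=0.5)

    def test_rasterized_disk_heywood_near_one(self):
        mask = rasterize_ellipse(12, 12)
        feats = measure_particles(mask, np.zeros(mask.shape, np.uint8), 1.0)
        assert feats[0].heywood_circularity == pytest.approx(1.0, abs=0.05)

    def test_empty_mask_gives_empty_list(self):
        assert measure_particles(np.zeros((8, 8), bool),
                                 np.zeros((8, 8), np.uint8), 1.0) == []

    def test_intensity_stats_come_from_the_image(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        img = np.zeros((8, 8), np.uint8)
        img[2:4, 2:4] = [[10, 20], [30, 40]]
        f = measure_particles(mask, img, 1.0)[0]
        assert f.mean_intensity == pytest.approx(25.0)
        assert f.intensity_variance == pytest.approx(np.var([10, 20, 30, 40]))


class TestBruteForceOracle:
    def test_random_masks_match_pixel_loops(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            mask = random_blob(rng)
            feats = measure_particles(mask, np.zeros(mask.shape, np.uint8), 1.0)
            assert len(feats) == 1
            f = feats[0]
            assert f.area_px == int(mask.sum())
            assert f.waddel_disk_diameter_um == \
                pytest.approx(2 * math.sqrt(mask.sum() / math.pi), rel=1e-12)
            ratio = oracle_axis_ratio(mask)
            if math.isfinite(ratio):
                assert f.ellipse_ratio == pytest.approx(ratio, rel=1e-9)
            assert f.max_feret_um == pytest.approx(oracle_feret_max(mask),
                                                   rel=1e-9)
            checked += 1
        assert checked == 200

    def test_feret_min_max_of_rectangle(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:35] = True
        coords = np.argwhere(mask)
        fmax, fmin = feret_diameters(coords)
        assert fmax == pytest.approx(math.hypot(10, 30), rel=1e-12)
        assert fmin == pytest.approx(10.0, rel=1e-12)


class TestShapeProperties:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(ratio=st.floats(min_value=1.0, max_value=8.0))
    def test_ellipse_ratio_tracks_generating_ratio(self, ratio):
        b = 5.0
        mask = rasterize_ellipse(b * ratio, b, size=100)
        f = measure_particles(mask, np.zeros(mask.shape, np.uint8), 1.0)[0]
        assert f.ellipse_ratio == pytest.approx(ratio, rel=0.12)

    def test_heywood_increases_with_elongation_at_fixed_area(self):
        area = 600.0
        vals = []
        for ratio in [1, 2, 3, 4, 5, 6, 7, 8]:
            b = math.sqrt(area / (math.pi * ratio))
            mask = rasterize_ellipse(b * ratio, b, size=120)
            f = measure_particles(mask, np.zeros(mask.shape, np.uint8), 1.0)[0]
            assert f.heywood_circularity >= 1.0 - 0.05
            vals.append(f.heywood_circularity)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("theta_deg", [0, 20, 45, 70, 90, 135, 160])
    def test_ellipse_ratio_rotation_invariant(self, theta_deg):
        mask = rasterize_ellipse(14, 7, math.radians(theta_deg), size=64)
        f = measure_particles(mask, np.zeros(mask.shape, np.uint8), 1.0)[0]
        assert f.ellipse_ratio == pytest.approx(2.0, rel=0.05)


class TestDropletVolume:
    def test_experimental_scale_droplet(self):
        # pi * 40.5^2 * 30 um^3 ~ 154.6 pL, the experimental droplet scale
        area = math.pi * 40.5 ** 2
        assert droplet_volume(area, 30.0) == pytest.approx(154.55, abs=0.1)

    def test_unit_identity(self):
        # 10^3 um^3 is one picolitre
        assert droplet_volume(100.0, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            droplet_volume(0.0, 30.0)
        with pytest.raises(ValueError):
            droplet_volume(100.0, -1.0)


class TestDropletRecord:
    def test_record_assembled_from_masks(self):
        scene = ring_scene(2)
        img, dmask, cmask = segment_scene(scene)
        rec = measure_droplet(dmask, cmask, img, droplet_id=7,
                              timestamp_s=1.5, channel_height_um=30.0)
        assert rec.droplet_id == 7
        assert rec.cell_count == 2 == len(rec.cells)
        # radius 100 px * 0.25 um/px = 25 um -> V = pi*25^2*30/1000 pL
        assert rec.volume_pL == pytest.approx(math.pi * 25 ** 2 * 30 / 1e3,
                                              rel=0.06)
        assert rec.droplet_length_um == pytest.approx(50.0, rel=0.05)
        assert rec.droplet_width_um == pytest.approx(50.0, rel=0.05)
        assert rec.droplet_circularity == pytest.approx(1.0, abs=0.07)
        assert rec.hole_area_um2 == pytest.approx(
            sum(c.area_um2 for c in rec.cells), rel=1e-12)
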