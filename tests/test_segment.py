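"""Segmentation chain: subtraction, droplet mask, cell mask, fluorescence."""

import numpy as np
import pytest

from dropsort import segment
from dropsort.fixtures import NO_NOISE, CellSpec, SceneSpec, render_frame
from dropsort.micrograph import Micrograph
from dropsort.segment import (FillError, NoDropletError, NoSignalError,
                              SegmentationConfig)

from conftest import ring_scene, segment_scene


def _u8(a):
    return Micrograph(np.asarray(a, dtype=np.uint8))


class TestSubtractBackground:
    def test_identical_frames_give_zero(self):
        img = _u8(np.full((10, 10), 120))
        assert segment.subtract_background(img, img).max() == 0

    def test_single_dark_pixel(self):
        bg = np.full((8, 8), 100, np.uint8)
        im = bg.copy()
        im[3, 4] = 40
        diff = segment.subtract_background(_u8(im), _u8(bg))
        assert diff[3, 4] == 60
        assert diff.sum() == 60

    def test_absolute_value_serves_both_contrasts(self):
        bg = np.full((8, 8), 100, np.uint8)
        brighter = bg.copy()
        brighter[2, 2] = 180
        assert segment.subtract_background(_u8(brighter), _u8(bg))[2, 2] == 80

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            segment.subtract_background(_u8(np.zeros((4, 4))),
                                        _u8(np.zeros((5, 5))))


class TestDropletMask:
    def test_disk_area_within_five_percent(self):
        scene = ring_scene(0)
        img, bg = render_frame(scene, 1)
        diff = segment.subtract_background(img, bg)
        mask = segment.droplet_mask(diff)
        assert mask.sum() == pytest.approx(np.pi * 100 ** 2, rel=0.05)

    def test_all_zero_diff_signals_no_droplet(self):
        with pytest.raises(NoDropletError):
            segment.droplet_mask(np.zeros((64, 64), np.uint8))

    def test_sub_floor_component_signals_no_droplet(self):
        diff = np.zeros((64, 64), np.uint8)
        diff[10:20, 10:20] = 50  # 100 px, below the 500 px droplet floor
        with pytest.raises(NoDropletError):
            segment.droplet_mask(diff)

    def test_speckle_invariance(self):
        # adding isolated bright pixels must not change the droplet mask
        scene = ring_scene(0)
        img, bg = render_frame(scene, 2)
        diff = segment.subtract_background(img, bg)
        clean = segment.droplet_mask(diff)
        noisy = diff.copy()
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 256, size=(20, 2))
        for r, c in pts:
            noisy[r, c] = 200
        assert np.array_equal(segment.droplet_mask(noisy), clean)

    def test_deterministic(self):
        scene = ring_scene(2)
        img, bg = render_frame(scene, 3)
        diff = segment.subtract_background(img, bg)
        assert np.array_equal(segment.droplet_mask(diff),
                              segment.droplet_mask(diff))


class TestCellMask:
    def test_empty_droplet_gives_empty_mask(self):
        _, _, cmask = segment_scene(ring_scene(0))
        assert segment.count_cells(cmask) == 0

    def test_single_cell_one_component_area_eroded_by_dilation(self):
        # the double 3x3 dilation of the fill erodes ~2 px of cell radius
        scene = SceneSpec(frame_shape=(256, 256), droplet_center=(128, 128),
                          droplet_radius=100, noise=NO_NOISE,
                          cells=[CellSpec((128, 128), 8, 8)])
        img, dmask, cmask = segment_scene(scene)
        assert segment.count_cells(cmask) == 1
        iters = SegmentationConfig().dilation_iterations
        lo = np.pi * (8 - 2 * iters - 1) ** 2
        hi = np.pi * 8 ** 2
        assert lo <= cmask.sum() <= hi

    @pytest.mark.parametrize("n_cells", [1, 2, 3, 4, 5])
    def test_exact_count_recovery(self, n_cells):
        _, _, cmask = segment_scene(ring_scene(n_cells))
        assert segment.count_cells(cmask) == n_cells

    def test_rim_touching_cell_is_lost(self):
        _, _, cmask = segment_scene(ring_scene(2, n_boundary=1))
        assert segment.count_cells(cmask) == 2

    def test_components_strictly_inside_droplet(self):
        _, dmask, cmask = segment_scene(ring_scene(3))
        assert np.all(dmask[cmask])

    def test_cell_on_centroid_still_fills(self):
        # a cell sitting exactly on the droplet centroid blocks the seed;
        # the fill must still find the interior
        scene = SceneSpec(frame_shape=(256, 256), droplet_center=(128, 128),
                          droplet_radius=100, noise=NO_NOISE,
                          cells=[CellSpec((128, 128), 12, 12)])
        _, _, cmask = segment_scene(scene)
        assert segment.count_cells(cmask) == 1

    def test_empty_droplet_mask_rejected(self):
        with pytest.raises(ValueError):
            segment.cell_mask(np.zeros((32, 32), np.uint8),
                              np.zeros((32, 32), bool))

    def test_unfillable_interior_signals_fill_failure(self):
        # droplet mask present but every interior pixel above edge threshold
        diff = np.full((64, 64), 60, np.uint8)
        droplet = np.zeros((64, 64), bool)
        droplet[16:48, 16:48] = True
        with pytest.raises(FillError):
            segment.cell_mask(diff, droplet)


class TestFluorescent:
    def _nucleus_frame(self, peaks):
        scene = SceneSpec(frame_shape=(128, 128), droplet_center=(64, 64),
                          droplet_radius=50, background_level=5,
                          mode="fluorescent", noise=NO_NOISE,
                          cells=[CellSpec(p, 8, 8, intensity_offset=175)
                                 for p in peaks])
        img, _ = render_frame(scene, 4)
        return img

    def test_threshold_is_quarter_of_max(self):
        img = self._nucleus_frame([(64, 64)])
        mask = segment.segment_fluorescent(img)
        imax = img.pixels.max()
        assert np.all(img.pixels[mask] > 0.25 * imax)
        # pixels just below the threshold stay out
        assert not np.any(mask & (img.pixels <= 0.25 * imax))

    def test_two_nuclei_two_components(self):
        img = self._nucleus_frame([(45, 45), (85, 85)])
        assert segment.count_cells(segment.segment_fluorescent(img)) == 2

    def test_dim_frame_signals_no_signal(self):
        img = Micrograph(np.full((32, 32), 10, np.uint8), mode="fluorescent")
        with pytest.raises(NoSignalError):
            segment.segment_fluorescent(img)

    def test_brightfield_frame_rejected(self):
        img = Micrograph(np.full((32, 32), 200, np.uint8))
        with pytest.raises(ValueError):
            segment.segment_fluorescent(img)


class TestConfig:
    def test_edge_threshold_must_dominate(self):
        with pytest.raises(ValueError):
            SegmentationConfig(droplet_threshold=20, edge_threshold=10)

    def test_thresholds_bounded(self):
        with pytest.raises(ValueError):
            SegmentationConfig(droplet_threshold=0)
        with pytest.raises(ValueError):
            SegmentationConfig(edge_threshold=255)
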