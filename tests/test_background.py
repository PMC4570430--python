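"""Mean shift depth clustering and vegetation filtering."""
import numpy as np
import pytest

import leafseg3d as L
from leafseg3d.background import mean_shift_depth, normalize_depth
from leafseg3d.errors import EmptyInputError
from oracles import (group_modes_bruteforce, mean_shift_modes_bruteforce,
                     partitions_equal, plateau_image)
from conftest import iou


def _frame(depth, color_value=(40, 160, 50)):
    color = np.zeros(depth.shape + (3,), np.uint8)
    color[:] = color_value
    return L.RGBDFrame(color=color, depth=depth.astype(np.uint16),
                       frame_id="t")


class TestMeanShift:
    def test_constant_depth_single_segment(self):
        frame = _frame(np.full((16, 16), 1000))
        lm = mean_shift_depth(frame, L.MeanShiftParams())
        assert lm.n_segments == 1
        assert np.all(lm.labels == 1)

    def test_step_edge_two_segments(self):
        depth = np.full((16, 16), 800)
        depth[:, 8:] = 1600
        lm = mean_shift_depth(_frame(depth), L.MeanShiftParams(sr=6))
        assert lm.n_segments == 2
        assert len(np.unique(lm.labels[:, :8])) == 1
        assert len(np.unique(lm.labels[:, 8:])) == 1
        assert lm.labels[0, 0] != lm.labels[0, 15]

    def test_invalid_pixels_stay_unlabeled(self):
        depth = np.full((12, 12), 900)
        depth[4:6, 4:6] = 0
        lm = mean_shift_depth(_frame(depth), L.MeanShiftParams(min_region_px=0))
        assert np.all(lm.labels[4:6, 4:6] == 0)
        assert np.all(lm.labels[depth > 0] > 0)

    def test_all_invalid_raises(self):
        with pytest.raises(EmptyInputError):
            mean_shift_depth(_frame(np.zeros((8, 8))), L.MeanShiftParams())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_plateaus(self, seed):
        """Partition equality with literal per-pixel mode seeking."""
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(12, 25)), int(rng.integers(12, 25))
        depths = [500, 900, 1300][:int(rng.integers(2, 4))]
        img = plateau_image(rng, h, w, depths, 2.0)
        frame = _frame(img)
        params = L.MeanShiftParams(sp=12, sr=6, min_region_px=0, eps=1e-3)
        lm = mean_shift_depth(frame, params)
        norm = normalize_depth(img, frame.valid_mask, "scale_8bit")
        modes = mean_shift_modes_bruteforce(norm, frame.valid_mask,
                                            12, 6.0, 50, 1e-3)
        ref = group_modes_bruteforce(modes, frame.valid_mask, 6.0)
        assert partitions_equal(lm.labels, ref)

    def test_depth_coherence_within_segments(self, scene4):
        """Mode grouping keeps each segment within a 2*sr depth band.

        min_region_px is disabled here: speckle absorption deliberately
        folds tiny noise islands into their spatial neighbours, which may
        sit outside the band.
        """
        frame, _ = scene4
        params = L.MeanShiftParams(min_region_px=0)
        lm, trace = mean_shift_depth(frame, params, return_trace=True)
        for sid in lm.segment_ids():
            vals = trace.modes[lm.labels == sid]
            assert vals.max() - vals.min() <= 2 * params.sr + 1e-9

    def test_convergence_fraction_small(self, scene4):
        frame, _ = scene4
        _, trace = mean_shift_depth(frame, L.MeanShiftParams(),
                                    return_trace=True)
        assert trace.max_iter_fraction < 0.05
        assert trace.iterations.max() <= L.MeanShiftParams().max_iter

    def test_small_regions_absorbed(self):
        depth = np.full((20, 20), 1000)
        depth[9:11, 9:11] = 1060  # 4-px speckle well past sr
        lm = mean_shift_depth(_frame(depth), L.MeanShiftParams(sr=6,
                                                               min_region_px=50))
        assert lm.n_segments == 1


class TestVegetationFilter:
    def _two_segment_frame(self, c1, c2):
        depth = np.full((16, 16), 800)
        depth[:, 8:] = 1600
        color = np.zeros((16, 16, 3), np.uint8)
        color[:, :8] = c1
        color[:, 8:] = c2
        frame = L.RGBDFrame(color=color, depth=depth.astype(np.uint16),
                            frame_id="t")
        labels = mean_shift_depth(frame, L.MeanShiftParams())
        return frame, labels

    def test_green_kept_brown_removed(self):
        frame, labels = self._two_segment_frame((40, 160, 50), (120, 80, 40))
        veg = L.VegetationParams(g_min=100, g_margin=20)
        out = L.vegetation_filter(labels, frame, veg)
        assert out.n_segments == 1
        assert np.all(out.labels[:, :8] == 1)
        assert np.all(out.labels[:, 8:] == 0)

    def test_gray_scene_has_no_foreground(self):
        frame, labels = self._two_segment_frame((100, 100, 100),
                                                (100, 100, 100))
        out = L.vegetation_filter(labels, frame, L.VegetationParams())
        assert out.n_segments == 0
        assert not np.any(out.labels)

    def test_excess_green_mode(self):
        frame, labels = self._two_segment_frame((40, 160, 50), (120, 80, 40))
        veg = L.VegetationParams(mode="excess_green", exg_min=40)
        out = L.vegetation_filter(labels, frame, veg)
        assert out.n_segments == 1

    def test_foreground_matches_ground_truth_union(self, scene4,
                                                   default_config):
        frame, gt = scene4
        _, fg = L.remove_background(frame, default_config.mean_shift,
                                    default_config.vegetation)
        union = np.zeros(frame.shape, bool)
        for m in gt.instance_masks:
            union |= m
        assert iou(fg.labels > 0, union) >= 0.95


class TestRemoveBackground:
    def test_all_background_scene_zeroed(self):
        depth = np.full((16, 16), 1500)
        frame = _frame(depth, color_value=(110, 95, 70))
        out, fg = L.remove_background(frame, L.MeanShiftParams(),
                                      L.VegetationParams())
        assert fg.n_segments == 0
        assert not np.any(out.depth)
        assert not np.any(out.color)

    def test_single_clean_leaf_recovered_exactly(self, single_clean_scene,
                                                 default_config):
        frame, gt = single_clean_scene
        _, fg = L.remove_background(frame, default_config.mean_shift,
                                    default_config.vegetation)
        assert np.array_equal(fg.labels > 0, gt.instance_masks[0])

    def test_idempotent_on_own_output(self, single_clean_scene,
                                      default_config):
        frame, _ = single_clean_scene
        out1, fg1 = L.remove_background(frame, default_config.mean_shift,
                                        default_config.vegetation)
        out2, fg2 = L.remove_background(out1, default_config.mean_shift,
                                        default_config.vegetation)
        assert np.array_equal(fg1.labels > 0, fg2.labels > 0)

    def test_foreground_recall_under_noise(self):
        """Leaf pixels survive background removal under 5 mm depth noise."""
        params = L.SceneParams(height=240, width=320, n_leaves=3,
                               depth_noise_sd_mm=5.0, seed=11)
        frame, gt = L.generate_scene(params)
        cfg = L.PipelineConfig()
        _, fg = L.remove_background(frame, cfg.mean_shift, cfg.vegetation)
        union = np.zeros(frame.shape, bool)
        for m in gt.instance_masks:
            union |= m
        recall = np.count_nonzero((fg.labels > 0) & union) / union.sum()
        assert recall >= 0.95
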