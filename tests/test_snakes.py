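"""Snake evolution, instance rasterization and the composed pipeline."""
import numpy as np
import pytest

import leafseg3d as L
from leafseg3d.snakes import _internal_inverse
from conftest import iou

SMALL = dict(height=240, width=320)


def _internal_energy(verts, alpha, beta):
    d1 = np.roll(verts, -1, axis=0) - verts
    d2 = np.roll(verts, -1, axis=0) - 2 * verts + np.roll(verts, 1, axis=0)
    return (alpha * np.sum(d1 ** 2) + beta * np.sum(d2 ** 2))


class TestEvolveSnake:
    def test_zero_field_contour_shrinks(self):
        """Pure elasticity contracts the contour monotonically."""
        field = L.VectorField(u=np.zeros((64, 64)), v=np.zeros((64, 64)))
        areas = []
        for n_iter in (1, 5, 10, 20):
            params = L.SnakeParams(n_iter=n_iter, balloon=0.0,
                                   converge_eps=1e-9)
            out = L.evolve_snake(L.circle_contour((32, 32), 20, 48),
                                 field, params)
            areas.append(abs(out.area()))
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_zero_field_internal_energy_nonincreasing(self):
        """The implicit internal step is a descent on bending energy."""
        field = L.VectorField(u=np.zeros((64, 64)), v=np.zeros((64, 64)))
        params = L.SnakeParams(balloon=0.0)
        verts = L.circle_contour((32, 32), 15, 40).vertices
        inv = _internal_inverse(len(verts), params)
        energies = [_internal_energy(verts, params.alpha, params.beta)]
        for _ in range(30):
            verts = inv @ (params.gamma * verts)
            energies.append(_internal_energy(verts, params.alpha,
                                             params.beta))
        assert np.all(np.diff(energies) <= 1e-9)

    def test_circle_rim_recovery(self, circle_field):
        """A radius-5 seed inflates to the radius-20 edge ring."""
        _, field = circle_field
        out = L.evolve_snake(L.circle_contour((32, 32), 5, 40), field,
                             L.SnakeParams())
        radii = np.hypot(out.vertices[:, 0] - 32, out.vertices[:, 1] - 32)
        assert abs(radii.mean() - 20.0) <= 1.0

    def test_equilibrium_is_a_fixed_point(self, circle_field):
        _, field = circle_field
        params = L.SnakeParams()
        first = L.evolve_snake(L.circle_contour((32, 32), 5, 40), field,
                               params)
        r_star = np.hypot(first.vertices[:, 0] - 32,
                          first.vertices[:, 1] - 32).mean()
        again = L.evolve_snake(L.circle_contour((32, 32), r_star, 63),
                               field, params)
        radii = np.hypot(again.vertices[:, 0] - 32,
                         again.vertices[:, 1] - 32)
        assert np.abs(radii - r_star).mean() <= 0.5


class TestContoursToSegments:
    def test_disjoint_contours_keep_their_interiors(self):
        fg = np.ones((40, 60), bool)
        c1 = L.circle_contour((15, 20), 8, 32)
        c2 = L.circle_contour((45, 20), 8, 32)
        cods = L.CoDSet(points=[(15, 20), (45, 20)])
        segs = L.contours_to_segments([c1, c2], fg, cods)
        assert len(segs) == 2
        assert np.array_equal(segs[0].mask, c1.to_mask((40, 60)))
        assert np.array_equal(segs[1].mask, c2.to_mask((40, 60)))
        assert segs[0].area_px == segs[0].mask.sum()

    def test_overlap_goes_to_nearest_seed_with_index_tiebreak(self):
        fg = np.ones((40, 60), bool)
        c1 = L.circle_contour((25, 20), 10, 40)
        c2 = L.circle_contour((35, 20), 10, 40)
        cods = L.CoDSet(points=[(25, 20), (35, 20)])
        segs = L.contours_to_segments([c1, c2], fg, cods)
        m1, m2 = segs[0].mask, segs[1].mask
        assert not np.any(m1 & m2)
        # strictly closer pixels go to their own seed
        assert m1[20, 20] and not m2[20, 20]
        assert m2[20, 40] and not m1[20, 40]
        # the equidistant column belongs to the lower index
        assert m1[20, 30] and not m2[20, 30]

    def test_fg_mask_clips_segments(self):
        fg = np.zeros((40, 40), bool)
        fg[:, :20] = True
        c = L.circle_contour((20, 20), 10, 40)
        segs = L.contours_to_segments([c], fg, L.CoDSet(points=[(20, 20)]))
        assert len(segs) == 1
        assert not np.any(segs[0].mask[:, 20:])


class TestSegmentLeaves:
    def test_all_background_frame_gives_empty_list(self, default_config):
        color = np.full((32, 32, 3), (110, 95, 70), np.uint8)
        depth = np.full((32, 32), 1500, np.uint16)
        frame = L.RGBDFrame(color=color, depth=depth, frame_id="bg")
        assert L.segment_leaves(frame, default_config) == []

    def test_single_clean_leaf_high_iou(self, single_clean_scene,
                                        default_config):
        frame, gt = single_clean_scene
        segs = L.segment_leaves(frame, default_config)
        assert len(segs) == 1
        assert iou(segs[0].mask, gt.instance_masks[0]) >= 0.9

    def test_occluding_pair_split_with_good_masks(self, segmented_two_leaf):
        frame, gt, segs, _ = segmented_two_leaf
        assert len(segs) == 2
        pair = []
        for m in gt.instance_masks:
            best = max(range(len(segs)), key=lambda k: iou(segs[k].mask, m))
            pair.append(best)
            assert iou(segs[best].mask, m) >= 0.7
        assert pair[0] != pair[1]

    def test_masks_disjoint_and_inside_foreground(self, segmented_two_leaf,
                                                  default_config):
        frame, _, segs, debug = segmented_two_leaf
        fg = debug["fg_labels"].labels > 0
        acc = np.zeros(frame.shape, bool)
        for s in segs:
            assert not np.any(acc & s.mask)
            acc |= s.mask
            assert not np.any(s.mask & ~fg)

    def test_deterministic_rerun(self, two_leaf_scene, default_config):
        frame, _ = two_leaf_scene
        a = L.segment_leaves(frame, default_config)
        b = L.segment_leaves(frame, default_config)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.mask, sb.mask)
            assert np.array_equal(sa.contour.vertices, sb.contour.vertices)

    def test_zero_offset_pair_degrades_to_unseparated(self, default_config):
        """Leaves at identical depth cannot be split, but nothing crashes."""
        params = L.SceneParams(n_leaves=2, occluded_fraction=1.0,
                               inter_leaf_offset_mm=0.0, seed=0, **SMALL)
        frame, gt = L.generate_scene(params)
        segs = L.segment_leaves(frame, default_config)
        report = L.evaluate_batch([(segs, gt)])
        assert report.overall.n_unseparated >= 1
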