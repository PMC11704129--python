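"""Membrane profile, cavity detection, and nested-cycle refinement."""

import numpy as np
import pytest

from persiseg.contours import ContourCurve, fill_contour
from persiseg.evaluation import iou_score
from persiseg.image import IntensityImage
from persiseg.phantom import generate_toy_image
from persiseg.segmentation import (
    NoMembraneFoundError,
    SegmentationConfig,
    detect_cavities,
    directed_hausdorff,
    refine_nested,
    segment_membrane,
    segment_slice,
    split_nested_pair,
)


def disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestDirectedHausdorff:
    def test_single_point_pair(self):
        assert directed_hausdorff([(0.0, 0.0)], [(3.0, 4.0)]) == pytest.approx(5.0)

    def test_subset_gives_zero(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert directed_hausdorff(pts, pts) == 0.0

    def test_shifted_square_brute_force(self):
        a = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        b = a + (0.0, 2.0)
        brute = max(min(np.linalg.norm(p - q) for q in b) for p in a)
        assert directed_hausdorff(a, b) == pytest.approx(brute) == pytest.approx(2.0)

    def test_asymmetry(self):
        a = [(0.0, 0.0)]
        b = [(0.0, 0.0), (0.0, 10.0)]
        assert directed_hausdorff(a, b) == 0.0
        assert directed_hausdorff(b, a) == 10.0


class TestSegmentMembrane:
    def test_constant_image_raises_no_membrane(self):
        with pytest.raises(NoMembraneFoundError):
            segment_membrane(IntensityImage(np.full((8, 8), 0.4)))

    def test_bright_blob_with_faint_speckle(self):
        u = np.full((40, 40), 0.1)
        blob = disk((40, 40), (20, 20), 10)
        u[blob] = 0.9
        rng = np.random.default_rng(5)
        for _ in range(6):
            r, c = rng.integers(2, 38, 2)
            if not disk((40, 40), (20, 20), 13)[r, c]:
                u[r, c] = 0.25  # low-persistence speckle
        gamma = segment_membrane(IntensityImage(u))
        assert np.array_equal(gamma.interior_mask, blob)

    def test_noiseless_phantom_outer_boundary(self, phantom_noiseless, segmented_noiseless):
        _, gt = phantom_noiseless
        for k, res in enumerate(segmented_noiseless):
            gamma = res.segmentation.membrane_boundary
            assert iou_score(gamma.interior_mask, gt.membrane_masks[k]) >= 0.95


class TestDetectCavities:
    def test_two_disks_found_within_one_pixel(self, phantom_noiseless, segmented_noiseless):
        _, gt = phantom_noiseless
        k = 10  # both cavity ellipsoids intersect this slice
        seg = segmented_noiseless[k].segmentation
        assert len(seg.cavities) == 2
        for cav in seg.cavities:
            best = max(
                iou_score(cav.interior_mask, cm[k]) for cm in gt.cavity_masks
            )
            assert best >= 0.6
            truth = max(gt.cavity_masks, key=lambda cm: iou_score(cav.interior_mask, cm[k]))
            truth_curve = ContourCurve.from_mask(truth[k])
            assert directed_hausdorff(cav, truth_curve) <= 2.0

    def test_dark_blob_outside_gamma_is_never_returned(self):
        u = np.full((48, 64), 0.05)
        u[disk((48, 64), (24, 20), 14)] = 0.9
        u[disk((48, 64), (24, 20), 10)] = 0.6
        u[disk((48, 64), (24, 20), 4)] = 0.15  # cavity inside the cell
        u[disk((48, 64), (24, 52), 8)] = 0.7  # a second object outside
        u[disk((48, 64), (24, 52), 4)] = 0.12  # with its own dark core
        img = IntensityImage(u)
        gamma = segment_membrane(img)
        cavities = detect_cavities(img, gamma)
        assert len(cavities) == 1
        center = np.argwhere(cavities[0].interior_mask).mean(axis=0)
        assert np.allclose(center, (24, 20), atol=1.0)

    def test_no_interior_minima_gives_empty_list(self):
        u = np.full((32, 32), 0.05)
        u[disk((32, 32), (16, 16), 10)] = 0.9
        img = IntensityImage(u)
        gamma = segment_membrane(img)
        assert detect_cavities(img, gamma) == []


class TestSplitNested:
    def make_pair(self):
        outer = ContourCurve.from_mask(disk((40, 40), (20, 20), 14))
        inner = ContourCurve.from_mask(disk((40, 40), (26, 20), 4))
        return inner, outer

    def test_offset_disk_split_is_disjoint_lobe(self):
        inner, outer = self.make_pair()
        new_outer = split_nested_pair(inner, outer)
        assert new_outer is not outer
        assert not new_outer.overlaps(inner)
        assert new_outer.area < outer.area

    def test_requires_nesting(self):
        inner, outer = self.make_pair()
        with pytest.raises(ValueError):
            split_nested_pair(outer, inner)

    def test_near_coincident_curves_trigger_fallback(self):
        from scipy import ndimage

        big_mask = disk((40, 40), (20, 20), 10)
        big = ContourCurve.from_mask(big_mask)
        small = ContourCurve.from_mask(ndimage.binary_erosion(big_mask))
        assert split_nested_pair(small, big) is big


class TestRefineNested:
    def test_no_nesting_is_identity(self):
        a = ContourCurve.from_mask(disk((40, 40), (12, 12), 5))
        b = ContourCurve.from_mask(disk((40, 40), (28, 28), 5))
        out = refine_nested([a, b])
        assert out == [a, b]

    def test_one_nested_pair_becomes_disjoint(self):
        outer = ContourCurve.from_mask(disk((40, 40), (20, 20), 14))
        inner = ContourCurve.from_mask(disk((40, 40), (26, 20), 4))
        out = refine_nested([inner, outer])
        assert len(out) == 2
        assert not out[0].overlaps(out[1])

    def test_three_level_chain_all_pairwise_disjoint(self):
        c1 = ContourCurve.from_mask(disk((60, 60), (38, 30), 4))
        c2 = ContourCurve.from_mask(disk((60, 60), (34, 30), 12))
        c3 = ContourCurve.from_mask(disk((60, 60), (30, 30), 22))
        out = refine_nested([c1, c2, c3])
        assert len(out) == 3
        total = sum(c.interior_mask.astype(int) for c in out)
        assert (total <= 1).all()

    def test_idempotence(self):
        outer = ContourCurve.from_mask(disk((40, 40), (20, 20), 14))
        inner = ContourCurve.from_mask(disk((40, 40), (26, 20), 4))
        once = refine_nested([inner, outer])
        twice = refine_nested(list(once))
        assert all(
            np.array_equal(a.interior_mask, b.interior_mask)
            for a, b in zip(once, twice)
        )


class TestSegmentSlice:
    def test_nested_cavities_fixture_yields_disjoint_curves(self):
        img = generate_toy_image("nested_cavities")
        seg = segment_slice(img)
        assert len(seg.cavities) == 2
        total = sum(c.interior_mask.astype(int) for c in seg.cavities)
        assert (total <= 1).all()
        for cav in seg.cavities:
            assert cav.nested_in(seg.membrane_boundary)

    def test_constant_image_propagates_error(self):
        with pytest.raises(NoMembraneFoundError):
            segment_slice(IntensityImage(np.full((6, 6), 0.2)))

    def test_invariants_on_phantom(self, segmented_noiseless):
        for res in segmented_noiseless:
            seg = res.segmentation
            gamma = seg.membrane_boundary
            total = np.zeros_like(gamma.interior_mask, dtype=int)
            for cav in seg.cavities:
                assert cav.nested_in(gamma)
                assert np.array_equal(
                    fill_contour(cav.vertices, cav.interior_mask.shape),
                    cav.interior_mask,
                )
                total += cav.interior_mask
            assert (total <= 1).all()

    def test_pad_border_closes_border_touching_structure(self):
        # a bright blob touching the border cannot be enclosed by a dark
        # cycle without padding, so its persistence collapses to zero
        u = np.full((30, 30), 0.1)
        blob = disk((30, 30), (0, 15), 9)
        u[blob] = 0.9
        img = IntensityImage(u)
        with pytest.raises(NoMembraneFoundError):
            segment_membrane(img)
        cfg = SegmentationConfig(pad_border=True)
        gamma = segment_membrane(img, cfg)
        assert gamma.interior_mask.shape == (30, 30)
        assert gamma.interior_mask[0, 15]
        assert np.array_equal(gamma.interior_mask, blob)
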