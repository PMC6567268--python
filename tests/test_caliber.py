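import numpy as np
import pytest

from angioprint.caliber import (
    build_ladder,
    classify_vessels,
    cross_section_map,
    equivalent_diameter_um,
    geometric_mean_ratio,
    min_cross_section,
)
from tests.conftest import make_binary


def brute_min_cross_section(v: np.ndarray, voxel) -> int:
    """Independent per-voxel oracle: BFS flood fill in each of the 3 planes."""
    z, y, x = voxel
    areas = []
    for axis, idx, seed in ((0, z, (y, x)), (1, y, (z, x)), (2, x, (z, y))):
        plane = np.take(v, idx, axis=axis)
        seen = {seed}
        frontier = [seed]
        while frontier:
            i, j = frontier.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    p = (i + di, j + dj)
                    if (
                        p not in seen
                        and 0 <= p[0] < plane.shape[0]
                        and 0 <= p[1] < plane.shape[1]
                        and plane[p]
                    ):
                        seen.add(p)
                        frontier.append(p)
        areas.append(len(seen))
    return min(areas)


class TestBuildLadder:
    def test_default_ladder_reproduces_integer_voxel_rounding(self):
        ladder = build_ladder(4, 1.8, 6, 0.41)
        assert ladder.thresholds_voxels == (4, 7, 13, 23, 42, 76, 136)
        np.testing.assert_allclose(
            ladder.thresholds_um2, (1.64, 2.87, 5.33, 9.43, 17.22, 31.16, 55.76)
        )

    def test_powers_of_two(self):
        assert build_ladder(1, 2.0, 2, 1.0).thresholds_voxels == (1, 2, 4)

    @pytest.mark.parametrize("bad", [{"ratio": 1.0}, {"offset_voxels": 0}, {"n_classes": 0}])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = {"offset_voxels": 4, "ratio": 1.8, "n_classes": 6, "voxel_area": 0.41}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            build_ladder(**kwargs)

    def test_diameter_and_ratio_helpers(self):
        assert equivalent_diameter_um(np.pi) == pytest.approx(2.0)
        assert geometric_mean_ratio(4, 136, 6) == pytest.approx((136 / 4) ** (1 / 6))
        with pytest.raises(ValueError):
            geometric_mean_ratio(0, 1, 1)


class TestMinCrossSection:
    def test_isolated_voxel(self):
        v = np.zeros((5, 5, 5), dtype=bool)
        v[2, 2, 2] = True
        assert min_cross_section(make_binary(v), (2, 2, 2)) == 1

    def test_solid_bar_takes_transverse_plane(self):
        v = np.zeros((7, 7, 12), dtype=bool)
        v[2:5, 2:5, 1:11] = True  # 3x3 cross-section, length 10
        assert min_cross_section(make_binary(v), (3, 3, 5)) == min(9, 30, 30)

    def test_diagonal_pair_is_one_component_under_8_connectivity(self):
        # two 3-voxel columns touching only diagonally in the z-planes:
        # the diagonal plane section (size 2) is the minimum iff 8-connected
        v = np.zeros((3, 5, 5), dtype=bool)
        v[:, 1, 1] = v[:, 2, 2] = True
        assert min_cross_section(make_binary(v), (1, 1, 1)) == 2

    def test_background_voxel_rejected(self):
        v = np.zeros((3, 3, 3), dtype=bool)
        v[1, 1, 1] = True
        with pytest.raises(ValueError):
            min_cross_section(make_binary(v), (0, 0, 0))

    def test_map_matches_brute_force_on_random_stacks(self, rng):
        for _ in range(2):
            v = rng.random((9, 10, 11)) < 0.3
            b = make_binary(v)
            amap = cross_section_map(b)
            coords = np.argwhere(v)
            idx = rng.choice(len(coords), size=min(60, len(coords)), replace=False)
            for voxel in coords[idx]:
                voxel = tuple(int(c) for c in voxel)
                assert amap[voxel] == brute_min_cross_section(v, voxel)
        assert (amap[~v] == 0).all()


class TestClassifyVessels:
    def bar(self, side_y, side_x, length=30, grid=(40, 40, 40)):
        v = np.zeros(grid, dtype=bool)
        y0 = (grid[1] - side_y) // 2
        x0 = (grid[2] - side_x) // 2
        v[2 : 2 + length, y0 : y0 + side_y, x0 : x0 + side_x] = True
        return make_binary(v)

    @pytest.mark.parametrize(
        "side_y,side_x,expected_label",
        [
            (10, 10, 1),   # area 100: 76 < 100 <= 136 -> largest class
            (8, 17, 1),    # area 136: upper-inclusive boundary stays class 1
            (4, 19, 2),    # area 76: falls to the next class (T4 < 76 <= T5)
            (12, 12, 8),   # area 144 > 136: over-range sentinel
            (2, 2, 7),     # area 4 <= offset: sub-offset class
            (3, 3, 5),     # area 9: 7 < 9 <= 13
        ],
    )
    def test_class_assignment_follows_half_open_intervals(self, side_y, side_x, expected_label):
        b = self.bar(side_y, side_x)
        ladder = build_ladder(4, 1.8, 6, b.voxel_area)
        cm = classify_vessels(b, ladder)
        mid = (17, 20, 20)
        assert b.voxels[mid]
        assert cm.labels[mid] == expected_label

    def test_labels_partition_foreground(self, rng):
        v = rng.random((10, 12, 12)) < 0.3
        b = make_binary(v)
        cm = classify_vessels(b, build_ladder(4, 1.8, 6, b.voxel_area))
        assert (cm.labels[~v] == 0).all()
        assert ((cm.labels[v] >= 1) & (cm.labels[v] <= cm.over_range_label)).all()
        assert sum(cm.class_counts().values()) == v.sum()

    def test_axis_permutation_leaves_histogram_unchanged(self, rng):
        v = rng.random((8, 10, 12)) < 0.25
        ladder = build_ladder(4, 1.8, 6, 0.64**2)
        counts = classify_vessels(make_binary(v), ladder).class_counts()
        for perm in [(1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            permuted = classify_vessels(make_binary(np.transpose(v, perm)), ladder)
            assert permuted.class_counts() == counts

    def test_rasterized_cylinder_interior_matches_disk_area(self):
        # axis-aligned cylinder of radius 3 voxels
        r = 3
        v = np.zeros((9, 9, 20), dtype=bool)
        zz, yy = np.mgrid[0:9, 0:9]
        disk = (zz - 4) ** 2 + (yy - 4) ** 2 <= r * r
        v[:, :, :] = disk[:, :, None]
        b = make_binary(v)
        disk_area = int(disk.sum())
        assert disk_area == 29  # brute-force disk rasterization
        assert min_cross_section(b, (4, 4, 10)) == disk_area
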