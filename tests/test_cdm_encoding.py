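"""Depth LUT, volume -> CDM projection, rasterization and mirroring."""

import numpy as np
import pytest

from cdmip.cdm_encoding import (
    BACKGROUND,
    DecodeError,
    DepthLUT,
    DepthLUTError,
    build_depth_lut,
    combine_mirror,
    crosses_midline,
    decode_depth,
    depth_map,
    encode_volume,
    luminance,
    mirror_cdm,
    rasterize_skeleton,
)
from cdmip.core_model import (
    AlignmentSpace,
    CDMImage,
    Skeleton,
    SkeletonNode,
    Volume3D,
)

from conftest import make_cdm


class TestDepthLUT:
    def test_two_slices_are_pure_blue_and_red(self):
        lut = build_depth_lut(2)
        assert tuple(lut.colors[0]) == (0, 0, 255)  # anterior = blue
        assert tuple(lut.colors[1]) == (255, 0, 0)  # posterior = red

    def test_256_distinct_monotone_hue(self):
        lut = build_depth_lut(256)
        assert len({tuple(c) for c in lut.colors}) == 256
        # hue decreases monotonically blue -> red
        import colorsys

        hues = [colorsys.rgb_to_hsv(*(c / 255.0))[0] for c in lut.colors]
        assert all(h1 >= h2 for h1, h2 in zip(hues, hues[1:]))

    @pytest.mark.parametrize("n", [2, 3, 17, 64, 256, 512])
    def test_decode_is_exact_inverse(self, n):
        lut = build_depth_lut(n)
        for k in range(n):
            assert decode_depth(lut.colors[k], lut) == k

    @pytest.mark.parametrize("n", [0, 1, 1025])
    def test_bounds_rejected(self, n):
        with pytest.raises(DepthLUTError):
            build_depth_lut(n)

    def test_duplicate_colors_rejected(self):
        with pytest.raises(DepthLUTError):
            DepthLUT(colors=np.array([[1, 2, 3], [1, 2, 3]], dtype=np.uint8))

    def test_serialization_round_trip(self, tmp_path):
        lut = build_depth_lut(33)
        p = tmp_path / "lut.json"
        lut.to_json(p)
        assert np.array_equal(DepthLUT.from_json(p).colors, lut.colors)


class TestDecode:
    def test_black_is_background(self):
        lut = build_depth_lut(16)
        assert decode_depth((0, 0, 0), lut) == BACKGROUND

    def test_far_off_color_raises(self):
        lut = build_depth_lut(16)
        with pytest.raises(DecodeError):
            decode_depth((255, 0, 255), lut)  # magenta: outside the hue ramp

    def test_intensity_scaled_color_decodes(self):
        lut = build_depth_lut(16)
        for k in (0, 5, 11, 15):
            for scale in (1.0, 0.8, 0.4, 0.1):
                dim = np.rint(lut.colors[k] * scale)
                assert decode_depth(dim, lut) == k

    def test_depth_map_matches_scalar_decode(self, small_space, small_lut):
        rng = np.random.default_rng(3)
        from conftest import random_cdm

        cdm = random_cdm(small_space, small_lut, rng, density=0.2)
        dm = depth_map(cdm, small_lut)
        for y in range(0, small_space.shape_xyz[1], 5):
            for x in range(0, small_space.shape_xyz[0], 7):
                assert dm[y, x] == decode_depth(cdm.pixels[y, x], small_lut)


class TestEncodeVolume:
    def test_empty_volume_all_black(self, small_space, small_lut):
        vol = Volume3D(small_space, np.zeros(small_space.shape_zyx, np.uint8))
        cdm = encode_volume(vol, small_lut)
        assert not cdm.pixels.any()

    def test_single_voxel(self, small_space, small_lut):
        data = np.zeros(small_space.shape_zyx, np.uint8)
        data[9, 7, 30] = 255  # z=9, y=7, x=30
        cdm = encode_volume(Volume3D(small_space, data), small_lut)
        fg = cdm.foreground_mask()
        assert fg.sum() == 1 and fg[7, 30]
        assert tuple(cdm.pixels[7, 30]) == tuple(small_lut.colors[9])

    def test_tie_breaks_toward_shallower_slice(self, small_space, small_lut):
        data = np.zeros(small_space.shape_zyx, np.uint8)
        data[3, 5, 5] = 200
        data[7, 5, 5] = 200
        cdm = encode_volume(Volume3D(small_space, data), small_lut)
        assert decode_depth(cdm.pixels[5, 5], small_lut) == 3

    def test_matches_per_column_scan_oracle(self, small_space, small_lut):
        """Argmax slice and foreground agree with a per-column brute scan
        on 1000+ random columns."""
        rng = np.random.default_rng(4)
        from conftest import random_volume

        vol = random_volume(small_space, rng, density=0.1)
        thr = 40
        cdm = encode_volume(vol, small_lut, intensity_threshold=thr)
        dm = depth_map(cdm, small_lut)
        sz, sy, sx = small_space.shape_zyx
        for y in range(sy):
            for x in range(sx):
                col = vol.data[:, y, x]
                if col.max() > thr:
                    best = min(np.nonzero(col == col.max())[0])
                    assert dm[y, x] == best
                else:
                    assert dm[y, x] == BACKGROUND

    def test_foreground_count_equals_suprathreshold_columns(
        self, small_space, small_lut
    ):
        rng = np.random.default_rng(5)
        from conftest import random_volume

        vol = random_volume(small_space, rng, density=0.05)
        cdm = encode_volume(vol, small_lut, intensity_threshold=10)
        expected = int((vol.data.max(axis=0) > 10).sum())
        assert int(cdm.foreground_mask().sum()) == expected

    def test_slice_count_mismatch_rejected(self, small_space):
        lut = build_depth_lut(8)  # space has 16 slices
        vol = Volume3D(small_space, np.zeros(small_space.shape_zyx, np.uint8))
        with pytest.raises(ValueError, match="slices"):
            encode_volume(vol, lut)

    def test_dim_voxels_stay_decodable(self, small_space, small_lut):
        data = np.zeros(small_space.shape_zyx, np.uint8)
        data[4, 3, 3] = 1  # minimum nonzero intensity
        cdm = encode_volume(Volume3D(small_space, data), small_lut)
        assert cdm.pixels[3, 3].any()
        assert decode_depth(cdm.pixels[3, 3], small_lut) == 4


def _brute_capsule_count(skel, space, radius_um):
    """Brute-force oracle: test every voxel's distance to every segment."""
    by_id = {n.node_id: n for n in skel.nodes}
    segs = []
    used = set()
    for n in skel.nodes:
        if n.parent_id != -1:
            p = by_id[n.parent_id]
            segs.append((np.array([p.x, p.y, p.z]), np.array([n.x, n.y, n.z])))
            used.update((n.node_id, p.node_id))
    for n in skel.nodes:
        if n.node_id not in used:
            pt = np.array([n.x, n.y, n.z])
            segs.append((pt, pt))
    vs = np.array(space.voxel_size_um)
    sx, sy, sz = space.shape_xyz
    count = 0
    for z in range(sz):
        for y in range(sy):
            for x in range(sx):
                p = np.array([x, y, z]) * vs
                for a, b in segs:
                    d = b - a
                    dd = d @ d
                    t = 0.0 if dd == 0 else float(np.clip((p - a) @ d / dd, 0, 1))
                    if np.linalg.norm(p - (a + t * d)) <= radius_um:
                        count += 1
                        break
    return count


class TestRasterize:
    def test_single_node_is_sphere(self, small_space):
        skel = Skeleton([SkeletonNode(1, 1, 30, 15, 8, 1.0, -1)], small_space)
        vol = rasterize_skeleton(skel, small_space, radius_um=1.0)
        zz, yy, xx = np.nonzero(vol.data)
        # 3D cross of radius 1 voxel around (30, 15, 8)
        assert len(zz) == 7
        assert (vol.data[8, 15, 30] == 255).all()

    def test_segment_count_matches_brute_force(self, small_space):
        skel = Skeleton(
            [
                SkeletonNode(1, 1, 10.0, 15.0, 8.0, 1.0, -1),
                SkeletonNode(2, 3, 25.0, 15.0, 8.0, 1.0, 1),
            ],
            small_space,
        )
        r = 2.3
        vol = rasterize_skeleton(skel, small_space, radius_um=r)
        assert int((vol.data > 0).sum()) == _brute_capsule_count(skel, small_space, r)

    def test_three_node_bend_matches_brute_force(self, small_space):
        skel = Skeleton(
            [
                SkeletonNode(1, 1, 10.0, 10.0, 5.0, 1.0, -1),
                SkeletonNode(2, 3, 20.0, 12.0, 8.0, 1.0, 1),
                SkeletonNode(3, 3, 22.0, 20.0, 10.0, 1.0, 2),
            ],
            small_space,
        )
        r = 1.7
        vol = rasterize_skeleton(skel, small_space, radius_um=r)
        assert int((vol.data > 0).sum()) == _brute_capsule_count(skel, small_space, r)

    def test_radius_monotone(self, small_space):
        skel = Skeleton(
            [
                SkeletonNode(1, 1, 10.0, 10.0, 5.0, 1.0, -1),
                SkeletonNode(2, 3, 20.0, 12.0, 8.0, 1.0, 1),
                SkeletonNode(3, 3, 22.0, 20.0, 10.0, 1.0, 2),
            ],
            small_space,
        )
        small = rasterize_skeleton(skel, small_space, 1.0).data > 0
        big = rasterize_skeleton(skel, small_space, 2.0).data > 0
        assert np.all(big[small])

    def test_rotation_consistent_foreground_count(self):
        """A 180° in-plane rotation about the space center preserves the
        rasterized voxel count (symmetric grid)."""
        space = AlignmentSpace("rot", (41, 41, 11), (1.0, 1.0, 1.0))
        cx = cy = 20.0
        pts = [(10.0, 12.0, 5.0), (25.0, 18.0, 5.0), (30.0, 30.0, 5.0)]
        rot = [(2 * cx - x, 2 * cy - y, z) for x, y, z in pts]

        def mk(points):
            nodes = [
                SkeletonNode(i + 1, 3, x, y, z, 1.0, i if i else -1)
                for i, (x, y, z) in enumerate(points)
            ]
            return Skeleton(nodes, space)

        a = rasterize_skeleton(mk(pts), space, 1.5).data
        b = rasterize_skeleton(mk(rot), space, 1.5).data
        assert int((a > 0).sum()) == int((b > 0).sum())

    def test_out_of_bounds_warns_and_clips(self, small_space):
        skel = Skeleton(
            [
                SkeletonNode(1, 1, 60.0, 15.0, 8.0, 1.0, -1),
                SkeletonNode(2, 3, 70.0, 15.0, 8.0, 1.0, 1),  # beyond x=64
            ],
            small_space,
        )
        with pytest.warns(UserWarning, match="clip"):
            vol = rasterize_skeleton(skel, small_space, 1.0)
        assert (vol.data > 0).any()

    def test_nonpositive_radius_rejected(self, small_space):
        skel = Skeleton([SkeletonNode(1, 1, 5, 5, 5, 1.0, -1)], small_space)
        with pytest.raises(ValueError):
            rasterize_skeleton(skel, small_space, 0.0)


class TestMirror:
    def test_involution(self, small_space, small_lut):
        cdm = make_cdm(
            small_space, small_lut, [(3, 4, 2), (10, 20, 9), (55, 7, 15)]
        )
        back = mirror_cdm(mirror_cdm(cdm))
        assert np.array_equal(back.pixels, cdm.pixels)

    def test_mirror_reflects_about_midline(self, small_space, small_lut):
        cdm = make_cdm(small_space, small_lut, [(3, 4, 2)])
        m = mirror_cdm(cdm)
        # midline at 32 µm, pixel-center reflection: x' = 64 - 1 - x
        assert m.foreground_mask()[4, 60]
        assert m.foreground_mask().sum() == 1

    def test_symmetric_cdm_combines_to_itself(self, small_space, small_lut):
        cdm = make_cdm(small_space, small_lut, [(3, 4, 2), (60, 4, 2)])
        comb = combine_mirror(cdm)
        assert np.array_equal(comb.pixels, cdm.pixels)

    def test_one_sided_combine_doubles_foreground(self, small_space, small_lut):
        pix = [(3, 4, 2), (5, 9, 7), (10, 20, 12)]  # all left of midline
        cdm = make_cdm(small_space, small_lut, pix)
        comb = combine_mirror(cdm)
        assert int(comb.foreground_mask().sum()) == 2 * len(pix)

    def test_combine_keeps_brighter_pixel(self, small_space, small_lut):
        # bright pixel at x=3 and a dim one at its mirror position x=60
        px = np.zeros((32, 64, 3), dtype=np.uint8)
        px[4, 3] = small_lut.colors[2]
        px[4, 60] = np.rint(small_lut.colors[9] * 0.3).astype(np.uint8)
        cdm = CDMImage(small_space, px)
        comb = combine_mirror(cdm)
        assert tuple(comb.pixels[4, 60]) == tuple(small_lut.colors[2])
        assert tuple(comb.pixels[4, 3]) == tuple(small_lut.colors[2])

    def test_luminance_is_value_channel(self):
        assert luminance(np.array([10, 200, 30])) == 200


class TestCrossesMidline:
    def _skel(self, space, xs):
        nodes = [
            SkeletonNode(i + 1, 3, x, 10.0, 5.0, 1.0, i if i else -1)
            for i, x in enumerate(xs)
        ]
        return Skeleton(nodes, space)

    def test_spanning_neuron_crosses(self, small_space):
        assert crosses_midline(self._skel(small_space, [10.0, 50.0]), small_space)

    def test_one_sided_neuron_does_not(self, small_space):
        assert not crosses_midline(self._skel(small_space, [5.0, 20.0]), small_space)

    def test_band_tolerance(self, small_space):
        # midline at 32; endpoint at 28 is within the default 5 µm band
        assert crosses_midline(self._skel(small_space, [5.0, 28.0]), small_space)
        assert not crosses_midline(
            self._skel(small_space, [5.0, 28.0]), small_space, band_um=2.0
        )
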