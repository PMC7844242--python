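"""Core reduction math: thresholds, labeling, packing, levels, centroids."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from recode.calibration import CalibrationFrame
from recode.reduction import (
    BinaryMap,
    CorruptionError,
    Puddle,
    decode_centroids,
    encode_centroids,
    expand_frame,
    label_components,
    localize_puddle,
    pack_binary_map,
    pack_bits,
    reduce_frame,
    summarize_puddle,
    threshold_frame,
    unpack_bits,
)


class TestThreshold:
    def test_strictly_greater(self):
        thr = np.full((4, 4), 100.0)
        frame = np.full((4, 4), 100, dtype=np.uint16)
        assert threshold_frame(frame, thr).n_signal == 0
        frame[2, 3] = 101
        bmap = threshold_frame(frame, thr)
        assert bmap.n_signal == 1 and bmap.mask[2, 3]

    def test_dead_pixels_never_signal(self):
        thr = np.full((2, 2), np.inf)
        frame = np.full((2, 2), 65535, dtype=np.uint16)
        assert threshold_frame(frame, thr).n_signal == 0

    def test_matches_elementwise_oracle(self, rng):
        thr = rng.normal(110, 5, size=(32, 32))
        frame = rng.integers(0, 200, size=(32, 32)).astype(np.uint16)
        assert np.array_equal(threshold_frame(frame, thr).mask, frame > thr)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            threshold_frame(np.zeros((3, 3), dtype=np.uint16),
                            CalibrationFrame(threshold=np.full((4, 4), 1.0)))


def _flood_fill_components(mask, connectivity=8):
    """Brute-force BFS oracle for connected components."""
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp, stack_ = [], [(r, c)]
                seen[r, c] = True
                while stack_:
                    y, x = stack_.pop()
                    comp.append((y, x))
                    for dr, dc in nbrs:
                        ny, nx = y + dr, x + dc
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack_.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


class TestLabeling:
    def test_diagonal_pair_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, connectivity=8).n_puddles == 1
        assert label_components(mask, connectivity=4).n_puddles == 2

    def test_empty_map(self):
        pset = label_components(np.zeros((5, 5), dtype=bool))
        assert pset.n_puddles == 0 and pset.labels.max() == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(60):
            mask = rng.random((24, 24)) < rng.uniform(0.05, 0.5)
            pset = label_components(mask, connectivity=connectivity)
            oracle = _flood_fill_components(mask, connectivity)
            assert pset.n_puddles == len(oracle)
            got = {frozenset(map(tuple, p.pixels)) for p in pset.puddles}
            assert got == set(oracle)

    def test_first_touch_label_order(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 4] = True  # touched first in raster order
        mask[3, 0] = True
        pset = label_components(mask)
        assert pset.labels[0, 4] == 1 and pset.labels[3, 0] == 2

    def test_translation_equivariance(self, rng):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:10, 4:10] = rng.random((6, 6)) < 0.5
        shifted = np.roll(mask, (7, 11), axis=(0, 1))
        a = label_components(mask)
        b = label_components(shifted)
        assert a.n_puddles == b.n_puddles
        moved = {
            frozenset(((r + 7) % 32, (c + 11) % 32) for r, c in map(tuple, p.pixels))
            for p in a.puddles
        }
        got = {frozenset(map(tuple, p.pixels)) for p in b.puddles}
        assert moved == got

    def test_areas_partition_the_mask(self, rng):
        mask = rng.random((40, 40)) < 0.2
        pset = label_components(mask)
        assert pset.areas().sum() == mask.sum()


class TestBitPacking:
    def test_eight_single_bits_in_one_byte(self):
        assert len(pack_bits(np.array([1, 0, 1, 1, 0, 0, 1, 0]), 1)) == 1

    def test_twelve_bit_example(self):
        payload = pack_bits(np.array([4095, 0]), 12)
        assert len(payload) == 3
        assert np.array_equal(unpack_bits(payload, 2, 12), [4095, 0])

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            pack_bits(np.array([4096]), 12)

    @given(
        bit_depth=st.integers(1, 16),
        n=st.integers(0, 300),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_identity(self, bit_depth, n, seed):
        values = np.random.default_rng(seed).integers(0, 2**bit_depth, size=n)
        payload = pack_bits(values, bit_depth)
        assert len(payload) == (n * bit_depth + 7) // 8
        assert np.array_equal(unpack_bits(payload, n, bit_depth), values)

    def test_large_12bit_roundtrip(self, rng):
        values = rng.integers(0, 4096, size=100_000)
        assert np.array_equal(unpack_bits(pack_bits(values, 12), values.size, 12), values)

    def test_wrong_length_payload_rejected(self):
        with pytest.raises(CorruptionError):
            unpack_bits(b"\x00", 3, 12)


class TestPuddleFeatures:
    def test_summary_statistics(self):
        p = Puddle(1, np.array([[0, 0], [0, 1]]), np.array([10, 30]))
        assert summarize_puddle(p, "sum") == 40
        assert summarize_puddle(p, "max") == 30
        assert summarize_puddle(p, "mean") == 20

    def test_single_pixel_all_statistics_equal(self):
        p = Puddle(1, np.array([[2, 2]]), np.array([7]))
        assert {summarize_puddle(p, s) for s in ("sum", "max", "mean")} == {7}

    def test_statistics_match_recomputation(self, rng):
        for _ in range(20):
            n = rng.integers(1, 9)
            vals = rng.integers(1, 1000, size=n)
            p = Puddle(1, np.stack([np.zeros(n, int), np.arange(n)], axis=1), vals)
            assert summarize_puddle(p, "sum") == vals.sum()
            assert summarize_puddle(p, "max") == vals.max()
            assert summarize_puddle(p, "mean") == int(np.rint(vals.mean()))

    def test_max_pixel_localization(self):
        p = Puddle(1, np.array([[0, 0], [0, 1]]), np.array([10, 30]))
        assert localize_puddle(p, "max_pixel") == (0, 1)

    def test_square_centroid_rounds_half_down(self):
        # 2x2 uniform square: centroid (0.5, 0.5) -> top-left pixel
        p = Puddle(1, np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                   np.array([5, 5, 5, 5]))
        assert localize_puddle(p, "unweighted_centroid") == (0, 0)
        assert localize_puddle(p, "weighted_centroid") == (0, 0)

    def test_weighted_centroid_arithmetic(self):
        # col = (0*1 + 3*3)/4 = 2.25 -> pixel column 2
        p = Puddle(1, np.array([[0, 0], [0, 3]]), np.array([1, 3]))
        assert localize_puddle(p, "weighted_centroid") == (0, 2)

    def test_intensity_strategy_needs_values(self):
        p = Puddle(1, np.array([[0, 0]]), None)
        with pytest.raises(ValueError, match="ADU"):
            localize_puddle(p, "max_pixel")
        assert localize_puddle(p, "unweighted_centroid") == (0, 0)


class TestReduceExpand:
    @staticmethod
    def _frame_and_thr(rng, shape=(10, 10), density=0.1):
        thr = np.full(shape, 100.0)
        frame = rng.integers(80, 100, size=shape).astype(np.uint16)
        hot = rng.random(shape) < density
        frame[hot] = rng.integers(101, 4000, size=int(hot.sum()))
        return frame, thr

    def test_l3_payload_is_exactly_packed_map(self, rng):
        frame, thr = self._frame_and_thr(rng)
        red = reduce_frame(frame, thr, 3)
        assert len(red.binary_payload) == 13  # ceil(100/8)
        assert red.intensity_payload == b""

    def test_l4_single_puddle_single_pixel(self):
        thr = np.full((6, 6), 100.0)
        frame = np.full((6, 6), 90, dtype=np.uint16)
        frame[2:4, 2:4] = 200
        red = reduce_frame(frame, thr, 4, strategy="unweighted_centroid")
        counted = expand_frame(red)
        assert counted.sum() == 1 and counted[2, 2] == 1

    def test_l1_expand_is_masked_identity(self, rng):
        for _ in range(25):
            frame, thr = self._frame_and_thr(rng, shape=(16, 16))
            red = reduce_frame(frame, thr, 1)
            back = expand_frame(red)
            mask = frame > thr
            assert np.array_equal(back[mask], frame[mask])
            assert np.all(back[~mask] == 0)

    def test_l2_statistics_in_label_order(self, rng):
        frame, thr = self._frame_and_thr(rng, shape=(20, 20))
        red = reduce_frame(frame, thr, 2, statistic="sum")
        bmap, stats_arr = expand_frame(red)
        pset = label_components(bmap, frame=frame)
        expect = [summarize_puddle(p, "sum") for p in pset.puddles]
        assert list(stats_arr) == expect

    def test_l3_expand_equals_threshold_map(self, rng):
        frame, thr = self._frame_and_thr(rng)
        red = reduce_frame(frame, thr, 3)
        assert np.array_equal(expand_frame(red).mask, frame > thr)

    def test_l4_true_count_equals_puddle_count(self, rng):
        frame, thr = self._frame_and_thr(rng, shape=(24, 24), density=0.05)
        red4 = reduce_frame(frame, thr, 4)
        n_puddles = label_components(frame > thr).n_puddles
        assert red4.n_puddles == n_puddles
        assert expand_frame(red4).sum() == n_puddles

    def test_invalid_level_rejected(self, rng):
        frame, thr = self._frame_and_thr(rng)
        with pytest.raises(ValueError, match="level"):
            reduce_frame(frame, thr, 5)

    def test_truncated_payloads_raise_corruption(self, rng):
        frame, thr = self._frame_and_thr(rng, shape=(16, 16))
        red = reduce_frame(frame, thr, 1)
        import dataclasses

        clipped = dataclasses.replace(red, intensity_payload=red.intensity_payload[:-1])
        with pytest.raises(CorruptionError):
            expand_frame(clipped)
        with pytest.raises(CorruptionError):
            dataclasses.replace(red, binary_payload=red.binary_payload[:-1])
        # mask/count inconsistency is caught too
        bad_map = bytearray(red.binary_payload)
        bad_map[0] ^= 0xFF
        with pytest.raises(CorruptionError):
            expand_frame(dataclasses.replace(red, binary_payload=bytes(bad_map)))


class TestCentroidEncodings:
    def test_single_origin_centroid_linear_index(self):
        payload = encode_centroids(np.array([[0, 0]]), (16, 16), "linear_index")
        assert payload == b"\x00\x00"  # one 16-bit word, value 0

    def test_empty_set_all_modes(self):
        for mode in ("linear_index", "rle", "binary_image"):
            payload = encode_centroids(np.zeros((0, 2)), (16, 16), mode)
            decoded = decode_centroids(payload, (16, 16), mode)
            if mode == "binary_image":
                assert len(payload) == 32  # packed empty map
            else:
                assert payload == b""
            assert decoded.shape == (0, 2)

    def test_modes_agree_on_random_sets(self, rng):
        shape = (64, 96)
        pts = np.stack(
            [rng.integers(0, shape[0], 1000), rng.integers(0, shape[1], 1000)], axis=1
        )
        reference = None
        for mode in ("linear_index", "rle", "binary_image"):
            decoded = decode_centroids(encode_centroids(pts, shape, mode), shape, mode)
            got = set(map(tuple, decoded))
            assert got == set(map(tuple, pts))
            if reference is None:
                reference = got
            assert got == reference

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            encode_centroids(np.array([[16, 0]]), (16, 16), "binary_image")
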