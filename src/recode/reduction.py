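"""Core reduction math: thresholding, puddle labeling, bit packing, L1-L4.

An electron puddle is the cluster of supra-threshold pixels left by one
incident electron's secondary charge cloud.  All four reduction levels
start from the same per-frame binary map (pixel strictly above its
per-pixel threshold = signal):

* L1 keeps the binary map plus the bit-packed ADU values of every signal
  pixel (row-major order) - lossless above threshold, recalibratable.
* L2 keeps the binary map plus one packed summary statistic (sum, max or
  mean ADU) per puddle, in label order.
* L3 keeps the binary map only.
* L4 keeps a binary map with a single localization pixel per puddle
  (the estimated electron entry point).

Everything here is deterministic: no RNG, fixed tie-breaks, fixed
row-major first-touch label order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationFrame

__all__ = [
    "BinaryMap",
    "Puddle",
    "PuddleSet",
    "ReducedFrame",
    "CorruptionError",
    "threshold_frame",
    "label_components",
    "pack_bits",
    "unpack_bits",
    "pack_binary_map",
    "unpack_binary_map",
    "summarize_puddle",
    "localize_puddle",
    "reduce_frame",
    "expand_frame",
    "encode_centroids",
    "decode_centroids",
    "sum_statistic_bit_depth",
]

LEVELS = (1, 2, 3, 4)
STATISTICS = ("sum", "max", "mean")
STRATEGIES = ("max_pixel", "weighted_centroid", "unweighted_centroid")

#: cap on puddle area assumed when sizing the packed width of the "sum"
#: statistic (sum of up to 256 pixels needs bit_depth + 8 bits)
MAX_SUM_AREA = 256


class CorruptionError(ValueError):
    """A reduced payload is inconsistent with its declared geometry."""


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    raise ValueError("connectivity must be 4 or 8")


@dataclass
class BinaryMap:
    """Per-frame boolean signal map (True = supra-threshold pixel)."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_signal(self) -> int:
        return int(self.mask.sum())


@dataclass
class Puddle:
    """One labeled connected component of a binary map.

    ``pixels`` are stored in row-major order; ``values`` holds the ADUs at
    those pixels when the source frame is available (L1-grade input) and
    is ``None`` otherwise (shape-only input).
    """

    label: int
    pixels: np.ndarray  # (area, 2) int rows/cols, row-major order
    values: np.ndarray | None = None

    @property
    def area(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PuddleSet:
    """All puddles of one frame, with the label image that induced them."""

    labels: np.ndarray
    puddles: list[Puddle]
    frame_index: int = 0

    @property
    def n_puddles(self) -> int:
        return len(self.puddles)

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.puddles], dtype=np.int64)


def threshold_frame(frame: np.ndarray, calib: CalibrationFrame | np.ndarray, frame_index: int = 0) -> BinaryMap:
    """Binary signal map: pixel is signal iff strictly above its threshold.

    Dead pixels carry a +inf threshold and therefore never appear as
    signal.  Strict ``>`` is deliberate: a pixel exactly at threshold is
    noise.
    """
    threshold = calib.threshold if isinstance(calib, CalibrationFrame) else np.asarray(calib)
    frame = np.asarray(frame)
    if frame.shape != threshold.shape:
        raise ValueError(f"frame shape {frame.shape} != threshold shape {threshold.shape}")
    return BinaryMap(frame > threshold, frame_index=frame_index)


def _first_touch_relabel(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Remap scipy labels to row-major first-touch order (1..n)."""
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence index of each label in the raster scan
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")  # old label-1 sorted by first touch
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels], n


def label_components(
    bmap: BinaryMap | np.ndarray,
    connectivity: int = 8,
    frame: np.ndarray | None = None,
) -> PuddleSet:
    """Label maximal connected clusters (electron puddles) of a binary map.

    Labels are assigned in deterministic row-major first-touch order.
    When the source ``frame`` is supplied, per-pixel ADU values are
    attached to every puddle (needed for intensity-based statistics and
    localizations).
    """
    if isinstance(bmap, BinaryMap):
        mask, frame_index = bmap.mask, bmap.frame_index
    else:
        mask, frame_index = np.asarray(bmap, dtype=bool), 0
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    labels, n = _first_touch_relabel(labels, n)
    puddles: list[Puddle] = []
    if n:
        flat = labels.ravel()
        nz = np.flatnonzero(flat)  # row-major order within each puddle
        order = np.argsort(flat[nz], kind="stable")
        nz = nz[order]
        counts = np.bincount(flat[nz])[1:]
        bounds = np.concatenate([[0], np.cumsum(counts)])
        w = mask.shape[1]
        fvals = None if frame is None else np.asarray(frame).ravel()
        for k in range(n):
            idx = nz[bounds[k] : bounds[k + 1]]
            pixels = np.stack([idx // w, idx % w], axis=1)
            values = None if fvals is None else fvals[idx].astype(np.int64)
            puddles.append(Puddle(label=k + 1, pixels=pixels, values=values))
    return PuddleSet(labels=labels, puddles=puddles, frame_index=frame_index)


# ---------------------------------------------------------------------------
# Bit packing


def pack_bits(values: np.ndarray, bit_depth: int) -> bytes:
    """Pack unsigned integers at ``bit_depth`` bits each, LSB-first.

    Output is ``ceil(count * bit_depth / 8)`` bytes; :func:`unpack_bits`
    is the exact inverse given the count.
    """
    if not 1 <= bit_depth <= 32:
        raise ValueError("bit_depth must be in 1..32")
    values = np.asarray(values, dtype=np.uint64)
    if values.size == 0:
        return b""
    if int(values.max()) >= (1 << bit_depth):
        raise ValueError(
            f"value {int(values.max())} does not fit in {bit_depth} bits"
        )
    shifts = np.arange(bit_depth, dtype=np.uint64)
    bits = ((values[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    return np.packbits(bits.ravel(), bitorder="little").tobytes()


def unpack_bits(payload: bytes, count: int, bit_depth: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; validates the payload length."""
    expected = (count * bit_depth + 7) // 8
    if len(payload) != expected:
        raise CorruptionError(
            f"packed payload is {len(payload)} bytes, expected {expected} "
            f"for {count} values at {bit_depth} bits"
        )
    if count == 0:
        return np.zeros(0, dtype=np.uint32)
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), bitorder="little")
    bits = bits[: count * bit_depth].reshape(count, bit_depth).astype(np.uint64)
    weights = (np.uint64(1) << np.arange(bit_depth, dtype=np.uint64))
    out = (bits * weights).sum(axis=1)
    return out.astype(np.uint32)


def pack_binary_map(mask: np.ndarray) -> bytes:
    """Row-major 1-bit-per-pixel packing; ceil(H*W/8) bytes."""
    return np.packbits(np.asarray(mask, dtype=bool).ravel(), bitorder="little").tobytes()


def unpack_binary_map(payload: bytes, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    expected = (h * w + 7) // 8
    if len(payload) != expected:
        raise CorruptionError(
            f"binary-map payload is {len(payload)} bytes, expected {expected} for {h}x{w}"
        )
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), bitorder="little")
    return bits[: h * w].reshape(h, w).astype(bool)


# ---------------------------------------------------------------------------
# Per-puddle features


def summarize_puddle(puddle: Puddle, statistic: str = "max") -> int:
    """Summary ADU statistic of one puddle (sum, max, or mean).

    The mean is rounded to the nearest integer so it fits the packed
    integer grid.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if puddle.values is None:
        raise ValueError("puddle carries no ADU values; cannot summarize")
    v = puddle.values
    if v.size == 0:
        raise ValueError("empty puddle")
    if statistic == "sum":
        return int(v.sum())
    if statistic == "max":
        return int(v.max())
    return int(np.rint(v.mean()))


def _round_half_down(x: float) -> int:
    # 0.5 -> 0, 2.25 -> 2, 0.6 -> 1; fixed tie-break used for centroids
    return int(math.ceil(x - 0.5))


def localize_puddle(puddle: Puddle, strategy: str = "max_pixel") -> tuple[int, int]:
    """Reduce a puddle to a single representative pixel (entry-point guess).

    ``max_pixel`` and ``weighted_centroid`` need ADU values (L1-grade
    input); ``unweighted_centroid`` works from the shape alone (L2/L3).
    Centroids are rounded half-down per axis, so a uniform 2x2 square
    maps to its top-left pixel.  Ties in ``max_pixel`` go to the first
    (row-major) maximal pixel.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if puddle.area == 0:
        raise ValueError("empty puddle")
    if strategy == "unweighted_centroid":
        r, c = puddle.pixels.mean(axis=0)
        return _round_half_down(float(r)), _round_half_down(float(c))
    if puddle.values is None:
        raise ValueError(f"strategy {strategy!r} requires ADU values (L1-grade input)")
    if strategy == "max_pixel":
        i = int(np.argmax(puddle.values))  # first max in row-major order
        return int(puddle.pixels[i, 0]), int(puddle.pixels[i, 1])
    total = float(puddle.values.sum())
    if total <= 0:
        r, c = puddle.pixels.mean(axis=0)
    else:
        r, c = (puddle.pixels * puddle.values[:, None]).sum(axis=0) / total
    return _round_half_down(float(r)), _round_half_down(float(c))


def sum_statistic_bit_depth(bit_depth: int) -> int:
    """Packed width of the per-puddle 'sum' statistic.

    A sum over up to ``MAX_SUM_AREA`` pixels of ``bit_depth``-bit values
    needs ``bit_depth + log2(MAX_SUM_AREA)`` bits.
    """
    return bit_depth + int(math.ceil(math.log2(MAX_SUM_AREA)))


def _statistic_bit_depth(statistic: str, bit_depth: int) -> int:
    return sum_statistic_bit_depth(bit_depth) if statistic == "sum" else bit_depth


# ---------------------------------------------------------------------------
# Reduced frames


@dataclass
class ReducedFrame:
    """The packed representation of one reduced frame.

    ``binary_payload`` is the packed binary map (L1-L3) or packed
    localization-pixel map (L4).  ``intensity_payload`` holds bit-packed
    signal-pixel ADUs in row-major mask order (L1) or packed per-puddle
    statistics in label order (L2); it is empty for L3/L4.
    """

    level: int
    shape: tuple[int, int]
    bit_depth: int
    binary_payload: bytes
    intensity_payload: bytes = b""
    n_signal_pixels: int = 0
    n_puddles: int = 0
    statistic: str = "max"
    strategy: str = "max_pixel"
    connectivity: int = 8
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"invalid reduction level {self.level}")
        h, w = self.shape
        expected = (h * w + 7) // 8
        if len(self.binary_payload) != expected:
            raise CorruptionError(
                f"binary payload length {len(self.binary_payload)} != {expected}"
            )
        if self.level in (3, 4) and self.intensity_payload:
            raise CorruptionError("L3/L4 frames carry no intensity payload")

    @property
    def payload_bytes(self) -> int:
        return len(self.binary_payload) + len(self.intensity_payload)


def reduce_frame(
    frame: np.ndarray,
    calib: CalibrationFrame | np.ndarray,
    level: int,
    statistic: str = "max",
    strategy: str = "max_pixel",
    bit_depth: int | None = None,
    connectivity: int = 8,
    frame_index: int = 0,
) -> ReducedFrame:
    """Reduce one dense frame to the requested level.

    L1 stores the thresholded-but-unmodified original ADUs (no dark
    subtraction baked in) so the data can be recalibrated after
    acquisition.  ``bit_depth`` defaults to the input bit depth inferred
    from the threshold map's dtype container (8 or 16).
    """
    if level not in LEVELS:
        raise ValueError(f"invalid reduction level {level}")
    frame = np.asarray(frame)
    if bit_depth is None:
        bit_depth = 8 * frame.dtype.itemsize if frame.dtype.kind == "u" else 16
    bmap = threshold_frame(frame, calib, frame_index=frame_index)
    mask = bmap.mask
    n_signal = int(mask.sum())
    common = dict(
        shape=mask.shape,
        bit_depth=bit_depth,
        statistic=statistic,
        strategy=strategy,
        connectivity=connectivity,
        frame_index=frame_index,
    )
    if level == 1:
        payload = pack_bits(frame[mask].astype(np.uint64), bit_depth)
        return ReducedFrame(
            level=1,
            binary_payload=pack_binary_map(mask),
            intensity_payload=payload,
            n_signal_pixels=n_signal,
            n_puddles=0,
            **common,
        )
    pset = label_components(bmap, connectivity=connectivity, frame=frame)
    if level == 2:
        stats = np.array(
            [summarize_puddle(p, statistic) for p in pset.puddles], dtype=np.uint64
        )
        sbd = _statistic_bit_depth(statistic, bit_depth)
        stats = np.minimum(stats, (1 << sbd) - 1)  # clamp pathological sums
        return ReducedFrame(
            level=2,
            binary_payload=pack_binary_map(mask),
            intensity_payload=pack_bits(stats, sbd),
            n_signal_pixels=n_signal,
            n_puddles=pset.n_puddles,
            **common,
        )
    if level == 3:
        return ReducedFrame(
            level=3,
            binary_payload=pack_binary_map(mask),
            n_signal_pixels=n_signal,
            n_puddles=0,
            **common,
        )
    # L4: one localization pixel per puddle
    loc = np.zeros(mask.shape, dtype=bool)
    for p in pset.puddles:
        r, c = localize_puddle(p, strategy)
        loc[r, c] = True
    return ReducedFrame(
        level=4,
        binary_payload=pack_binary_map(loc),
        n_signal_pixels=int(loc.sum()),
        n_puddles=pset.n_puddles,
        **common,
    )


def expand_frame(reduced: ReducedFrame):
    """Expand a reduced frame back to its level's natural representation.

    Returns a dense sparse frame (L1: ADUs at signal pixels, 0
    elsewhere), ``(BinaryMap, statistics array)`` (L2), a
    :class:`BinaryMap` (L3), or a counted map of localization pixels
    (L4).  Malformed payloads raise :class:`CorruptionError` rather than
    decoding to a silently wrong frame.
    """
    mask = unpack_binary_map(reduced.binary_payload, reduced.shape)
    n_true = int(mask.sum())
    if reduced.level == 1:
        if n_true != reduced.n_signal_pixels:
            raise CorruptionError(
                f"mask holds {n_true} signal pixels but header says {reduced.n_signal_pixels}"
            )
        values = unpack_bits(reduced.intensity_payload, n_true, reduced.bit_depth)
        frame = np.zeros(reduced.shape, dtype=np.uint16 if reduced.bit_depth > 8 else np.uint8)
        frame[mask] = values.astype(frame.dtype)
        return frame
    if reduced.level == 2:
        sbd = _statistic_bit_depth(reduced.statistic, reduced.bit_depth)
        stats = unpack_bits(reduced.intensity_payload, reduced.n_puddles, sbd)
        return BinaryMap(mask, frame_index=reduced.frame_index), stats
    if reduced.level == 3:
        return BinaryMap(mask, frame_index=reduced.frame_index)
    # L4: counted map (one count per localization pixel)
    if n_true != reduced.n_signal_pixels:
        raise CorruptionError(
            f"L4 map holds {n_true} pixels but header says {reduced.n_signal_pixels}"
        )
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Centroid encodings

CENTROID_MODES = ("linear_index", "rle", "binary_image")


def _coord_bits(shape: tuple[int, int]) -> int:
    # per-coordinate width: enough bits for the larger dimension, min 8
    return max(8, int(math.ceil(math.log2(max(shape)))) if max(shape) > 1 else 1)


def _check_centroids(centroids: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    centroids = np.asarray(centroids, dtype=np.int64).reshape(-1, 2)
    if centroids.size:
        h, w = shape
        if (
            centroids.min() < 0
            or centroids[:, 0].max() >= h
            or centroids[:, 1].max() >= w
        ):
            raise ValueError("centroid outside frame bounds")
    # merge duplicates, sort by linear index for a canonical payload
    lin = np.unique(centroids[:, 0] * shape[1] + centroids[:, 1])
    return lin


def encode_centroids(centroids: np.ndarray, shape: tuple[int, int], mode: str = "binary_image") -> bytes:
    """Encode a set of centroid pixels in one of three interchangeable forms.

    ``linear_index`` packs each centroid as a 2n-bit row/col pair
    (n = per-coordinate bit width, at least 8); ``rle`` stores the
    zero-run lengths between successive centroids of the sorted
    linearized map; ``binary_image`` packs the centroid map like an L4
    binary frame.  The binary image form is the container default - it
    avoids the sort that RLE needs.
    """
    if mode not in CENTROID_MODES:
        raise ValueError(f"unknown centroid mode {mode!r}")
    lin = _check_centroids(centroids, shape)
    if mode == "binary_image":
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[lin] = True
        return pack_binary_map(mask)
    if lin.size == 0:
        return b""
    if mode == "linear_index":
        n = _coord_bits(shape)
        rows, cols = lin // shape[1], lin % shape[1]
        packed = (rows.astype(np.uint64) << np.uint64(n)) | cols.astype(np.uint64)
        return pack_bits(packed, 2 * n)
    # rle: first index, then gaps (zeros between consecutive centroids)
    runs = np.concatenate([[lin[0]], np.diff(lin) - 1]).astype(np.uint64)
    width = max(1, int(runs.max()).bit_length())
    return bytes([width]) + pack_bits(runs, width)


def decode_centroids(payload: bytes, shape: tuple[int, int], mode: str, count: int | None = None) -> np.ndarray:
    """Decode any centroid encoding back to a sorted (row, col) array."""
    if mode not in CENTROID_MODES:
        raise ValueError(f"unknown centroid mode {mode!r}")
    if mode == "binary_image":
        mask = unpack_binary_map(payload, shape)
        lin = np.flatnonzero(mask.ravel())
    elif len(payload) == 0:
        lin = np.zeros(0, dtype=np.int64)
    elif mode == "linear_index":
        n = _coord_bits(shape)
        if count is None:
            count = len(payload) * 8 // (2 * n)
        packed = unpack_bits(payload, count, 2 * n).astype(np.int64)
        rows, cols = packed >> n, packed & ((1 << n) - 1)
        lin = rows * shape[1] + cols
    else:  # rle
        width = payload[0]
        body = payload[1:]
        if count is None:
            count = len(body) * 8 // width
        runs = unpack_bits(body, count, width).astype(np.int64)
        lin = np.cumsum(runs + 1) - 1
    lin = np.sort(lin)
    return np.stack([lin // shape[1], lin % shape[1]], axis=1)
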