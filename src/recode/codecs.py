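"""Pluggable lossless codec layer for reduced-frame payloads.

Binary maps and packed intensity payloads are compressed independently,
each through one of six general-purpose lossless algorithms at one of
two internal optimization extremes ("optimal_speed" = the library's
fastest preset, "optimal_compression" = its strongest).  An optional
bitshuffle prefilter transposes the bit matrix of fixed-size chunks
before compression, which groups slowly-varying high-order bits into
long runs; it never changes decompressed content.

Deflate at its fastest level ("Deflate-1") is the package default.

Compressed blocks are self-describing: a 1-byte spec id plus the
uncompressed length precede the stream, so any block can be decoded
without out-of-band metadata.  The id registry below is stable; ids
must never be reassigned.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CodecSpec",
    "default_codec",
    "compress_block",
    "decompress_block",
    "CodecFormatError",
    "bitshuffle",
    "bitunshuffle",
    "ALGORITHMS",
    "OPTIMIZATIONS",
    "PREFILTERS",
]

ALGORITHMS = ("deflate", "zstd", "bzip2", "lzma", "lz4", "snappy")
OPTIMIZATIONS = ("optimal_speed", "optimal_compression")
PREFILTERS = ("none", "bitshuffle")

#: stable id registry: algorithm index in bits 0-2, optimization in bit 3,
#: prefilter in bit 4
_ALG_ID = {a: i for i, a in enumerate(ALGORITHMS)}
_ID_ALG = {i: a for a, i in _ALG_ID.items()}

DEFAULT_CHUNK_SIZE = 1 << 16  # bitshuffle chunk; sized for small caches


class CodecFormatError(ValueError):
    """Unknown codec id or malformed block framing."""


def _pyarrow():
    try:
        import pyarrow
    except ImportError as exc:  # pragma: no cover - pyarrow is a hard dep
        raise CodecFormatError(
            "zstd/lz4/snappy need pyarrow, which is not importable"
        ) from exc
    return pyarrow


@dataclass(frozen=True)
class CodecSpec:
    """One codec configuration: algorithm, optimization extreme, prefilter."""

    algorithm: str = "deflate"
    optimization: str = "optimal_speed"
    prefilter: str = "none"
    chunk_size: int = DEFAULT_CHUNK_SIZE

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")
        if self.optimization not in OPTIMIZATIONS:
            raise ValueError(f"unknown optimization {self.optimization!r}")
        if self.prefilter not in PREFILTERS:
            raise ValueError(f"unknown prefilter {self.prefilter!r}")
        if self.prefilter == "bitshuffle" and self.chunk_size <= 0:
            raise ValueError("chunk_size must be positive when the prefilter is active")
        if self.algorithm in ("zstd", "lz4", "snappy"):
            pa = _pyarrow()
            name = "lz4_frame" if self.algorithm == "lz4" else self.algorithm
            if not pa.Codec.is_available(name):  # fail loudly at construction
                raise ValueError(f"codec {self.algorithm!r} unavailable in this build")

    @property
    def spec_id(self) -> int:
        return (
            _ALG_ID[self.algorithm]
            | (OPTIMIZATIONS.index(self.optimization) << 3)
            | (PREFILTERS.index(self.prefilter) << 4)
        )

    @classmethod
    def from_spec_id(cls, spec_id: int, chunk_size: int = DEFAULT_CHUNK_SIZE) -> "CodecSpec":
        alg = _ID_ALG.get(spec_id & 0b111)
        if alg is None or spec_id >> 5:
            raise CodecFormatError(f"unknown codec id {spec_id}")
        return cls(
            algorithm=alg,
            optimization=OPTIMIZATIONS[(spec_id >> 3) & 1],
            prefilter=PREFILTERS[(spec_id >> 4) & 1],
            chunk_size=chunk_size,
        )


def default_codec() -> CodecSpec:
    """Deflate at its fastest internal level, no prefilter ("Deflate-1")."""
    return CodecSpec("deflate", "optimal_speed", "none")


# ---------------------------------------------------------------------------
# bitshuffle prefilter


def _shuffle_chunk(chunk: np.ndarray) -> np.ndarray:
    bits = np.unpackbits(chunk, bitorder="little").reshape(chunk.size, 8)
    return np.packbits(bits.T.ravel(), bitorder="little")


def bitshuffle(payload: bytes, chunk_size: int = DEFAULT_CHUNK_SIZE) -> bytes:
    """Bit-transpose each chunk: bit k of every byte becomes contiguous."""
    data = np.frombuffer(payload, dtype=np.uint8)
    out = []
    for start in range(0, data.size, chunk_size):
        out.append(_shuffle_chunk(data[start : start + chunk_size]).tobytes())
    return b"".join(out)


def bitunshuffle(payload: bytes, chunk_size: int = DEFAULT_CHUNK_SIZE) -> bytes:
    """Exact inverse of :func:`bitshuffle` for the same chunk size."""
    data = np.frombuffer(payload, dtype=np.uint8)
    out = []
    for start in range(0, data.size, chunk_size):
        chunk = data[start : start + chunk_size]
        bits = np.unpackbits(chunk, bitorder="little").reshape(8, chunk.size)
        out.append(np.packbits(bits.T.ravel(), bitorder="little").tobytes())
    return b"".join(out)


# ---------------------------------------------------------------------------
# algorithm backends


def _compress_raw(data: bytes, spec: CodecSpec) -> bytes:
    fast = spec.optimization == "optimal_speed"
    if spec.algorithm == "deflate":
        return zlib.compress(data, level=1 if fast else 9)
    if spec.algorithm == "bzip2":
        return bz2.compress(data, compresslevel=1 if fast else 9)
    if spec.algorithm == "lzma":
        return lzma.compress(data, preset=0 if fast else 9)
    pa = _pyarrow()
    if spec.algorithm == "zstd":
        codec = pa.Codec("zstd", compression_level=1 if fast else pa.Codec.maximum_compression_level("zstd"))
    elif spec.algorithm == "lz4":
        codec = pa.Codec("lz4", compression_level=1 if fast else pa.Codec.maximum_compression_level("lz4"))
    else:  # snappy exposes no optimization levels; both extremes coincide
        codec = pa.Codec("snappy")
    return codec.compress(data, asbytes=True)


def _decompress_raw(data: bytes, spec: CodecSpec, size: int) -> bytes:
    try:
        if spec.algorithm == "deflate":
            return zlib.decompress(data)
        if spec.algorithm == "bzip2":
            return bz2.decompress(data)
        if spec.algorithm == "lzma":
            return lzma.decompress(data)
        pa = _pyarrow()
        name = "lz4" if spec.algorithm == "lz4" else spec.algorithm
        return pa.Codec(name).decompress(data, decompressed_size=size, asbytes=True)
    except CodecFormatError:
        raise
    except Exception as exc:
        raise CodecFormatError(f"corrupted {spec.algorithm} stream: {exc}") from exc


# ---------------------------------------------------------------------------
# block framing: [id u8 | uncompressed length u32 LE | stream]


def compress_block(payload: bytes, spec: CodecSpec) -> bytes:
    """Compress one payload into a self-describing block.

    An empty payload encodes as a zero-length block.
    """
    if len(payload) == 0:
        return b""
    if spec.prefilter == "bitshuffle":
        payload = bitshuffle(payload, spec.chunk_size)
    stream = _compress_raw(payload, spec)
    header = bytes([spec.spec_id]) + len(payload).to_bytes(4, "little")
    if spec.prefilter == "bitshuffle":
        header += spec.chunk_size.to_bytes(4, "little")
    return header + stream


def decompress_block(block: bytes) -> bytes:
    """Decode a block written by :func:`compress_block`."""
    if len(block) == 0:
        return b""
    if len(block) < 5:
        raise CodecFormatError("block shorter than its header")
    spec = CodecSpec.from_spec_id(block[0])
    size = int.from_bytes(block[1:5], "little")
    offset = 5
    chunk_size = DEFAULT_CHUNK_SIZE
    if spec.prefilter == "bitshuffle":
        if len(block) < 9:
            raise CodecFormatError("bitshuffle block missing chunk size")
        chunk_size = int.from_bytes(block[5:9], "little")
        offset = 9
    payload = _decompress_raw(block[offset:], spec, size)
    if len(payload) != size:
        raise CodecFormatError(
            f"decompressed {len(payload)} bytes but block promised {size}"
        )
    if spec.prefilter == "bitshuffle":
        payload = bitunshuffle(payload, chunk_size)
    return payload
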