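"""The on-disk container: header + per-frame records + footer index.

Layout (all little-endian):

* fixed 512-byte header: magic, version, reduction level, codec id,
  frame geometry, bit depth, statistic/strategy/connectivity codes,
  frame count (patched at finalize), frame rate, calibration checksum,
  footer offset (0 while unfinalized);
* per-frame records, append-only:
  ``frame_number u64 | timestamp u64 | len_binary u32 | len_intensity u32 |
  n_signal u32 | n_puddles u32 | flags u8 | crc_binary u32 |
  crc_intensity u32 | len_raw u32 | payloads``
  where the binary/intensity payloads are independently compressed
  blocks and an optional verbatim raw frame follows when flag bit 0 is
  set (raw frames retained at intervals for validation/recalibration);
* a footer appended at finalize: ``n_frames u64`` then per frame
  ``frame_number u64 | record offset u64``, giving O(1) random access.

Part files written by independent workers are identical but footer-less
(their index is rebuilt by scanning); merging copies compressed record
bytes verbatim into frame-number order and writes a finalized header
and footer.  Per-payload CRC-32 checksums catch truncation and bit rot.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codecs import CodecSpec, compress_block, decompress_block
from .reduction import (
    STATISTICS,
    STRATEGIES,
    CorruptionError,
    ReducedFrame,
)

__all__ = [
    "ContainerHeader",
    "FrameRecord",
    "RecodeWriter",
    "RecodeContainer",
    "write_reduced",
    "merge_parts",
    "extension_for_level",
]

MAGIC = b"RECODE01"
VERSION = 1
HEADER_BYTES = 512
_HEADER_FMT = "<8sHBBBBBBIIQQdIQ"  # through footer_offset; rest reserved
_RECORD_FIXED = struct.Struct("<QQIIIIBIII")
FLAG_RAW = 0x01


def extension_for_level(level: int) -> str:
    return f".rc{level}"


@dataclass
class ContainerHeader:
    level: int
    height: int
    width: int
    bit_depth: int
    codec: CodecSpec
    statistic: str = "max"
    strategy: str = "max_pixel"
    connectivity: int = 8
    n_frames: int = 0
    frame_rate: float = 0.0
    calibration_checksum: int = 0
    footer_offset: int = 0
    finalized: bool = False

    def compatible_with(self, other: "ContainerHeader") -> bool:
        return (
            self.level == other.level
            and self.height == other.height
            and self.width == other.width
            and self.bit_depth == other.bit_depth
            and self.codec == other.codec
            and self.statistic == other.statistic
            and self.strategy == other.strategy
            and self.connectivity == other.connectivity
        )

    def pack(self) -> bytes:
        body = struct.pack(
            _HEADER_FMT,
            MAGIC,
            VERSION,
            self.level,
            self.codec.spec_id,
            self.bit_depth,
            STATISTICS.index(self.statistic),
            STRATEGIES.index(self.strategy),
            self.connectivity,
            self.height,
            self.width,
            self.n_frames,
            self.footer_offset,
            self.frame_rate,
            self.calibration_checksum,
            int(self.finalized),
        )
        return body.ljust(HEADER_BYTES, b"\0")

    @classmethod
    def unpack(cls, raw: bytes) -> "ContainerHeader":
        if len(raw) < HEADER_BYTES:
            raise CorruptionError("file shorter than container header")
        (
            magic,
            version,
            level,
            codec_id,
            bit_depth,
            stat_i,
            strat_i,
            connectivity,
            height,
            width,
            n_frames,
            footer_offset,
            frame_rate,
            calib_crc,
            finalized,
        ) = struct.unpack_from(_HEADER_FMT, raw, 0)
        if magic != MAGIC:
            raise CorruptionError("not a recode container (bad magic)")
        if version != VERSION:
            raise CorruptionError(f"unsupported container version {version}")
        return cls(
            level=level,
            height=height,
            width=width,
            bit_depth=bit_depth,
            codec=CodecSpec.from_spec_id(codec_id),
            statistic=STATISTICS[stat_i],
            strategy=STRATEGIES[strat_i],
            connectivity=connectivity,
            n_frames=n_frames,
            frame_rate=frame_rate,
            calibration_checksum=calib_crc,
            footer_offset=footer_offset,
            finalized=bool(finalized),
        )


@dataclass
class FrameRecord:
    """One decoded record: a reduced frame, optionally plus its raw frame."""

    frame_number: int
    timestamp: int
    reduced: ReducedFrame
    raw: np.ndarray | None = None

    @property
    def is_raw_retained(self) -> bool:
        return self.raw is not None


class RecodeWriter:
    """Append-only writer for containers and worker part files.

    Call :meth:`append` with frames in increasing frame-number order,
    then :meth:`finalize` (merged/standalone files) or :meth:`close_part`
    (footer-less intermediate files).
    """

    def __init__(self, path: str | Path, header: ContainerHeader):
        self.path = Path(path)
        self.header = header
        self._fh = open(self.path, "wb")
        self._fh.write(header.pack())
        self._index: list[tuple[int, int]] = []  # (frame_number, offset)
        self._last_frame = -1

    def append(
        self,
        reduced: ReducedFrame,
        frame_number: int | None = None,
        timestamp: int | None = None,
        raw: np.ndarray | None = None,
    ) -> None:
        h = self.header
        if reduced.level != h.level:
            raise ValueError(f"mixed reduction levels: {reduced.level} vs {h.level}")
        if reduced.shape != (h.height, h.width):
            raise ValueError("frame shape differs from container header")
        if frame_number is None:
            frame_number = reduced.frame_index
        if frame_number <= self._last_frame:
            raise ValueError("frame numbers within a file must be strictly increasing")
        if timestamp is None:
            timestamp = frame_number
        binary = compress_block(reduced.binary_payload, h.codec)
        intensity = compress_block(reduced.intensity_payload, h.codec)
        flags = 0
        raw_bytes = b""
        if raw is not None:
            raw_arr = np.ascontiguousarray(raw)
            if raw_arr.shape != (h.height, h.width):
                raise ValueError("raw frame shape differs from container header")
            raw_bytes = raw_arr.astype(raw_arr.dtype.newbyteorder("<")).tobytes()
            flags |= FLAG_RAW
        rec = _RECORD_FIXED.pack(
            frame_number,
            timestamp,
            len(binary),
            len(intensity),
            reduced.n_signal_pixels,
            reduced.n_puddles,
            flags,
            zlib.crc32(binary),
            zlib.crc32(intensity),
            len(raw_bytes),
        )
        offset = self._fh.tell()
        self._fh.write(rec)
        self._fh.write(binary)
        self._fh.write(intensity)
        self._fh.write(raw_bytes)
        self._index.append((frame_number, offset))
        self._last_frame = frame_number

    def _patch_header(self) -> None:
        self._fh.seek(0)
        self._fh.write(self.header.pack())

    def finalize(self) -> Path:
        """Write the footer index and a finalized header."""
        footer_offset = self._fh.tell()
        self._fh.write(struct.pack("<Q", len(self._index)))
        for frame_number, offset in self._index:
            self._fh.write(struct.pack("<QQ", frame_number, offset))
        self.header.n_frames = len(self._index)
        self.header.footer_offset = footer_offset
        self.header.finalized = True
        self._patch_header()
        self._fh.close()
        return self.path

    def close_part(self) -> Path:
        """Close a footer-less intermediate (part) file."""
        self.header.n_frames = len(self._index)
        self.header.finalized = False
        self._patch_header()
        self._fh.close()
        return self.path


class RecodeContainer:
    """Reader with sequential iteration and O(1) random access."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = open(self.path, "rb")
        self.header = ContainerHeader.unpack(self._fh.read(HEADER_BYTES))
        if self.header.finalized and self.header.footer_offset:
            self._index = self._read_footer()
        else:
            self._index = self._scan_records()
        self._by_number = {fn: off for fn, off in self._index}

    # -- index construction ------------------------------------------------
    def _read_footer(self) -> list[tuple[int, int]]:
        self._fh.seek(self.header.footer_offset)
        raw = self._fh.read()
        if len(raw) < 8:
            raise CorruptionError("missing footer")
        (n,) = struct.unpack_from("<Q", raw, 0)
        if len(raw) < 8 + 16 * n:
            raise CorruptionError("footer shorter than its frame count")
        return [
            struct.unpack_from("<QQ", raw, 8 + 16 * i) for i in range(n)
        ]

    def _scan_records(self) -> list[tuple[int, int]]:
        index = []
        offset = HEADER_BYTES
        end = self.path.stat().st_size
        stop = self.header.footer_offset or end
        while offset < stop:
            self._fh.seek(offset)
            fixed = self._fh.read(_RECORD_FIXED.size)
            if len(fixed) < _RECORD_FIXED.size:
                raise CorruptionError(f"truncated record header at byte {offset}")
            fn, _, lb, li, _, _, _, _, _, lr = _RECORD_FIXED.unpack(fixed)
            rec_len = _RECORD_FIXED.size + lb + li + lr
            if offset + rec_len > stop:
                raise CorruptionError(f"truncated record payload for frame {fn}")
            index.append((fn, offset))
            offset += rec_len
        return index

    # -- access ------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self._index)

    @property
    def frame_numbers(self) -> list[int]:
        return [fn for fn, _ in self._index]

    def _read_record_at(self, offset: int, verify: bool = True) -> FrameRecord:
        self._fh.seek(offset)
        fixed = self._fh.read(_RECORD_FIXED.size)
        if len(fixed) < _RECORD_FIXED.size:
            raise CorruptionError(f"truncated record header at byte {offset}")
        fn, ts, lb, li, n_signal, n_puddles, flags, crc_b, crc_i, lr = _RECORD_FIXED.unpack(fixed)
        payload = self._fh.read(lb + li + lr)
        if len(payload) < lb + li + lr:
            raise CorruptionError(f"truncated payload for frame {fn}")
        binary, intensity, raw_bytes = (
            payload[:lb],
            payload[lb : lb + li],
            payload[lb + li :],
        )
        if verify and (zlib.crc32(binary) != crc_b or zlib.crc32(intensity) != crc_i):
            raise CorruptionError(f"checksum mismatch in frame {fn}")
        h = self.header
        reduced = ReducedFrame(
            level=h.level,
            shape=(h.height, h.width),
            bit_depth=h.bit_depth,
            binary_payload=decompress_block(binary),
            intensity_payload=decompress_block(intensity),
            n_signal_pixels=n_signal,
            n_puddles=n_puddles,
            statistic=h.statistic,
            strategy=h.strategy,
            connectivity=h.connectivity,
            frame_index=fn,
        )
        raw = None
        if flags & FLAG_RAW:
            dtype = np.dtype(np.uint16 if h.bit_depth > 8 else np.uint8).newbyteorder("<")
            if lr != h.height * h.width * dtype.itemsize:
                raise CorruptionError(f"raw payload length mismatch in frame {fn}")
            raw = np.frombuffer(raw_bytes, dtype=dtype).reshape(h.height, h.width)
            raw = raw.astype(dtype.newbyteorder("="))
        return FrameRecord(frame_number=fn, timestamp=ts, reduced=reduced, raw=raw)

    def read_frame(self, frame_number: int) -> FrameRecord:
        """Random access by frame number; reads only that frame's record."""
        off = self._by_number.get(frame_number)
        if off is None:
            raise IndexError(f"frame {frame_number} not in container")
        return self._read_record_at(off)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for _, off in self._index:
            yield self._read_record_at(off)

    def raw_record_bytes(self, frame_number: int) -> bytes:
        """The verbatim on-disk bytes of one record (used by merge)."""
        off = self._by_number[frame_number]
        self._fh.seek(off)
        fixed = self._fh.read(_RECORD_FIXED.size)
        fn, _, lb, li, _, _, _, _, _, lr = _RECORD_FIXED.unpack(fixed)
        return fixed + self._fh.read(lb + li + lr)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_reduced(
    frames,
    codec: CodecSpec,
    path: str | Path,
    raw_retention_interval: int = 0,
    raw_source=None,
    frame_rate: float = 0.0,
    timestamps=None,
    finalize: bool = True,
) -> Path:
    """Write a stream of :class:`ReducedFrame` to one container file.

    All frames must share level/shape/bit depth.  With a positive
    ``raw_retention_interval`` and a ``raw_source`` (indexable by frame
    number), every interval-th frame also stores its verbatim raw frame.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    if any(f.level != first.level for f in frames):
        raise ValueError("mixed reduction levels in one container")
    header = ContainerHeader(
        level=first.level,
        height=first.shape[0],
        width=first.shape[1],
        bit_depth=first.bit_depth,
        codec=codec,
        statistic=first.statistic,
        strategy=first.strategy,
        connectivity=first.connectivity,
        frame_rate=frame_rate,
    )
    writer = RecodeWriter(path, header)
    for i, f in enumerate(frames):
        raw = None
        if raw_retention_interval and raw_source is not None and f.frame_index % raw_retention_interval == 0:
            raw = raw_source[f.frame_index]
        ts = None if timestamps is None else timestamps[i]
        writer.append(f, frame_number=f.frame_index, timestamp=ts, raw=raw)
    return writer.finalize() if finalize else writer.close_part()


def merge_parts(part_paths, out_path: str | Path) -> Path:
    """Merge worker part files into one time-ordered finalized container.

    Compressed record bytes are copied verbatim (no re-compression).
    Parts must share header parameters; the union of their frame
    numbers must cover 0..N-1 exactly once - duplicates and gaps are
    rejected with an explicit listing.
    """
    parts = [RecodeContainer(p) for p in part_paths]
    if not parts:
        raise ValueError("no part files to merge")
    try:
        head = parts[0].header
        for p in parts[1:]:
            if not head.compatible_with(p.header):
                raise ValueError(f"header mismatch between {parts[0].path} and {p.path}")
        owner: dict[int, RecodeContainer] = {}
        dupes = set()
        for p in parts:
            for fn in p.frame_numbers:
                if fn in owner:
                    dupes.add(fn)
                owner[fn] = p
        if dupes:
            raise ValueError(f"duplicate frame numbers across parts: {sorted(dupes)[:20]}")
        n = (max(owner) + 1) if owner else 0
        missing = sorted(set(range(n)) - set(owner))
        if missing:
            raise ValueError(f"missing frame numbers (gaps): {missing[:20]}")
        out_header = ContainerHeader(
            level=head.level,
            height=head.height,
            width=head.width,
            bit_depth=head.bit_depth,
            codec=head.codec,
            statistic=head.statistic,
            strategy=head.strategy,
            connectivity=head.connectivity,
            frame_rate=head.frame_rate,
            calibration_checksum=head.calibration_checksum,
        )
        out_path = Path(out_path)
        with open(out_path, "wb") as fh:
            fh.write(out_header.pack())
            index = []
            for fn in range(n):
                index.append((fn, fh.tell()))
                fh.write(owner[fn].raw_record_bytes(fn))
            footer_offset = fh.tell()
            fh.write(struct.pack("<Q", n))
            for fn, off in index:
                fh.write(struct.pack("<QQ", fn, off))
            out_header.n_frames = n
            out_header.footer_offset = footer_offset
            out_header.finalized = True
            fh.seek(0)
            fh.write(out_header.pack())
    finally:
        for p in parts:
            p.close()
    return out_path
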