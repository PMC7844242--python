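"""Dense-frame I/O: raw binary frame sequences, MRC/MRCS stacks, TIFF maps.

Detector movies arrive either as headerless raw frame sequences (the
"sequence file" style written by acquisition software, little-endian,
frame-sequential, optionally preceded by a fixed-size file header) or as
MRC2014 stacks.  Calibration maps (per-pixel thresholds, dark levels,
gains) travel as single-page float TIFFs.

Conventions used throughout the package: 0-based indices, row-major
(row, col) pixel coordinates, frame index 0 = first acquired frame.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "read_frame_stack",
    "read_raw_sequence",
    "read_mrc",
    "write_mrc",
    "write_raw_sequence",
    "read_calibration_tiff",
    "write_calibration_tiff",
]

_ALLOWED_DTYPES = {np.dtype(np.uint8), np.dtype(np.uint16)}


@dataclass
class FrameStack:
    """A dense movie cube of unsigned-integer detector frames.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Unsigned-integer pixel values, acquisition order.
    bit_depth : int
        Declared bits per pixel (1-16); every value must be < 2**bit_depth.
    frame_rate : float, optional
        Frames per second, if known.
    source : str
        Provenance string (file path, simulator settings, ...).
    """

    frames: np.ndarray
    bit_depth: int
    frame_rate: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (n_frames, height, width)")
        if self.frames.dtype not in _ALLOWED_DTYPES:
            raise ValueError(f"unsupported dtype {self.frames.dtype}; expected uint8/uint16")
        if not 1 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in 1..16")
        if self.frames.size and int(self.frames.max()) >= (1 << self.bit_depth):
            raise ValueError(
                f"pixel value {int(self.frames.max())} exceeds declared bit depth {self.bit_depth}"
            )
        n, h, w = self.frames.shape
        if n < 1 or h < 1 or w < 1:
            raise ValueError("empty frame stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def _dtype_for_bit_depth(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth <= 8 else np.dtype(np.uint16)


# ---------------------------------------------------------------------------
# Raw binary frame sequences


def read_raw_sequence(
    path: str | Path,
    height: int,
    width: int,
    dtype: np.dtype | str = np.uint16,
    bit_depth: int | None = None,
    header_skip: int = 0,
    frame_rate: float | None = None,
) -> FrameStack:
    """Read a headerless little-endian frame-sequential raw file.

    ``header_skip`` bytes at the start of the file are ignored, which
    accommodates sequence-file dialects with a fixed-size file header.
    The remaining byte count must be an exact multiple of one frame.
    """
    dtype = np.dtype(dtype)
    if dtype.kind != "u" or dtype.itemsize > 2:
        raise ValueError(f"unsupported raw dtype {dtype}; expected uint8/uint16")
    dtype = dtype.newbyteorder("<")
    path = Path(path)
    data = path.read_bytes()[header_skip:]
    frame_bytes = height * width * dtype.itemsize
    if frame_bytes == 0:
        raise ValueError("zero-sized frame")
    if len(data) == 0 or len(data) % frame_bytes != 0:
        raise ValueError(
            f"truncated stack: {len(data)} payload bytes is not a positive multiple "
            f"of the {frame_bytes}-byte frame size"
        )
    n_frames = len(data) // frame_bytes
    frames = np.frombuffer(data, dtype=dtype).reshape(n_frames, height, width)
    frames = frames.astype(dtype.newbyteorder("="))
    if bit_depth is None:
        bit_depth = 8 * dtype.itemsize
    return FrameStack(frames, bit_depth=bit_depth, frame_rate=frame_rate, source=str(path))


def write_raw_sequence(stack: FrameStack, path: str | Path) -> Path:
    """Write frames as a headerless little-endian raw sequence."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(stack.frames, dtype=stack.frames.dtype.newbyteorder("<")).tobytes())
    return path


# ---------------------------------------------------------------------------
# MRC2014 (modes 0, 1, 2, 6)

_MRC_HEADER_BYTES = 1024
_MODE_TO_DTYPE = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}
_DTYPE_TO_MODE = {v: k for k, v in _MODE_TO_DTYPE.items()}


def _build_mrc_header(nx: int, ny: int, nz: int, mode: int, dmin: float, dmax: float, dmean: float, rms: float) -> bytes:
    h = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", h, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    # cell dimensions (Å) default to pixel counts; 90° angles
    struct.pack_into("<6f", h, 40, float(nx), float(ny), float(nz), 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", h, 76, dmin, dmax, dmean)
    struct.pack_into("<i", h, 88, 0)  # ispg = 0 -> image stack
    struct.pack_into("<i", h, 92, 0)  # nsymbt
    h[208:212] = b"MAP "
    h[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", h, 216, rms)
    struct.pack_into("<i", h, 220, 1)  # nlabl
    label = b"recode: reduced electron-counting toolkit"
    h[224 : 224 + len(label)] = label
    return bytes(h)


def write_mrc(data: FrameStack | np.ndarray, path: str | Path, mode: int | None = None) -> Path:
    """Write a frame stack or a single 2-D image as an MRC2014 file.

    The MRC mode is chosen from the array dtype unless given explicitly
    (0=int8, 1=int16, 2=float32, 6=uint16).  Values that do not fit the
    chosen mode are rejected rather than silently wrapped.
    """
    if isinstance(data, FrameStack):
        arr = data.frames
    else:
        arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    if mode is None:
        if arr.dtype in _DTYPE_TO_MODE:
            mode = _DTYPE_TO_MODE[arr.dtype]
        elif np.issubdtype(arr.dtype, np.unsignedinteger):
            mode = 6
        elif np.issubdtype(arr.dtype, np.signedinteger):
            mode = 1
        else:
            mode = 2
    if mode not in _MODE_TO_DTYPE:
        raise ValueError(f"unsupported MRC mode {mode}")
    target = _MODE_TO_DTYPE[mode]
    if np.issubdtype(target, np.integer) and arr.size:
        info = np.iinfo(target)
        lo, hi = int(arr.min()), int(arr.max())
        if lo < info.min or hi > info.max:
            raise ValueError(f"values [{lo}, {hi}] overflow MRC mode {mode} ({target})")
    out = np.ascontiguousarray(arr.astype(target.newbyteorder("<"), copy=False))
    nz, ny, nx = out.shape
    if arr.size:
        dmin, dmax = float(arr.min()), float(arr.max())
        dmean, rms = float(arr.mean()), float(arr.std())
    else:  # pragma: no cover - empty stacks rejected upstream
        dmin = dmax = dmean = rms = 0.0
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_build_mrc_header(nx, ny, nz, mode, dmin, dmax, dmean, rms))
        fh.write(out.tobytes())
    return path


def read_mrc(path: str | Path, bit_depth: int | None = None) -> FrameStack:
    """Read an MRC2014 stack (modes 0/1/2/6) into a :class:`FrameStack`.

    Integer modes map onto the unsigned containers the rest of the
    package expects; negative values are rejected.  Mode 2 (float) is
    rejected because reduction operates on integer ADUs.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise ValueError("truncated stack: file smaller than MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MODE_TO_DTYPE:
        raise ValueError(f"unsupported MRC mode {mode}")
    if mode == 2:
        raise ValueError("float MRC (mode 2) is not a valid detector frame stack")
    dtype = _MODE_TO_DTYPE[mode].newbyteorder("<")
    offset = _MRC_HEADER_BYTES + nsymbt
    need = nx * ny * nz * dtype.itemsize
    payload = raw[offset : offset + need]
    if len(payload) != need:
        raise ValueError("truncated stack: MRC data section shorter than header promises")
    arr = np.frombuffer(payload, dtype=dtype).reshape(nz, ny, nx)
    if mode in (0, 1) and arr.size and int(arr.min()) < 0:
        raise ValueError("negative pixel values cannot be represented as detector ADUs")
    arr = arr.astype(np.uint8 if mode == 0 else np.uint16)
    if bit_depth is None:
        bit_depth = 8 if mode == 0 else 16
    return FrameStack(arr, bit_depth=bit_depth, source=str(path))


def read_frame_stack(
    path: str | Path,
    layout: str = "mrc",
    *,
    height: int | None = None,
    width: int | None = None,
    dtype: np.dtype | str = np.uint16,
    bit_depth: int | None = None,
    header_skip: int = 0,
) -> FrameStack:
    """Read a dense frame stack; ``layout`` selects ``"raw"`` or ``"mrc"``.

    Raw layout requires explicit ``height``/``width``/``dtype``; frames are
    returned in acquisition order with pixel values untouched.
    """
    if layout == "mrc":
        return read_mrc(path, bit_depth=bit_depth)
    if layout == "raw":
        if height is None or width is None:
            raise ValueError("raw layout requires height and width")
        return read_raw_sequence(
            path, height, width, dtype=dtype, bit_depth=bit_depth, header_skip=header_skip
        )
    raise ValueError(f"unknown layout {layout!r}; expected 'raw' or 'mrc'")


# ---------------------------------------------------------------------------
# Calibration maps (single-page float32 TIFF)


def write_calibration_tiff(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_calibration_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError("calibration TIFF must be a single 2-D page")
    return arr.astype(np.float32)
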