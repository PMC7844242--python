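"""Chunked multi-worker reduce-compress-write orchestration.

Frames are cut into contiguous chunks which are dealt round-robin to
workers; each worker reduces, compresses and appends its chunks to its
own intermediate ("part") file, and the parts are merged into one
time-ordered container when the stream ends.  Workers share nothing but
the read-only source; the merged container's decoded content is a pure
function of the frames, the calibration timeline and the reduction
settings - worker count and chunk size never change it.

The per-pixel threshold frame can be reloaded at a fixed chunk
interval, so an external recalibration process may update thresholds
mid-acquisition; chunks after a change use the new thresholds.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationFrame
from .codecs import CodecSpec, default_codec
from .container import (
    ContainerHeader,
    RecodeContainer,
    RecodeWriter,
    merge_parts,
)
from .frame_io import FrameStack, read_calibration_tiff
from .reduction import reduce_frame

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "file_calibration_provider"]

logger = logging.getLogger("recode.pipeline")


@dataclass
class PipelineConfig:
    level: int = 1
    codec: CodecSpec = field(default_factory=default_codec)
    statistic: str = "max"
    strategy: str = "max_pixel"
    connectivity: int = 8
    n_workers: int = 1
    chunk_frames: int = 16
    raw_retention_interval: int = 0  # 0 = keep no raw frames
    calibration_reload_interval: int = 0  # chunks between threshold reloads; 0 = never
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.chunk_frames < 1:
            raise ValueError("chunk_frames must be >= 1")


@dataclass
class RunReport:
    n_frames: int
    n_signal_pixels: int
    n_puddles: int
    bytes_in: int
    bytes_out: int
    part_paths: list[Path]
    reload_boundaries: list[int] = field(default_factory=list)

    @property
    def ratio(self) -> float:
        return self.bytes_in / self.bytes_out if self.bytes_out else float("inf")


def file_calibration_provider(path, reload_interval: int):
    """Calibration timeline that re-reads a threshold TIFF every N chunks.

    A missing or mis-shaped replacement keeps the previous thresholds
    and logs a warning, so acquisition never stalls on a bad update.
    """
    state = {"calib": None, "shape": None}

    def provider(chunk_index: int) -> CalibrationFrame:
        if state["calib"] is None or (
            reload_interval > 0 and chunk_index % reload_interval == 0
        ):
            try:
                thr = read_calibration_tiff(path)
                if state["shape"] is not None and thr.shape != state["shape"]:
                    raise ValueError(
                        f"threshold frame shape {thr.shape} != {state['shape']}"
                    )
                state["calib"] = CalibrationFrame(threshold=thr)
                state["shape"] = thr.shape
                logger.info("thresholds (re)loaded at chunk %d", chunk_index)
            except Exception as exc:
                if state["calib"] is None:
                    raise
                warnings.warn(f"threshold reload failed ({exc}); keeping old thresholds", stacklevel=2)
        return state["calib"]

    return provider


def _resolve_calibration(calibration, cfg: PipelineConfig):
    """Normalize the calibration argument to a chunk-indexed provider."""
    if callable(calibration):
        return calibration
    if isinstance(calibration, (str, Path)):
        return file_calibration_provider(calibration, cfg.calibration_reload_interval)
    if isinstance(calibration, np.ndarray):
        calibration = CalibrationFrame(threshold=calibration)
    fixed = calibration
    return lambda chunk_index: fixed


def run_pipeline(
    source: FrameStack,
    calibration,
    cfg: PipelineConfig,
    out_path: str | Path,
    keep_parts: bool = False,
) -> tuple[RecodeContainer, RunReport]:
    """Reduce, compress and write a frame stack through worker part files.

    ``calibration`` may be a :class:`CalibrationFrame`, a threshold
    array, a TIFF path (reloaded every
    ``cfg.calibration_reload_interval`` chunks), or a callable mapping
    chunk index to a :class:`CalibrationFrame`.  Workers fail loudly:
    a worker exception aborts the run but leaves its part files on disk
    for diagnosis.
    """
    frames = source.frames
    n_frames = frames.shape[0]
    bit_depth = cfg.bit_depth or source.bit_depth
    provider = _resolve_calibration(calibration, cfg)
    chunks = [
        (ci, range(start, min(start + cfg.chunk_frames, n_frames)))
        for ci, start in enumerate(range(0, n_frames, cfg.chunk_frames))
    ]
    # resolve the calibration timeline up-front (chunk order independent
    # of worker scheduling)
    calib_by_chunk = {}
    reload_boundaries = []
    prev = None
    for ci, _ in chunks:
        calib = provider(ci)
        if calib.shape != frames.shape[1:]:
            raise ValueError("calibration shape does not match the source frames")
        calib_by_chunk[ci] = calib
        if prev is not None and calib is not prev:
            reload_boundaries.append(ci)
        prev = calib
    out_path = Path(out_path)
    header_proto = dict(
        level=cfg.level,
        height=frames.shape[1],
        width=frames.shape[2],
        bit_depth=bit_depth,
        codec=cfg.codec,
        statistic=cfg.statistic,
        strategy=cfg.strategy,
        connectivity=cfg.connectivity,
        frame_rate=source.frame_rate or 0.0,
    )
    period_ns = int(1e9 / source.frame_rate) if source.frame_rate else 1
    totals = {"signal": 0, "puddles": 0}

    def work(worker_id: int, my_chunks) -> Path:
        part = out_path.with_suffix(out_path.suffix + f".part{worker_id}")
        writer = RecodeWriter(part, ContainerHeader(**header_proto))
        for ci, frame_range in my_chunks:
            calib = calib_by_chunk[ci]
            for f in frame_range:
                reduced = reduce_frame(
                    frames[f],
                    calib,
                    cfg.level,
                    statistic=cfg.statistic,
                    strategy=cfg.strategy,
                    bit_depth=bit_depth,
                    connectivity=cfg.connectivity,
                    frame_index=f,
                )
                raw = None
                if cfg.raw_retention_interval and f % cfg.raw_retention_interval == 0:
                    raw = frames[f]
                writer.append(reduced, frame_number=f, timestamp=f * period_ns, raw=raw)
                totals["signal"] += reduced.n_signal_pixels
                totals["puddles"] += reduced.n_puddles
            logger.debug("worker %d wrote chunk %d (%d frames)", worker_id, ci, len(frame_range))
        return writer.close_part()

    assignments = [chunks[w :: cfg.n_workers] for w in range(cfg.n_workers)]
    assignments = [a for a in assignments if a]
    part_paths: list[Path] = []
    with ThreadPoolExecutor(max_workers=cfg.n_workers) as pool:
        futures = [pool.submit(work, w, a) for w, a in enumerate(assignments)]
        for fut in futures:
            part_paths.append(fut.result())  # re-raises worker failures
    merge_parts(part_paths, out_path)
    if not keep_parts:
        for p in part_paths:
            p.unlink()
    container = RecodeContainer(out_path)
    report = RunReport(
        n_frames=n_frames,
        n_signal_pixels=totals["signal"],
        n_puddles=totals["puddles"],
        bytes_in=frames.nbytes,
        bytes_out=out_path.stat().st_size,
        part_paths=part_paths,
        reload_boundaries=reload_boundaries,
    )
    logger.info(
        "pipeline done: %d frames, %d signal pixels, ratio %.2f",
        n_frames,
        totals["signal"],
        report.ratio,
    )
    return container, report
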