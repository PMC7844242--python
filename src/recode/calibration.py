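"""Signal/noise calibration: per-pixel thresholds from dark statistics.

The reduction stage needs exactly one input beyond the frames: a
per-pixel ADU threshold separating dark noise from electron signal.  Two
routes produce it here.

The fast ("on-the-fly") route assumes dark values at each pixel are
normally distributed.  A single global threshold is placed at the
(1 - r) quantile of the fitted dark distribution, where r is the
tolerable false-positive rate per pixel per frame (a 3-sigma one-sided
tail by default).  Because pixels differ in dark level and gain, the
global threshold is then shifted to each pixel's dark level and scaled
by its relative gain:

    threshold_p = dark_p + (T_global - dark_global) * gain_p / gain_global

Per-pixel dark levels are medians over a low-dose calibration stack; a
pixel's gain is the median of its N largest dark-subtracted values,
where N is the estimated total dose per pixel in the stack.  N itself is
estimated by counting, in a few randomly placed small patches, the
connected components whose maximum-value pixel sits at the patch center
("a puddle emanates from its maximum pixel").

The fine route adds a common-mode correction (subtracting the correlated
thermal offset of 4x256-pixel readout blocks) and area-based puddle
filtering, and typically uses a stricter tail (4 sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "CalibrationFrame",
    "DoseEstimate",
    "sigma_to_rate",
    "estimate_global_threshold",
    "pixel_dark_levels",
    "pixel_gains",
    "estimate_dose_per_pixel",
    "build_calibration_frame",
    "common_mode_correct",
    "area_filter",
    "calibrate_on_the_fly",
]

DEFAULT_SIGMA = 3.0  # fast calibration tail; fine calibration uses 4.0
DEFAULT_BLOCK_SHAPE = (4, 256)  # correlated readout-block geometry
DEFAULT_N_PATCHES = 64
DEFAULT_PATCH_SIZE = 11


@dataclass
class CalibrationFrame:
    """Per-pixel threshold map with optional dark/gain companions.

    Dead pixels are flagged with a +inf threshold: they can never be
    classified as signal.  ``r`` is the per-pixel false-positive rate
    the thresholds were built for.
    """

    threshold: np.ndarray
    dark_level: np.ndarray | None = None
    gain: np.ndarray | None = None
    r: float | None = None
    n_calibration_frames: int = 0

    def __post_init__(self) -> None:
        self.threshold = np.asarray(self.threshold, dtype=np.float64)
        if self.threshold.ndim != 2:
            raise ValueError("threshold map must be 2-D")
        for name in ("dark_level", "gain"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=np.float64)
                if m.shape != self.threshold.shape:
                    raise ValueError(f"{name} map shape differs from threshold map")
                setattr(self, name, m)
        if self.dark_level is not None:
            live = np.isfinite(self.threshold)
            if np.any(self.threshold[live] < self.dark_level[live]):
                raise ValueError("threshold below dark level at a live pixel")
        if self.r is not None and not 0 < self.r < 0.5:
            raise ValueError("false-positive rate r must lie in (0, 0.5)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.threshold.shape

    @property
    def dead_pixel_mask(self) -> np.ndarray:
        return ~np.isfinite(self.threshold)


@dataclass
class DoseEstimate:
    """Total electrons per pixel over a calibration set (patch average)."""

    dose_per_pixel: float
    n_patches: int
    patch_size: int
    per_patch_counts: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.dose_per_pixel < 0:
            raise ValueError("dose must be non-negative")
        if self.n_patches < 1:
            raise ValueError("need at least one patch")

    @property
    def standard_error(self) -> float:
        c = np.asarray(self.per_patch_counts, dtype=float)
        if c.size < 2:
            return float("nan")
        return float(c.std(ddof=1) / np.sqrt(c.size))


def sigma_to_rate(sigma: float) -> float:
    """One-sided tail probability of a ``sigma``-multiple threshold."""
    return float(stats.norm.sf(sigma))


def estimate_global_threshold(
    dark_values: np.ndarray, r: float, robust: bool = False
) -> float:
    """Threshold at the (1 - r) quantile of the fitted dark normal.

    The fit uses the sample mean and standard deviation (dark histograms
    are taken as normal); ``robust=True`` switches to median and
    MAD-derived sigma for contaminated samples.
    """
    dark_values = np.asarray(dark_values, dtype=np.float64).ravel()
    if dark_values.size < 2:
        raise ValueError("need at least two dark samples")
    if not np.all(np.isfinite(dark_values)):
        raise ValueError("non-finite dark samples")
    if not 0 < r <= 0.5:
        raise ValueError("false-positive rate r must lie in (0, 0.5]")
    if robust:
        mu = float(np.median(dark_values))
        sd = float(stats.median_abs_deviation(dark_values, scale="normal"))
    else:
        mu = float(dark_values.mean())
        sd = float(dark_values.std(ddof=1))
    return mu + sd * float(stats.norm.isf(r))


def pixel_dark_levels(calib_stack, mode: str = "median") -> np.ndarray:
    """Per-pixel dark level over a low-dose stack (median, or faster mean).

    At low dose a pixel sees electrons in only a small fraction of
    frames, so its median across frames is effectively its dark level;
    the mean is cheaper but slightly biased upward by signal frames.
    """
    frames = calib_stack.frames if hasattr(calib_stack, "frames") else np.asarray(calib_stack)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 1:
        warnings.warn("single-frame calibration stack: dark level is that frame", stacklevel=2)
        return frames[0].astype(np.float64)
    if mode == "median":
        return np.median(frames, axis=0)
    if mode == "mean":
        return frames.mean(axis=0, dtype=np.float64)
    raise ValueError(f"unknown mode {mode!r}")


def pixel_gains(
    calib_stack,
    total_dose: float,
    dark_level: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel gain: median of the ceil(N) largest dark-subtracted values.

    ``total_dose`` (N, electrons per pixel over the whole stack) must be
    small enough that double hits on one pixel within a frame are
    negligible - the caller controls this through the calibration dose.
    """
    frames = calib_stack.frames if hasattr(calib_stack, "frames") else np.asarray(calib_stack)
    n_frames = frames.shape[0]
    n_top = int(np.ceil(total_dose))
    if n_top < 1:
        raise ValueError("total dose must be >= 1 electron/pixel for gain estimation")
    if n_top >= n_frames:
        raise ValueError(
            f"total dose {total_dose} needs more frames than the stack holds ({n_frames})"
        )
    if dark_level is None:
        dark_level = pixel_dark_levels(frames)
    sub = frames.astype(np.float64) - dark_level[None]
    # per pixel: median of the n_top largest values across frames
    top = np.partition(sub, n_frames - n_top, axis=0)[n_frames - n_top :]
    return np.maximum(np.median(top, axis=0), 0.0)


def estimate_dose_per_pixel(
    calib_stack,
    r: float = sigma_to_rate(DEFAULT_SIGMA),
    n_patches: int = DEFAULT_N_PATCHES,
    patch_size: int = DEFAULT_PATCH_SIZE,
    rng_seed: int | None = 0,
) -> DoseEstimate:
    """Estimate the total dose per pixel of a calibration stack.

    For each randomly placed odd-sized patch, per-pixel thresholds are
    fitted (normal dark model at rate ``r``), each frame's patch is
    thresholded and 8-connected components labeled, and components whose
    maximum-value pixel is the patch center are counted across all
    frames.  The patch average of these counts estimates the electrons
    per pixel accumulated over the stack.
    """
    frames = calib_stack.frames if hasattr(calib_stack, "frames") else np.asarray(calib_stack)
    n_frames, h, w = frames.shape
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd so a central pixel exists")
    if patch_size > min(h, w):
        raise ValueError("patch larger than frame")
    rng = np.random.default_rng(rng_seed)
    half = patch_size // 2
    rows = rng.integers(half, h - half, size=n_patches)
    cols = rng.integers(half, w - half, size=n_patches)
    z = float(stats.norm.isf(r))
    structure = np.ones((3, 3), dtype=bool)
    counts = np.zeros(n_patches, dtype=np.int64)
    for k in range(n_patches):
        patch = frames[
            :, rows[k] - half : rows[k] + half + 1, cols[k] - half : cols[k] + half + 1
        ].astype(np.float64)
        thr = patch.mean(axis=0) + z * patch.std(axis=0, ddof=1)
        masks = patch > thr[None]
        for f in range(n_frames):
            if not masks[f, half, half]:
                continue  # center pixel not signal: no component can emanate from it
            labels, n = ndimage.label(masks[f], structure=structure)
            lab = labels[half, half]
            sel = labels == lab
            vals = patch[f]
            # component emanates from its maximum-value pixel
            peak = np.unravel_index(np.argmax(np.where(sel, vals, -np.inf)), vals.shape)
            if peak == (half, half):
                counts[k] += 1
    return DoseEstimate(
        dose_per_pixel=float(counts.mean()),
        n_patches=n_patches,
        patch_size=patch_size,
        per_patch_counts=counts,
    )


def build_calibration_frame(
    global_threshold: float,
    global_dark_mean: float,
    global_gain: float,
    dark_level: np.ndarray,
    gain: np.ndarray,
    r: float | None = None,
    n_calibration_frames: int = 0,
) -> CalibrationFrame:
    """Adapt a global threshold to each pixel's dark level and gain.

    The global threshold is shifted so the pixel's dark level matches
    the global mean dark level, then scaled so the pixel's gain matches
    the global gain.  Pixels with non-positive gain are flagged dead
    (+inf threshold).
    """
    dark_level = np.asarray(dark_level, dtype=np.float64)
    gain = np.asarray(gain, dtype=np.float64)
    if dark_level.shape != gain.shape:
        raise ValueError("dark and gain maps must share one shape")
    if global_gain <= 0:
        raise ValueError("global gain must be strictly positive")
    margin = global_threshold - global_dark_mean
    with np.errstate(invalid="ignore"):
        threshold = dark_level + margin * (gain / global_gain)
    threshold = np.where(gain > 0, threshold, np.inf)
    return CalibrationFrame(
        threshold=threshold,
        dark_level=dark_level,
        gain=gain,
        r=r,
        n_calibration_frames=n_calibration_frames,
    )


def common_mode_correct(
    frame: np.ndarray,
    dark_level: np.ndarray,
    threshold: np.ndarray | None = None,
    block_shape: tuple[int, int] = DEFAULT_BLOCK_SHAPE,
) -> np.ndarray:
    """Remove per-block correlated thermal offsets from one frame.

    Pixels on the same readout block share a fluctuating offset; within
    each ``block_shape`` region the median dark-subtracted value of the
    non-signal pixels is subtracted.  Pixels above ``threshold`` are
    treated as signal and excluded from the offset estimate; a block
    whose pixels are all signal gets offset 0 and a warning.  Edge
    blocks are the remainder when the frame is not divisible.
    """
    frame = np.asarray(frame, dtype=np.float64)
    dark_level = np.asarray(dark_level, dtype=np.float64)
    if frame.shape != dark_level.shape:
        raise ValueError("frame and dark map shapes differ")
    sub = frame - dark_level
    signal = np.zeros(frame.shape, dtype=bool) if threshold is None else frame > threshold
    out = frame.copy()
    bh, bw = block_shape
    h, w = frame.shape
    for r0 in range(0, h, bh):
        for c0 in range(0, w, bw):
            blk = np.s_[r0 : min(r0 + bh, h), c0 : min(c0 + bw, w)]
            keep = ~signal[blk]
            if not keep.any():
                warnings.warn(
                    f"block at ({r0},{c0}) has no noise pixels; offset left at 0",
                    stacklevel=2,
                )
                continue
            out[blk] -= np.median(sub[blk][keep])
    return out


def area_filter(puddles, max_area: int, min_area: int = 1):
    """Keep only puddles with ``min_area <= area <= max_area`` pixels.

    Reduces false-positive detections (noise exceedances are mostly
    single pixels; abnormally large clusters are artifacts).  Returns a
    new puddle set with the label image zeroed where puddles were
    dropped; surviving puddles keep their labels.
    """
    from .reduction import PuddleSet  # local import to avoid a module cycle

    if not max_area >= min_area >= 1:
        raise ValueError("need max_area >= min_area >= 1")
    kept = [p for p in puddles.puddles if min_area <= p.area <= max_area]
    labels = puddles.labels.copy()
    keep_labels = np.zeros(labels.max() + 1 if labels.size else 1, dtype=bool)
    for p in kept:
        keep_labels[p.label] = True
    labels[~keep_labels[labels]] = 0
    return PuddleSet(labels=labels, puddles=kept, frame_index=puddles.frame_index)


def calibrate_on_the_fly(
    calib_stack,
    r: float = sigma_to_rate(DEFAULT_SIGMA),
    n_patches: int = DEFAULT_N_PATCHES,
    patch_size: int = DEFAULT_PATCH_SIZE,
    rng_seed: int | None = 0,
    dark_mode: str = "median",
) -> CalibrationFrame:
    """Full fast calibration: global threshold -> dose -> dark/gain -> per-pixel thresholds."""
    frames = calib_stack.frames if hasattr(calib_stack, "frames") else np.asarray(calib_stack)
    flat = frames.reshape(frames.shape[0], -1)
    # subsample pixels for the global normal fit on large stacks
    rng = np.random.default_rng(rng_seed)
    sample = flat if flat.size <= 4_000_000 else flat.ravel()[
        rng.integers(0, flat.size, size=4_000_000)
    ]
    global_threshold = estimate_global_threshold(np.asarray(sample, dtype=np.float64), r)
    dark = pixel_dark_levels(frames, mode=dark_mode)
    dose = estimate_dose_per_pixel(
        frames, r=r, n_patches=n_patches, patch_size=patch_size, rng_seed=rng_seed
    )
    n_top = max(1, int(np.ceil(dose.dose_per_pixel)))
    gain = pixel_gains(frames, total_dose=n_top, dark_level=dark)
    pos = gain[gain > 0]
    global_gain = float(np.median(pos)) if pos.size else 1.0
    return build_calibration_frame(
        global_threshold=global_threshold,
        global_dark_mean=float(dark.mean()),
        global_gain=global_gain,
        dark_level=dark,
        gain=gain,
        r=r,
        n_calibration_frames=frames.shape[0],
    )
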