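"""Synthetic electron-event movies with known ground truth.

The generator emulates the statistical structure the reduction scheme
assumes: electrons arrive per frame as a Poisson process with mean
``dose_rate * H * W`` (dose_rate = electrons/pixel/frame), each electron
deposits a "puddle" - a small 8-connected stamp of ADU weights drawn
from a shape library - on top of per-pixel Gaussian dark noise, scaled
by a per-pixel gain map.  Optionally each primary electron spawns a
backscatter event nearby, and dose-series generation emulates the
magnification-stepped dilution experiment used to measure
false-positive floors.

Fixed 1-pixel, 2x2 and 3x3 stamp libraries reproduce idealized
point-spread-function assumptions; the parametric library mimics a
back-thinned detector where most puddles span one or two pixels.

Every simulation is fully determined by its seed and returns the ground
truth event list alongside the frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .frame_io import FrameStack

__all__ = [
    "PuddleShape",
    "ShapeLibrary",
    "SimulationConfig",
    "Event",
    "simulate_frames",
    "simulate_binary_frames",
    "inject_backscatter",
    "simulate_dose_series",
    "rayleigh_displacement",
]

DEFAULT_DARK_MEAN = 100.0  # ADU
DEFAULT_DARK_SD = 4.0  # ADU
DEFAULT_AMP_MEAN = 40.0  # mean single-hit amplitude, 10 x dark sd


@dataclass(frozen=True)
class PuddleShape:
    """One stamp: pixel offsets (containing (0,0)) and ADU weight fractions."""

    offsets: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if (0, 0) not in self.offsets:
            raise ValueError("shape must contain offset (0, 0)")
        if len(self.offsets) != len(self.weights):
            raise ValueError("offsets and weights differ in length")
        if not _is_8_connected(self.offsets):
            raise ValueError("shape offsets must be 8-connected")

    @property
    def size(self) -> int:
        return len(self.offsets)


def _is_8_connected(offsets) -> bool:
    cells = set(offsets)
    if not cells:
        return False
    seen = {next(iter(cells))}
    frontier = list(seen)
    while frontier:
        r, c = frontier.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nb = (r + dr, c + dc)
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
    return len(seen) == len(cells)


def _square_shape(side: int) -> PuddleShape:
    offs = tuple((r, c) for r in range(side) for c in range(side))
    return PuddleShape(offsets=offs, weights=(1.0,) * len(offs))


@dataclass
class ShapeLibrary:
    """A set of puddle shapes with sampling probabilities."""

    shapes: list[PuddleShape]
    probabilities: np.ndarray
    mode: str = "parametric"

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if len(self.shapes) != self.probabilities.size:
            raise ValueError("one probability per shape required")
        if self.probabilities.min() < 0 or not math.isclose(
            float(self.probabilities.sum()), 1.0, rel_tol=1e-9
        ):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @classmethod
    def fixed_1px(cls) -> "ShapeLibrary":
        return cls([_square_shape(1)], [1.0], mode="fixed_1px")

    @classmethod
    def fixed_2x2(cls) -> "ShapeLibrary":
        return cls([_square_shape(2)], [1.0], mode="fixed_2x2")

    @classmethod
    def fixed_3x3(cls) -> "ShapeLibrary":
        return cls([_square_shape(3)], [1.0], mode="fixed_3x3")

    @classmethod
    def from_psf(cls, psf: str) -> "ShapeLibrary":
        try:
            return {"1px": cls.fixed_1px, "2x2": cls.fixed_2x2, "3x3": cls.fixed_3x3}[psf]()
        except KeyError:
            raise ValueError(f"unknown PSF {psf!r}; expected 1px, 2x2 or 3x3") from None

    @classmethod
    def parametric(
        cls,
        size_probabilities: dict[int, float] | None = None,
        seed: int = 0,
    ) -> "ShapeLibrary":
        """Shapes drawn uniformly from the fixed polyplets of each size.

        The default size distribution is a truncated-geometric-like law
        favouring 1-2 pixel puddles, mimicking back-thinned detectors
        where most puddles span fewer than three pixels.
        """
        from .analysis import enumerate_fixed_polyplets  # deferred: module cycle

        if size_probabilities is None:
            size_probabilities = {1: 0.45, 2: 0.34, 3: 0.13, 4: 0.08}
        total = sum(size_probabilities.values())
        shapes: list[PuddleShape] = []
        probs: list[float] = []
        rng = np.random.default_rng(seed)
        for size, p in sorted(size_probabilities.items()):
            polyplets = enumerate_fixed_polyplets(size)
            for offs in polyplets:
                offs = _anchor_at_origin(offs)
                # origin pixel strongest; satellites carry reproducible
                # sub-unit weights so each shape has a unique maximum
                w = [1.0] + list(np.round(rng.uniform(0.3, 0.7, size=len(offs) - 1), 3))
                shapes.append(PuddleShape(offsets=tuple(offs), weights=tuple(w)))
                probs.append(p / total / len(polyplets))
        return cls(shapes, probs, mode="parametric")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(len(self.shapes), size=n, p=self.probabilities)

    def size_distribution(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for s, p in zip(self.shapes, self.probabilities):
            out[s.size] = out.get(s.size, 0.0) + float(p)
        return out


def _anchor_at_origin(offsets):
    offsets = sorted(offsets)
    r0, c0 = offsets[0]
    moved = [(r - r0, c - c0) for r, c in offsets]
    if (0, 0) not in moved:  # anchor on the first cell of the top row instead
        top = min(moved)
        moved = [(r - top[0], c - top[1]) for r, c in moved]
    return moved


@dataclass
class Event:
    """Ground-truth electron event."""

    frame: int
    row: int
    col: int
    shape_id: int
    is_backscatter: bool = False
    amplitude: float = 0.0


def rayleigh_displacement(scale: float = 5.0):
    """2-D displacement sampler: Rayleigh radius, uniform angle."""

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        radius = rng.rayleigh(scale, size=n)
        angle = rng.uniform(0, 2 * np.pi, size=n)
        d = np.stack([radius * np.sin(angle), radius * np.cos(angle)], axis=1)
        return np.rint(d).astype(np.int64)

    return draw


@dataclass
class SimulationConfig:
    """Everything that determines one synthetic movie."""

    dose_rate: float = 0.005  # electrons/pixel/frame
    shape: tuple[int, int] = (256, 256)
    n_frames: int = 100
    shape_library: ShapeLibrary = field(default_factory=ShapeLibrary.fixed_1px)
    amp_mean: float = DEFAULT_AMP_MEAN  # ADU, mean single-hit amplitude
    amp_sigma: float = 0.2  # lognormal shape parameter; 0 = fixed amplitude
    dark_mean: np.ndarray | float = DEFAULT_DARK_MEAN
    dark_sd: np.ndarray | float = DEFAULT_DARK_SD
    gain: np.ndarray | float = 1.0
    backscatter_fraction: float = 0.0
    #: callable (rng, n) -> (n, 2) int displacements; None = Rayleigh(5 px)
    backscatter_displacement: object = None
    boundary: str = "periodic"  # periodic | clip
    bit_depth: int = 16
    frame_rate: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_rate < 0:
            raise ValueError("dose rate must be non-negative")
        if self.boundary not in ("periodic", "clip"):
            raise ValueError("boundary must be 'periodic' or 'clip'")


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator) -> list[Event]:
    h, w = cfg.shape
    mu = cfg.dose_rate * h * w
    events: list[Event] = []
    counts = rng.poisson(mu, size=cfg.n_frames)
    for f in range(cfg.n_frames):
        k = int(counts[f])
        if k == 0:
            continue
        rows = rng.integers(0, h, size=k)
        cols = rng.integers(0, w, size=k)
        shape_ids = cfg.shape_library.sample(rng, k)
        if cfg.amp_sigma > 0:
            # lognormal with the requested mean amplitude
            mu_ln = math.log(cfg.amp_mean) - cfg.amp_sigma**2 / 2
            amps = rng.lognormal(mu_ln, cfg.amp_sigma, size=k)
        else:
            amps = np.full(k, cfg.amp_mean)
        for i in range(k):
            events.append(
                Event(
                    frame=f,
                    row=int(rows[i]),
                    col=int(cols[i]),
                    shape_id=int(shape_ids[i]),
                    amplitude=float(amps[i]),
                )
            )
    return events


def inject_backscatter(
    events: list[Event],
    fraction: float,
    displacement_dist=None,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
    boundary: str = "periodic",
) -> list[Event]:
    """Each primary independently spawns a backscatter event nearby.

    With probability ``fraction`` a primary re-enters the sensor after
    scattering and deposits a second puddle displaced by a draw from
    ``displacement_dist`` (default: Rayleigh radius of 5 pixels).  A
    zero displacement lands on the parent puddle and merges with it
    (coincidence).  Secondary events inherit the primary's shape id.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0 or not events:
        return list(events)
    rng = np.random.default_rng(0) if rng is None else rng
    displacement_dist = displacement_dist or rayleigh_displacement()
    primaries = [e for e in events if not e.is_backscatter]
    spawn = rng.random(len(primaries)) < fraction
    n_spawn = int(spawn.sum())
    disp = displacement_dist(rng, n_spawn)
    out = list(events)
    j = 0
    for e, s in zip(primaries, spawn):
        if not s:
            continue
        r, c = e.row + int(disp[j, 0]), e.col + int(disp[j, 1])
        j += 1
        if shape is not None:
            h, w = shape
            if boundary == "periodic":
                r, c = r % h, c % w
            elif not (0 <= r < h and 0 <= c < w):
                continue  # scattered off the sensor
        out.append(
            Event(
                frame=e.frame,
                row=r,
                col=c,
                shape_id=e.shape_id,
                is_backscatter=True,
                amplitude=e.amplitude,
            )
        )
    return out


def _stamp_events(
    cfg: SimulationConfig, events: list[Event], signal: np.ndarray
) -> None:
    """Additively stamp each event's weighted shape into ``signal`` (float)."""
    h, w = cfg.shape
    lib = cfg.shape_library
    periodic = cfg.boundary == "periodic"
    for e in events:
        shp = lib.shapes[e.shape_id]
        for (dr, dc), wt in zip(shp.offsets, shp.weights):
            r, c = e.row + dr, e.col + dc
            if periodic:
                r, c = r % h, c % w
            elif not (0 <= r < h and 0 <= c < w):
                continue
            signal[e.frame, r, c] += e.amplitude * wt


def simulate_frames(cfg: SimulationConfig) -> tuple[FrameStack, list[Event]]:
    """Simulate a movie plus its ground-truth event list.

    Per frame, Poisson(dose_rate*H*W) electrons land uniformly; each
    stamps its shape's ADU pattern scaled by the per-pixel gain map
    (additively where puddles overlap); Gaussian dark noise is added per
    pixel; values are clipped to the declared bit depth.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    events = _draw_events(cfg, rng)
    if cfg.backscatter_fraction:
        events = inject_backscatter(
            events,
            cfg.backscatter_fraction,
            cfg.backscatter_displacement,
            rng,
            shape=cfg.shape,
            boundary=cfg.boundary,
        )
    signal = np.zeros((cfg.n_frames, h, w), dtype=np.float64)
    _stamp_events(cfg, events, signal)
    signal *= np.broadcast_to(np.asarray(cfg.gain, dtype=np.float64), (h, w))
    dark = rng.normal(
        np.broadcast_to(np.asarray(cfg.dark_mean, dtype=np.float64), (h, w)),
        np.broadcast_to(np.asarray(cfg.dark_sd, dtype=np.float64), (h, w)),
        size=(cfg.n_frames, h, w),
    )
    frames = np.clip(np.rint(signal + dark), 0, (1 << cfg.bit_depth) - 1)
    dtype = np.uint8 if cfg.bit_depth <= 8 else np.uint16
    stack = FrameStack(
        frames.astype(dtype),
        bit_depth=cfg.bit_depth,
        frame_rate=cfg.frame_rate,
        source=f"simulated(dose={cfg.dose_rate}, seed={cfg.seed})",
    )
    return stack, events


def simulate_binary_frames(cfg: SimulationConfig) -> tuple[np.ndarray, list[Event]]:
    """Noiseless boolean stamping of events (for coincidence studies).

    Returns the boolean occupancy movie and the event list; no dark
    noise, gain or amplitudes are applied.
    """
    rng = np.random.default_rng(cfg.seed)
    events = _draw_events(cfg, rng)
    h, w = cfg.shape
    masks = np.zeros((cfg.n_frames, h, w), dtype=bool)
    lib = cfg.shape_library
    periodic = cfg.boundary == "periodic"
    frames_idx = np.array([e.frame for e in events], dtype=np.int64)
    rows = np.array([e.row for e in events], dtype=np.int64)
    cols = np.array([e.col for e in events], dtype=np.int64)
    sids = np.array([e.shape_id for e in events], dtype=np.int64)
    for sid in np.unique(sids):
        sel = sids == sid
        shp = lib.shapes[int(sid)]
        for dr, dc in shp.offsets:
            r, c = rows[sel] + dr, cols[sel] + dc
            if periodic:
                r, c = r % h, c % w
                masks[frames_idx[sel], r, c] = True
            else:
                ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
                masks[frames_idx[sel][ok], r[ok], c[ok]] = True
    return masks, events


def simulate_dose_series(
    base_cfg: SimulationConfig,
    n_steps: int,
    dilution_factor: float = 200.0,
    fp_rate: float = 0.0,
) -> list[tuple[SimulationConfig, FrameStack, list[Event]]]:
    """Dose series with geometric dilution plus a constant spurious floor.

    Emulates the magnification-stepped experiment: the true dose rate
    shrinks by ``dilution_factor`` at each step while a constant
    per-pixel false-positive event rate ``fp_rate`` (spurious 1-pixel
    events from noise exceedances) is superimposed at every step.
    Returns one (config, frames, truth) triple per step; spurious events
    are flagged with ``shape_id = -1``.
    """
    if n_steps < 2:
        raise ValueError("need at least two dilution steps")
    out = []
    for k in range(n_steps):
        cfg = replace(
            base_cfg,
            dose_rate=base_cfg.dose_rate * dilution_factor ** (-k),
            seed=base_cfg.seed + 1000 * k,
        )
        stack, events = simulate_frames(cfg)
        if fp_rate > 0:
            rng = np.random.default_rng(cfg.seed + 500_000)
            fp_cfg = replace(
                cfg,
                dose_rate=fp_rate,
                shape_library=ShapeLibrary.fixed_1px(),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fp_masks, fp_events = simulate_binary_frames(fp_cfg)
            amp = np.asarray(base_cfg.amp_mean, dtype=np.float64)
            frames = stack.frames.astype(np.float64)
            frames[fp_masks] += float(amp)
            stack = FrameStack(
                np.clip(frames, 0, (1 << cfg.bit_depth) - 1).astype(stack.frames.dtype),
                bit_depth=cfg.bit_depth,
                frame_rate=cfg.frame_rate,
                source=stack.source + f"+fp({fp_rate})",
            )
            for e in fp_events:
                e.shape_id = -1
                events.append(e)
        out.append((cfg, stack, events))
    return out
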