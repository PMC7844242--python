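# Methods

This note documents the models, defaults and numerical conventions
behind `recode`, module by module, and what the synthetic-data tests do
and do not demonstrate about real detector data.

## Conventions

All coordinates are 0-based, row-major `(row, col)`; frame index 0 is
the first acquired frame. All on-disk integers are little-endian.
Nothing in the reduction path uses randomness: given a frame, a
threshold map and a configuration, every output is deterministic with
fixed tie-breaks (documented below).

## Thresholding and calibration

A pixel is signal iff its ADU value is **strictly greater** than its
threshold; a pixel exactly at threshold is noise. Dead pixels carry a
`+inf` threshold and can never be signal.

The fast calibration assumes each pixel's dark values are normally
distributed. The global threshold is the `(1−r)` quantile of a normal
fitted by sample mean/SD to the pooled dark values; `r` is the
tolerable per-pixel false-positive rate and is exposed both as a
probability and as a σ-multiple (`sigma_to_rate`). Defaults: 3σ
(`r ≈ 1.35e-3`) for fast calibration, 4σ for fine calibration. A
median/MAD fit is available (`robust=True`) for contaminated samples.
Per-pixel adaptation shifts the global threshold to the pixel's dark
level and scales it by the pixel's relative gain:

```
T_p = dark_p + (T_global − dark_global) · gain_p / gain_global
```

Pixels with non-positive gain are flagged dead.

*Dark levels* are per-pixel medians over the calibration stack (a mean
mode is provided: cheaper, slightly biased upward by signal frames).
*Gains* are the median of each pixel's `⌈N⌉` largest dark-subtracted
values, where `N` is the total dose per pixel over the stack. `N` is
itself estimated by thresholding small patches (default: 64 random
11×11 patches — the patch count/size are free choices; they only set
the estimator's variance), labeling 8-connected components per frame,
and counting components whose maximum-value pixel sits at the patch
center ("a puddle emanates from its maximum pixel"). The gain
estimator's error has Poisson tails: a pixel that happens to receive
fewer than ~N/2 electrons gets a noise-contaminated gain. At N = 30
and 1000 frames the mean relative gain error is ≈1.6% and the 95th
percentile ≈4%, but the worst pixel of a 64×64 region can be tens of
percent off; recovery bounds are therefore stated as aggregates over
pixels, and in practice such pixels are exactly what area filtering
and recalibration from L1 data are for.

*Fine calibration* adds (1) common-mode correction: within each 4×256
readout block (the geometry of correlated thermal response), the median
dark-subtracted value of the non-signal pixels is subtracted. The
statistic is the median and signal pixels are excluded by
threshold — both our choices; a block with no noise pixels keeps offset
0 and warns. (2) area filtering: puddles outside `[min_area,
max_area]` are dropped (single-pixel puddles are the dominant
false-positive class; oversized clusters are artifacts).

## Reduction levels

Connected components are labeled with `scipy.ndimage.label` and
relabeled to **row-major first-touch order**, which fixes the on-disk
order of L2 statistics. Connectivity defaults to 8 (diagonal contact
merges — required for consistency with the coincidence-loss tables and
with the max-pixel emanation rule); 4-connectivity is selectable.

* **L1** stores the packed binary map plus the thresholded but
  **unmodified** ADUs of signal pixels in row-major order (no dark
  subtraction baked in), at a packed bit depth defaulting to the input
  bit depth. This preserves post-acquisition recalibration, which is
  the point of L1.
* **L2** stores the binary map plus one packed statistic per puddle in
  label order. Packed widths: `max`/`mean` at the input bit depth
  (mean rounded to the integer grid), `sum` at bit depth + 8 bits
  (areas capped at 256 pixels; larger sums clamp). The original
  packing widths are not published; these are our choices.
* **L3** stores the binary map only — `⌈H·W/8⌉` bytes regardless of
  content, hence an exact 16× reduction for 16-bit input.
* **L4** stores a binary map with one localization pixel per puddle.
  Strategies: `max_pixel` (first row-major maximum on ties),
  `weighted_centroid`, `unweighted_centroid`. Centroids round
  **half-down per axis**, so a uniform 2×2 square maps to its top-left
  pixel; any consistent rule works, this one is fixed and tested.

`expand_frame` inverts each level up to its declared information loss
and validates payload lengths and mask/count consistency; malformed
payloads raise `CorruptionError` rather than decoding silently wrong.

Centroid sets can also be encoded standalone in three interchangeable
forms: a packed linear index per centroid (per-coordinate width
`max(8, ⌈log2 dim⌉)` bits), zero-run RLE of the sorted linearized map,
or a packed binary image. The binary image is the container's native
form (it needs no sort).

## Codec layer

Six algorithms × two optimization extremes, mapped to each library's
fastest/strongest presets: deflate (zlib 1/9), bzip2 (1/9), lzma
(preset 0/9), zstd (1/22), lz4 (frame format, 1/12), snappy (no
levels; both extremes coincide). zstd/lz4/snappy are provided through
pyarrow's codec bindings. The default is deflate at its fastest level
("Deflate-1"). An optional bitshuffle prefilter transposes the bit
matrix of fixed chunks (default 64 KiB — a reproducible stand-in for
"fits in L1 cache") before compression; it is exactly invertible and
never changes decoded content. Compressed blocks are self-describing:
a stable 1-byte spec id plus the uncompressed length (and chunk size
when prefiltered), so blocks decode without out-of-band metadata and
unknown ids fail loudly.

## Container format

Fixed 512-byte header; append-only per-frame records
(`frame_number, timestamp, payload lengths, counts, flags, CRC-32 per
compressed payload, payloads`); a footer offset table appended at
finalize gives O(1) random access. Worker part files are identical but
footer-less (their index is rebuilt by scanning). Merging copies
compressed record bytes **verbatim** into frame-number order — no
re-compression — and rejects duplicate or missing frame numbers with an
explicit listing. Raw frames can be retained uncompressed at a fixed
interval alongside their reduced form, for validation and on-the-fly
recalibration; they decode bit-identically. Timestamps are
caller-supplied monotonic integers (the pipeline uses
`frame_index · frame period` in ns). This layout is a re-design in the
spirit of the original format, not byte-compatible with it.

The pipeline cuts the stream into contiguous chunks (default 16
frames) dealt round-robin to workers; workers share nothing but the
read-only source and write disjoint part files, so the merged
container's decoded content is a pure function of frames + calibration
timeline + settings, independent of worker count and chunk size
(tested at 1 vs 8 workers). Threshold frames can be reloaded from a
TIFF every k chunks; a failed reload keeps the previous thresholds and
warns. Workers run in a thread pool — numpy releases the GIL for the
heavy steps, and the contract is the share-nothing layout, not a
particular parallel primitive.

## Simulator

Per frame, `K ~ Poisson(λ·H·W)` electrons land uniformly (λ =
e/pixel/frame); each stamps a shape from the library additively,
scaled by a per-pixel gain map; Gaussian dark noise (defaults: mean
100 ADU, σ 4 ADU) is added and values clip to the declared bit depth.
Single-hit amplitudes default to a lognormal with mean 40 ADU (10 dark
σ — a right-skewed stand-in for the Landau-like energy-loss spectrum)
and shape 0.2; σ=0 gives fixed amplitudes for calibration tests.
Boundaries: periodic (default for coincidence studies — no edge bias)
or clip. Fixed 1px/2×2/3×3 square stamps reproduce idealized PSF
assumptions; the parametric library draws puddle sizes from a
truncated-geometric-like law favouring 1–2 pixels (back-thinned
detectors: most puddles span under three pixels) and shapes uniformly
from the enumerated fixed polyplets of each size, with reproducible
satellite weights so shapes have a unique maximum pixel. The true
shape library of any particular detector is a configuration input, not
a constant.

Backscatter: each primary independently spawns, with probability `f`,
a secondary event displaced by a draw from a configurable distribution
(default Rayleigh radius 5 px, uniform angle — chosen as a plausible
few-to-tens-of-pixels re-entry scale; the estimator takes the
candidate distribution as input, so its exact form is a scenario
choice). Dose series: the true dose shrinks geometrically per step
(emulating magnification-stepped dilution) while a constant per-pixel
spurious event rate is superimposed; spurious events are 1-pixel
stamps flagged in the ground truth.

What the simulator does **not** model: charge transport physics (no
Geant4-style puddle formation), detector MTF/DQE, pixel cross-talk,
hot/flickering pixels, or temporally correlated dark drift (drift is
injected explicitly where a test needs it). Passing recovery tests
therefore shows the estimators are correct under the stated
statistical model, not that any particular detector satisfies it.

## Analyses

**Coincidence loss** is defined as `1 − counted/incident`, where
electrons landing on one pixel or in one 8-connected component count
as merged; the estimate is the ratio of totals over frames with a
delta-method standard error from per-frame variation. Two engines:

* *image*: stamp booleans, label with wrap-around (torus) connectivity,
  count. Works for any shape library and connectivity.
* *event graph*: for a single side-`s` square stamp under
  8-connectivity, two stamps merge iff their wrapped per-axis anchor
  offsets are ≤ `s`; components come from a union-find over event
  pairs, with dense frames (>1500 events) rasterized instead. This is
  exact — no raster approximation is involved — and makes λ = 1e-5
  studies tractable; the two engines agree within Monte-Carlo error
  wherever both run (tested).

First-order theory: a second electron merges with a given one when its
anchor falls in the `(2s+1)²` wrapped offsets (including the same
anchor), so `loss/λ → (2s+1)²/2` = 4.5, 12.5, 24.5 for 1px, 2×2, 3×3
stamps. The Monte-Carlo engines converge to these limits.

The *analytic* size-distribution estimate models puddles as square
bounding boxes of side `⌈√area⌉` and thins exponentially:
`loss = 1 − exp(−λ·E[(s₁+s₂+1)²])`. It is a deliberate stand-in — it
double-counts chain merges and overstates the small-λ slope by about
2× — documented for ordering/monotonicity use only.

**Polyplet enumeration** grows canonical (translation-anchored)
8-connected clusters cell by cell with deduplication; it matches an
exhaustive subset-filter oracle for sizes 1–5 (1, 4, 20, 110, 638).

**Benchmarking** uses payload-only accounting (reduced payload bytes
and the compressed blocks thereof, no container overhead), which makes
the L3/L4 reduction-only factor exactly the input bit depth. Level 0
means compressing the raw frames directly. Ratios are
hardware-independent sizes; no throughput claims are made.

**Backscatter estimation** histograms nearest-neighbour distances
between detected events (1-px bins to 30 px), and least-squares fits
the backscatter fraction over bins 1–15 (where the companion excess
lives; both binning choices are ours) against histograms simulated at
the same dose and geometry across a fraction grid, with quadratic
refinement around the grid minimum. It requires ultra-sparse data
(≥1000 events enforced; chance proximity must be rare) and reports
`(1−f)/f`, or "no detectable backscatter" when `f ≈ 0`. Recovery of an
injected fraction 0.104 from 1e5 primaries is accurate to a few
percent in the tests.

**False-positive floor**: with a known dilution factor `1/g` the model
`counted_k = d₀·g^k + f` is linear in `(d₀, f)` and solved by least
squares; a non-monotone series (beyond a 5% noise allowance) is
flagged. The scenario used in tests keeps the starting dose low
(0.003 e/pixel/frame, 1-px puddles) so coincidence loss does not bend
the geometric decay.

## Problem sizes used in tests

The quantitative suite simulates 100 frames of 1024×1024 per
coincidence-loss cell, ~25k sparse 4096×4096 frames (event-graph) for
the λ=1e-5 limits, 256 frames for the worker-invariance contract, 1e5
primaries for backscatter recovery, 5×1.5e6 pixel-frames for the
dose-series fit and 1000 calibration frames for dark/gain recovery;
the whole suite runs in about a minute on one CPU. These sizes were
chosen so Monte-Carlo standard errors sit well inside the stated
tolerances.

## Known limitations

* The container layout is self-consistent but not byte-compatible with
  any external tool's format.
* L1 packed bit depth ≤ input bit depth is not enforced against future
  recalibration needs; choose the packed depth deliberately if ADUs
  near the top of range matter.
* The analytic coincidence-loss column is a documented approximation
  (see above), not a calibrated estimator.
* `sum` statistics clamp at `2^(bit_depth+8) − 1`; pathological puddles
  larger than 256 pixels lose information in L2 (not in L1).
* The backscatter estimator assumes the candidate displacement family
  contains the truth; model mismatch biases the fraction.
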