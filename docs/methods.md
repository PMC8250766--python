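# Methods

## The measurement problem

Coleoid cephalopods repattern their skin in milliseconds by muscular control
of chromatophores — pigment sacs whose visible area grows when radial
muscles contract (expansion) and shrinks when they relax (retraction).  A
brief, bright light flash delivered to an intact squid elicits a
sub-jet-threshold startle response: a transient area change in many organs
at once, beginning tens of milliseconds after the flash and completing
within a few hundred milliseconds.  `chromodyn` quantifies that response
from grayscale video of a skin patch: per-organ area time series, a
statistical gate deciding which organs responded, and the timing and
magnitude metrics of each response.

Because the raw footage behind this kind of experiment is typically not
deposited, the package ships a ground-truthed simulator so every stage is
testable end to end without any data download.

## Trial model and the frame-time quantization

A trial is a fixed-length frame sequence at frame rate `f` (default 60 fps)
containing a short saturated block where the flash fired (the flash itself
lasts ~100 μs — far below one frame — and is modeled purely as
`flash_frame_count` saturated frames, default 2).  Frame `k` is pinned to
the exact time `(k − k_flash) · 1000 / f` ms, so the first flash frame is
`t = 0` and the inter-frame interval at 60 fps is 16.67 ms.  Every reported
time is a multiple of this interval: the quantization margin of each timing
metric is ±16.67 ms, and no sub-frame interpolation is attempted.  Times
are kept as exact fractions internally and rounded half-up to integer
milliseconds once, at reporting (116.67 → 117, 216.67 → 217).  Under this
convention a mean such as 133.33 ms would print as 133; published tables of
this kind occasionally print 134 for such cells, so a one-unit discrepancy
in the last digit of a rounded mean is possible and documented rather than
reverse-engineered.

The flash frames are excluded from every analysis (the animal is not
observable in them), so the earliest observable crossing with two flash
frames is post-flash frame 2 (33 ms).

## Simulator

Each organ is an anti-aliased dark ellipse on a light background (default
luminance 30 on 200, 8-bit).  Its area follows a piecewise-linear
trajectory: baseline until `onset_ms` after the flash, linear ramp to the
peak over `rise_ms`, linear return over `return_ms`, baseline after.  A
smoothstep variant is available (`profile="smooth"`).  The linear default
is a deliberate stand-in, not an inference: published data show only
averaged empirical curves, and a piecewise-linear ramp makes every
threshold-crossing frame exactly controllable for tests.  Retraction
mirrors expansion downward; after normalization by the pre-flash mean the
two are exact mirror images.

Ellipse axes are scaled by √(area ratio) so the rendered pixel area — not
the diameter — tracks the trajectory.  Coverage is computed by 4×4
sub-pixel sampling on the ellipse bounding box; summed coverage matches the
analytic area πab to well under 1%.

Geometry defaults follow squid skin: organ density 8 mm⁻², baseline
diameters sampled uniformly from 120–350 μm at 10 μm/pixel.  The anatomical
diameter range extends to ~1,520 μm for the largest fully expanded organs
and can be requested through `diameter_range_um`; the default caps baseline
diameters lower because the emulated animals sit light-toned with
chromatophores mostly retracted before the flash, and because at 8 mm⁻²
full-range baseline footprints cannot be placed without near-total overlap
(random sequential placement jams near 55% area coverage).  Placement
rejection-samples centers with a minimum spacing of 1.1× the summed
baseline radii and requires each organ's maximally expanded footprint to
fit inside the image; organs that would overlap when expanded only raise a
warning, mirroring the fact that real expanded chromatophores do touch.

Response parameters default to the regime the analysis targets: expansion
magnitudes ~N(155, 30)% clipped to [20, 400], retractions ~N(40, 10)%
clipped to [5, 95] (an area cannot shrink past 100%), onsets 30–45 ms,
rise times 70–110 ms, returns 150–300 ms, 1.6% of organs retracting and
90% of organs responding.  Noise is additive Gaussian luminance noise
clipped to the 8-bit range (default SD 5); optional whole-field jitter is
an integer-rounded Gaussian random walk.  Flash frames are written as fully
saturated (a saturated sensor clips the noise away).  Everything derives
from one integer seed; identical (config, seed) gives bit-identical stacks.

What the simulator does **not** emulate: organ deformation and
non-elliptical shapes, spatially correlated illumination drift, animal
locomotion beyond rigid jitter, color (the analysis is area-only), and
occlusion.  Tests passing on this generator therefore validate the
arithmetic and the statistical behavior of the pipeline, not its robustness
to footage of freely behaving animals.

## Segmentation and tracking

Organs are dark on light: each frame is thresholded (Otsu by default; the
dark class is `frame ≤ threshold`, which matters for noise-free two-valued
test frames), connected components are labeled (8-connectivity) and
filtered by `[min_area, max_area]`.  Tracks are grown by greedy
nearest-centroid assignment between consecutive non-excluded frames:
candidate pairs within `max_displacement` (default 10 px/frame) are taken
in order of increasing distance, ties broken by smaller track id.
Unmatched blobs start new tracks; a track undetected for more than
`max_gap` (default 3) consecutive non-excluded frames terminates; flash
frames are skipped without penalty.  When two tracks compete for one blob
and the loser has no alternative, both parents terminate and the blob
restarts as a new track — no splitting heuristics, matching the practice of
discarding footage that cannot be tracked cleanly.

A track is *usable* for analysis only if it spans the pre-flash baseline
window from its start and at least 50% of the post-flash window, with at
least 5 present baseline values.  This suitability gate is an engineering
proxy for footage-quality screening.

Areas are pixel counts (pixels²); physical area is available only through
the configured scale.  Relative metrics are scale-invariant, so pixel units
suffice throughout.

## Change-point gate

Whether an organ responded is decided by CUSUM change-point analysis with a
permutation bootstrap.  For a series `x₁…xₙ` (missing values removed,
original frame indices remembered):

    S₀ = 0,  Sᵢ = Sᵢ₋₁ + (xᵢ − x̄),  s_diff = max S − min S

The confidence is the fraction of `n_boot` (default 1000) random
permutations of the series whose `s_diff` is *strictly* below the observed
one; the change point is the first observation after the index of max |S|.
A result is significant only if confidence ≥ threshold (default 0.95) *and*
the change frame falls after the flash within the acceptance window
(default 30 frames): a change before the flash, however confident, is not a
flash response.  One change point per trace — the design targets a single
flash-locked transient, not segmentation.

For a transient (up-and-back) response the CUSUM extremum with the larger
magnitude sits at the response onset whenever the pre-flash baseline is at
least as long as the response; the default 60-frame windows guarantee this.
On null series the observed `s_diff` is exchangeable with its permutations,
so P(confidence ≥ 0.95) ≈ 5% before the window rule and ~1–2% after it;
this calibration is asserted by simulation in the test suite.

A trial counts as significant when at least one of its traces is; trials
can contain both expansion and retraction responses simultaneously.

## Timing and magnitude metrics

For each significant trace: BCSA is the arithmetic mean (and sample SD) of
present areas in a pre-flash window (≥5 values); RCSA is the post-flash
extremum — the direction (max vs min) with the larger absolute deviation
from BCSA wins and must exceed 3×(baseline SD), otherwise the organ is
declared a non-response.  The noise floor is secondary protection: the CPA
gate remains the primary inclusion criterion.

Thresholds are `BCSA + f·(RCSA − BCSA)` for f ∈ {0.05, 0.50, 1.0}:

- **tR** — time of the first post-flash frame at or past the 5% threshold;
- **tD** — likewise at 50%;
- **tRt** — time of the peak frame;
- **rD** — time of the first post-peak frame back at or inside the 5%
  threshold, minus tR.  If the trace never returns inside the threshold,
  `valid_rD` is False and the organ is excluded from duration means only.
- **magnitude** — 100·(RCSA − BCSA)/BCSA for expansion,
  100·(BCSA − RCSA)/BCSA for retraction; positive in both directions.

Retraction thresholds are treated symmetrically to expansion (the trough is
the "100% value").  `tR ≤ tD ≤ tRt` holds by construction; every metric is
invariant to multiplying the whole trace by a positive constant, which is
why normalization conventions cannot affect the results.

Note the RCSA estimator is a raw extremum: with heavy per-frame area noise
it is biased outward by the expected maximum of the noise.  Measured on
rendered trials, segmentation feeds this stage area noise of only ~0.4% of
baseline (at luminance noise of 10% of the background level), where the
bias is negligible; the estimator should not be used on raw traces with
area noise of several percent without smoothing.

## Aggregation

Metrics are grouped by (body region, direction); arithmetic means are
computed on exact fractional milliseconds and rounded half-up at output.
Organ and trial counts are both reported, since responses are counted at
both levels.  The metrics CSV stores exact times so summaries recomputed
from disk equal summaries computed in memory.  The wide table mirrors the
standard layout (regions as rows, tR/tD/tRt/rD × direction as columns) with
empty cells for absent groups.

## Numerical and design choices

- Threshold comparisons use a relative tolerance of 1e-9 so constructed
  exact-crossing traces are insensitive to float rounding.
- Per-trace bootstrap streams derive from (config seed, CRC32 of
  trial/organ id): reproducible across processes, independent across
  organs.
- CSV readers use round-trip float parsing; a write→read→write cycle is
  bit-stable, and end-to-end reruns with the same config and seed produce
  bit-identical outputs.
- The frame rate is recovered from the `time_ms` column on read and rounded
  to 6 decimals to undo float division error.
- Problem sizes in the test suite are chosen to exercise the statistics at
  meaningful scale while staying desk-sized: the type-I calibration runs
  1,000 null traces × 1,000 permutations; parameter recovery renders 10
  trials × 10 organs (100 organs) at 240×240 px with luminance noise at 10%
  of the background level.

## Known limitations

- The tracker has no occlusion or split handling; crowded fields at the
  full anatomical density fragment into short tracks that the suitability
  gate drops, shrinking the analyzable fraction exactly as happens with
  real footage.
- The bootstrap assumes exchangeable (uncorrelated) noise under the null;
  autocorrelated measurement noise (e.g. global threshold flicker shared
  across organs) inflates the false-positive rate slightly and correlates
  errors between organs of the same trial.
- Detection parameters were validated only against the simulator; real
  footage will need its own threshold/area/displacement settings.
- With two flash frames removed, crossings earlier than 33 ms are
  unobservable; reported latencies are right-shifted to the first
  observable frame.
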