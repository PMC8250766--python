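"""Ground-truthed synthetic trial videos and area traces.

The study design this emulates: a squid settles in a uniformly lit white
tank, a sub-millisecond light flash saturates one or two video frames, and
the dark pigment organs (chromatophores) in the recorded skin patch respond
with a transient surface-area change — expansion (area up) or retraction
(area down) — beginning tens of milliseconds after the flash and completing
within a few hundred milliseconds.

Each simulated organ is an anti-aliased dark ellipse on a light background
whose rendered pixel area follows a piecewise-linear trajectory: flat
baseline, linear ramp to the peak, linear return to baseline.  Axes are
scaled by the square root of the area ratio so rendered *area*, not
diameter, tracks the trajectory.  Flash frames are saturated to the maximum
luminance.  Additive Gaussian luminance noise and an optional whole-field
integer jitter walk reproduce the main failure modes of real footage.

Every stochastic choice flows from a single integer seed, and identical
(config, seed) pairs produce bit-identical stacks.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .trace import (
    DIRECTIONS,
    EXPANSION,
    REGIONS,
    RETRACTION,
    AreaTrace,
    ChromodynError,
    TrialTimeline,
)

__all__ = [
    "ChromatophoreSpec",
    "SimConfig",
    "GroundTruth",
    "area_profile",
    "sample_specs",
    "render_trial",
    "simulate_traces",
    "ground_truth_traces",
    "synthetic_crossing_trace",
    "write_stack",
    "read_stack",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass
class ChromatophoreSpec:
    """Ground-truth geometry and response trajectory of one simulated organ.

    Parameters
    ----------
    organ_id : int
    center : (x, y) tuple, pixels
    aspect_ratio : float
        Semi-major over semi-minor axis length, > 0.
    baseline_area : float, pixels^2
        Pre-flash ellipse area.
    direction : {"expansion", "retraction"}
    magnitude_pct : float
        Peak area change relative to baseline, percent.  Positive for both
        directions; a retraction must stay below 100 (area cannot go
        negative).
    onset_ms, rise_ms, return_ms : float
        Response onset after the flash, ramp duration to the peak, and ramp
        duration back to baseline, milliseconds.
    responds : bool
        If False the trajectory is constant at baseline (plus rendering
        noise).
    orientation : float
        Ellipse major-axis angle, radians.
    profile : {"linear", "smooth"}
        Ramp shape; "smooth" replaces each linear ramp by a smoothstep.
    """

    organ_id: int
    center: tuple
    aspect_ratio: float
    baseline_area: float
    direction: str
    magnitude_pct: float
    onset_ms: float
    rise_ms: float
    return_ms: float
    responds: bool = True
    orientation: float = 0.0
    profile: str = "linear"

    def __post_init__(self):
        if self.baseline_area <= 0:
            raise ChromodynError("baseline_area must be > 0")
        if self.aspect_ratio <= 0:
            raise ChromodynError("aspect_ratio must be > 0")
        if self.rise_ms <= 0 or self.return_ms <= 0:
            raise ChromodynError("rise_ms and return_ms must be > 0")
        if self.direction not in DIRECTIONS:
            raise ChromodynError(f"direction must be one of {DIRECTIONS}")
        if self.magnitude_pct <= 0:
            raise ChromodynError("magnitude_pct must be > 0")
        if self.direction == RETRACTION and self.magnitude_pct >= 100:
            raise ChromodynError(
                "retraction magnitude must be < 100% (area cannot go negative)"
            )
        if self.profile not in ("linear", "smooth"):
            raise ChromodynError("profile must be 'linear' or 'smooth'")

    @property
    def peak_area(self) -> float:
        s = 1.0 if self.direction == EXPANSION else -1.0
        return self.baseline_area * (1.0 + s * self.magnitude_pct / 100.0)

    def semi_axes(self, area: float | None = None) -> tuple:
        """(a, b) semi-axis lengths in pixels for the given area."""
        area = self.baseline_area if area is None else area
        b = math.sqrt(area / (math.pi * self.aspect_ratio))
        return self.aspect_ratio * b, b


def area_profile(spec: ChromatophoreSpec, t):
    """Trajectory area in pixels^2 at time ``t`` (ms relative to the flash).

    Piecewise (default linear): baseline for ``t < onset``; ramp to the peak
    at ``onset + rise``; ramp back to baseline at ``onset + rise + return``;
    baseline thereafter.  A retraction mirrors the expansion ramp downward.
    Total function: accepts any real ``t``, scalar or array.
    """
    t = np.asarray(t, dtype=float)
    if not spec.responds:
        out = np.full(t.shape, spec.baseline_area)
        return float(out) if out.ndim == 0 else out
    rise_f = np.clip((t - spec.onset_ms) / spec.rise_ms, 0.0, 1.0)
    fall_f = np.clip(
        (t - spec.onset_ms - spec.rise_ms) / spec.return_ms, 0.0, 1.0
    )
    frac = np.where(t <= spec.onset_ms + spec.rise_ms, rise_f, 1.0 - fall_f)
    if spec.profile == "smooth":
        frac = frac * frac * (3.0 - 2.0 * frac)
    out = spec.baseline_area + frac * (spec.peak_area - spec.baseline_area)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimConfig:
    """Trial-simulation parameters.

    Geometry defaults follow squid skin: organ density 8 per mm^2 with
    baseline (mostly retracted) diameters of 120-350 um, sampled uniformly;
    the anatomical diameter range extends to 1,520 um for the largest fully
    expanded organs and can be requested via ``diameter_range_um``.  The
    flash itself lasted ~100 us at 12,500 lx in the experiments — far below
    one frame — and is modeled purely as ``flash_frame_count`` saturated
    frames (the photometric values are retained as metadata only).
    """

    frame_rate: float = 60.0
    pre_flash_frames: int = 60
    post_flash_frames: int = 60
    flash_frame_count: int = 2
    image_size: tuple = (256, 256)  # (height, width) pixels
    organ_density: float = 8.0  # organs per mm^2
    mm_per_pixel: float = 0.01
    diameter_range_um: tuple = (120.0, 350.0)
    noise_sd: float = 5.0  # luminance units (8-bit scale)
    jitter_sd: float = 0.0  # pixels/frame random-walk step SD
    region_label: str = "mantle"
    seed: int = 0
    # rendering levels (8-bit)
    background_level: float = 200.0
    organ_level: float = 30.0
    # response sampling
    respond_fraction: float = 0.9
    retraction_fraction: float = 0.016
    expansion_magnitude: tuple = (155.0, 30.0)  # mean, sd (percent)
    retraction_magnitude: tuple = (40.0, 10.0)
    onset_range_ms: tuple = (30.0, 45.0)
    rise_range_ms: tuple = (70.0, 110.0)
    return_range_ms: tuple = (150.0, 300.0)
    aspect_ratio_range: tuple = (1.0, 1.4)
    min_spacing_factor: float = 1.1
    overlap_tolerance: float = 0.0
    # stimulus metadata (not used photometrically)
    flash_duration_us: float = 100.0
    flash_illuminance_lx: float = 12500.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ChromodynError("frame_rate must be > 0")
        if self.flash_frame_count < 1:
            raise ChromodynError("flash_frame_count must be >= 1")
        if self.pre_flash_frames < 0 or self.post_flash_frames < 0:
            raise ChromodynError("frame counts must be >= 0")
        if self.region_label not in REGIONS:
            raise ChromodynError(f"region_label must be one of {REGIONS}")
        if self.mm_per_pixel <= 0 or self.organ_density < 0:
            raise ChromodynError("invalid scale or density")

    @property
    def n_frames(self) -> int:
        return (
            self.pre_flash_frames
            + self.flash_frame_count
            + self.post_flash_frames
        )

    @property
    def flash_frame_index(self) -> int:
        return self.pre_flash_frames

    @property
    def flash_frames(self) -> frozenset:
        return frozenset(
            range(
                self.flash_frame_index,
                self.flash_frame_index + self.flash_frame_count,
            )
        )

    def timeline(self) -> TrialTimeline:
        return TrialTimeline(
            frame_rate=self.frame_rate,
            n_frames=self.n_frames,
            flash_frame_index=self.flash_frame_index,
            excluded_frames=self.flash_frames,
        )

    @property
    def field_area_mm2(self) -> float:
        h, w = self.image_size
        return h * w * self.mm_per_pixel**2


@dataclass
class GroundTruth:
    """Exact per-organ specs and per-frame areas for a simulated trial."""

    specs: list
    areas: np.ndarray  # (n_organs, n_frames) pixels^2
    flash_frame_index: int

    def to_dict(self) -> dict:
        return {
            "flash_frame_index": self.flash_frame_index,
            "specs": [asdict(s) for s in self.specs],
            "areas": np.asarray(self.areas).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        specs = []
        for s in d["specs"]:
            s = dict(s)
            s["center"] = tuple(s["center"])
            specs.append(ChromatophoreSpec(**s))
        return cls(
            specs=specs,
            areas=np.asarray(d["areas"], dtype=float),
            flash_frame_index=int(d["flash_frame_index"]),
        )


def _sample_spec_params(config: SimConfig, rng, organ_id, center, diam_px):
    aspect = rng.uniform(*config.aspect_ratio_range)
    orientation = rng.uniform(0.0, math.pi)
    # diameter is the major axis; area of an ellipse with semi-axes a, a/q
    a = diam_px / 2.0
    baseline_area = math.pi * a * (a / aspect)
    responds = bool(rng.random() < config.respond_fraction)
    retracting = bool(rng.random() < config.retraction_fraction)
    if retracting:
        mu, sd = config.retraction_magnitude
        mag = float(np.clip(rng.normal(mu, sd), 5.0, 95.0))
        direction = RETRACTION
    else:
        mu, sd = config.expansion_magnitude
        mag = float(np.clip(rng.normal(mu, sd), 20.0, 400.0))
        direction = EXPANSION
    return ChromatophoreSpec(
        organ_id=organ_id,
        center=center,
        aspect_ratio=aspect,
        baseline_area=baseline_area,
        direction=direction,
        magnitude_pct=mag,
        onset_ms=float(rng.uniform(*config.onset_range_ms)),
        rise_ms=float(rng.uniform(*config.rise_range_ms)),
        return_ms=float(rng.uniform(*config.return_range_ms)),
        responds=responds,
        orientation=orientation,
    )


def sample_specs(config: SimConfig, rng=None) -> list:
    """Sample organ specs at the configured density.

    Organ count is ``round(density × field area)``.  Centers are
    rejection-sampled so baseline footprints keep a minimum spacing and the
    maximally expanded footprint stays inside the image; an impossible
    request (field too small for the density) raises.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(config.organ_density * config.field_area_mm2))
    if n == 0:
        return []
    h, w = config.image_size
    lo_px = config.diameter_range_um[0] / 1000.0 / config.mm_per_pixel
    hi_px = config.diameter_range_um[1] / 1000.0 / config.mm_per_pixel
    # sample every organ's geometry and response first so the placement
    # margin can use its actual expanded footprint; place large organs
    # first (greatly improves packing at the study's density)
    protos = [
        _sample_spec_params(
            config, rng, i, (0.0, 0.0), float(rng.uniform(lo_px, hi_px))
        )
        for i in range(n)
    ]
    protos.sort(key=lambda s: -s.baseline_area)
    specs = []
    centers = []
    radii = []
    max_tries = 2000 * n
    tries = 0
    for organ_id, proto in enumerate(protos):
        eff_peak = proto.peak_area if proto.responds else proto.baseline_area
        a_peak, _ = proto.semi_axes(max(eff_peak, proto.baseline_area))
        a_base, _ = proto.semi_axes()
        margin = a_peak + 1.0
        if 2 * margin >= min(h, w):
            raise ChromodynError(
                "field too small for requested density/diameter range"
            )
        placed = False
        while tries < max_tries:
            tries += 1
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            ok = all(
                math.hypot(cx - px, cy - py)
                >= config.min_spacing_factor * (a_base + pr)
                for (px, py), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cx, cy))
                radii.append(a_base)
                proto.organ_id = organ_id
                proto.center = (cx, cy)
                specs.append(proto)
                placed = True
                break
        if not placed:
            raise ChromodynError(
                "field too small for requested density: could not place "
                f"organ {len(specs) + 1} of {n}"
            )
    return specs


# ---------------------------------------------------------------------------
# rendering


def _ellipse_coverage(shape, cx, cy, a, b, theta, oversample=4):
    """Fractional per-pixel coverage of an ellipse, on its bounding box.

    Returns (y0, x0, cov) where ``cov`` covers the clipped bounding box.
    Pixel centers sit at integer coordinates; each pixel is subdivided
    ``oversample``^2 times.
    """
    h, w = shape
    r = max(a, b) + 1.0
    x0 = max(int(math.floor(cx - r)), 0)
    x1 = min(int(math.ceil(cx + r)) + 1, w)
    y0 = max(int(math.floor(cy - r)), 0)
    y1 = min(int(math.ceil(cy + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return y0, x0, np.zeros((0, 0))
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    xs = (np.arange(x0, x1)[:, None] + sub[None, :]).ravel() - cx
    ys = (np.arange(y0, y1)[:, None] + sub[None, :]).ravel() - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = xs[None, :] * ct + ys[:, None] * st
    v = -xs[None, :] * st + ys[:, None] * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ny, nx = y1 - y0, x1 - x0
    cov = inside.reshape(ny, oversample, nx, oversample).mean(axis=(1, 3))
    return y0, x0, cov


def _warn_on_overlap(specs, tolerance):
    """Warn when expanded footprints may overlap beyond the tolerance."""
    for i, si in enumerate(specs):
        ai = max(si.semi_axes(si.peak_area if si.responds else None))
        for sj in specs[i + 1 :]:
            aj = max(sj.semi_axes(sj.peak_area if sj.responds else None))
            d = math.hypot(
                si.center[0] - sj.center[0], si.center[1] - sj.center[1]
            )
            if d < (1.0 - tolerance) * (ai + aj):
                warnings.warn(
                    f"organs {si.organ_id} and {sj.organ_id} may overlap "
                    "when expanded",
                    stacklevel=3,
                )
                return


def render_trial(config: SimConfig, specs: list | None = None):
    """Render a full trial stack and its ground truth.

    Returns ``(stack, GroundTruth)`` with ``stack`` a uint8 array of shape
    (n_frames, height, width).  Flash frames are saturated to 255.  Organs
    whose maximally expanded footprint falls outside the image raise; mere
    overlap between organs only warns.
    """
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs = sample_specs(config, rng)
    h, w = config.image_size
    timeline = config.timeline()
    times = timeline.frame_times()
    n = config.n_frames

    for s in specs:
        eff_peak = s.peak_area if s.responds else s.baseline_area
        a, _ = s.semi_axes(max(eff_peak, s.baseline_area))
        cx, cy = s.center
        if (
            cx - a < 0
            or cx + a > w - 1
            or cy - a < 0
            or cy + a > h - 1
        ):
            raise ChromodynError(
                f"organ {s.organ_id} footprint does not fit inside the image"
            )
    _warn_on_overlap(specs, config.overlap_tolerance)

    gt_areas = np.array(
        [area_profile(s, times) for s in specs], dtype=float
    ).reshape(len(specs), n)

    # whole-field integer jitter as a rounded Gaussian random walk
    if config.jitter_sd > 0:
        steps = rng.normal(0.0, config.jitter_sd, size=(n, 2))
        offsets = np.rint(np.cumsum(steps, axis=0)).astype(int)
    else:
        offsets = np.zeros((n, 2), dtype=int)

    stack = np.empty((n, h, w), dtype=np.uint8)
    bg, fg = config.background_level, config.organ_level
    for k in range(n):
        if k in config.flash_frames:
            # the flash saturates the sensor; noise is clipped away
            stack[k] = 255
            continue
        else:
            cov = np.zeros((h, w))
            for i, s in enumerate(specs):
                aa, bb = s.semi_axes()
                scale = math.sqrt(gt_areas[i, k] / s.baseline_area)
                cx = s.center[0] + offsets[k, 0]
                cy = s.center[1] + offsets[k, 1]
                y0, x0, c = _ellipse_coverage(
                    (h, w), cx, cy, aa * scale, bb * scale, s.orientation
                )
                if c.size:
                    sl = (slice(y0, y0 + c.shape[0]), slice(x0, x0 + c.shape[1]))
                    np.maximum(cov[sl], c, out=cov[sl])
            frame = bg - (bg - fg) * cov
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, size=(h, w))
        stack[k] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        specs=list(specs),
        areas=gt_areas,
        flash_frame_index=config.flash_frame_index,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# bare area traces (no rendering)


def ground_truth_traces(gt: GroundTruth, config: SimConfig, trial_id="sim"):
    """Exact ground-truth area traces (flash frames masked)."""
    timeline = config.timeline()
    return [
        AreaTrace(
            trial_id=trial_id,
            organ_id=s.organ_id,
            region=config.region_label,
            timeline=timeline,
            areas=gt.areas[i],
            centroid=s.center,
        )
        for i, s in enumerate(gt.specs)
    ]


def simulate_traces(
    config: SimConfig,
    specs: list | None = None,
    area_noise_frac: float = 0.0,
    trial_id: str = "sim",
):
    """Generate per-organ area traces directly, bypassing rendering.

    ``area_noise_frac`` is the SD of additive Gaussian area noise as a
    fraction of each organ's baseline area.  Returns
    ``(traces, GroundTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs = sample_specs(config, rng)
    timeline = config.timeline()
    times = timeline.frame_times()
    n = config.n_frames
    gt_areas = np.array(
        [area_profile(s, times) for s in specs], dtype=float
    ).reshape(len(specs), n)
    traces = []
    for i, s in enumerate(specs):
        areas = gt_areas[i].copy()
        if area_noise_frac > 0:
            areas = areas + rng.normal(
                0.0, area_noise_frac * s.baseline_area, size=n
            )
        areas = np.maximum(areas, 1e-6)
        traces.append(
            AreaTrace(
                trial_id=trial_id,
                organ_id=s.organ_id,
                region=config.region_label,
                timeline=timeline,
                areas=areas,
                centroid=s.center,
            )
        )
    gt = GroundTruth(
        specs=list(specs),
        areas=gt_areas,
        flash_frame_index=config.flash_frame_index,
    )
    return traces, gt


def synthetic_crossing_trace(
    peak: float,
    rise5_frame: int,
    rise50_frame: int,
    peak_frame: int,
    fall5_frame: int,
    baseline_cycle=(98.0, 101.0, 100.0, 99.0, 102.0),
    pre_flash_frames: int = 30,
    post_flash_frames: int = 40,
    flash_frame_count: int = 2,
    frame_rate: float = 60.0,
    trial_id: str = "constructed",
    organ_id: int = 0,
    region: str = "mantle",
) -> AreaTrace:
    """Construct a trace with exactly controlled threshold-crossing frames.

    Frame arguments are post-flash frame numbers (0 = first flash frame).
    The trace first reaches the 5%-of-response threshold at ``rise5_frame``,
    the 50% threshold at ``rise50_frame``, peaks at ``peak_frame`` and first
    returns inside the 5% threshold at ``fall5_frame``.  The pre-flash
    baseline repeats ``baseline_cycle`` (its mean defines the baseline
    level).  ``peak`` below the baseline mean builds a retraction trace.
    """
    if not (
        flash_frame_count <= rise5_frame < rise50_frame < peak_frame < fall5_frame
    ):
        raise ChromodynError("crossing frames must be strictly ordered")
    if fall5_frame >= post_flash_frames:
        raise ChromodynError("fall5_frame outside post-flash window")
    cycle = np.asarray(baseline_cycle, dtype=float)
    b = float(cycle.mean())
    dev = peak - b
    if dev == 0:
        raise ChromodynError("peak must differ from the baseline mean")
    n_post = post_flash_frames
    frac = np.zeros(n_post + flash_frame_count)
    knots_k = [rise5_frame, rise50_frame, peak_frame, fall5_frame]
    knots_f = [0.10, 0.55, 1.00, 0.04]
    for k in range(flash_frame_count, len(frac)):
        if k < rise5_frame:
            frac[k] = 0.0
        elif k <= fall5_frame:
            frac[k] = float(np.interp(k, knots_k, knots_f))
        else:
            frac[k] = 0.0
    n = pre_flash_frames + flash_frame_count + post_flash_frames
    areas = np.empty(n)
    reps = int(np.ceil(pre_flash_frames / len(cycle)))
    areas[:pre_flash_frames] = np.tile(cycle, reps)[:pre_flash_frames]
    # flash frames (masked below) and the pre-crossing post-flash frames
    # sit exactly at the baseline mean
    areas[pre_flash_frames : pre_flash_frames + flash_frame_count] = b
    areas[pre_flash_frames + flash_frame_count :] = (
        b + dev * frac[flash_frame_count:]
    )
    timeline = TrialTimeline(
        frame_rate=frame_rate,
        n_frames=n,
        flash_frame_index=pre_flash_frames,
        excluded_frames=frozenset(
            range(pre_flash_frames, pre_flash_frames + flash_frame_count)
        ),
    )
    return AreaTrace(
        trial_id=trial_id,
        organ_id=organ_id,
        region=region,
        timeline=timeline,
        areas=areas,
    )


# ---------------------------------------------------------------------------
# I/O


def write_stack(stack: np.ndarray, path) -> None:
    """Write a stack as a multi-page TIFF (``.tif``/``.tiff``) or, given a
    directory, as a numbered 8-bit PNG sequence (``frame_0000.png`` ...)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{k:04d}.png", frame)


def read_stack(path) -> np.ndarray:
    """Read a TIFF stack or a numbered PNG/TIFF sequence directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ChromodynError(f"no image files in {path}")
        return np.stack([iio.imread(p) for p in files])
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def save_ground_truth(gt: GroundTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(gt.to_dict()))


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
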