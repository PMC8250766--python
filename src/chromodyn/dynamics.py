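"""Temporal-dynamics and magnitude metrics for significant responses.

For each responding organ the metrics are defined relative to the baseline
chromatophore surface area (BCSA, the pre-flash mean) and the response peak
(RCSA, the post-flash extremum):

- ``tR`` (response time): time of the first post-flash frame whose area
  reaches or passes 5% of the maximal response deviation;
- ``tD`` (delay time): likewise at the 50% level;
- ``tRt`` (rise time): time of the response peak (100%);
- ``rD`` (response duration): time between the 5%-level points before and
  after the peak;
- ``magnitude_pct``: percent change of RCSA versus BCSA, reported positive
  for both expansion and retraction.

"Reach or pass" is evaluated frame-by-frame with no sub-frame
interpolation, because recorded times are quantized to the inter-frame
interval (16.67 ms at 60 fps).  Times are kept as exact fractions
``k × 1000 / frame_rate`` internally and rounded half-up to integer
milliseconds only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import (
    DIRECTIONS,
    EXPANSION,
    RETRACTION,
    AreaTrace,
    ChromodynError,
    round_half_up,
)

__all__ = [
    "BaselineStats",
    "ResponsePeak",
    "DynamicsMetrics",
    "InconsistentPeakError",
    "baseline_stats",
    "find_peak",
    "compute_metrics",
    "magnitude",
    "analyze_trace",
    "metrics_to_frame",
    "write_metrics",
    "read_metrics",
]

#: Response levels (fractions of the peak deviation) defining tR, tD, tRt.
LEVELS = (0.05, 0.50, 1.0)

#: Peak deviation must exceed this many baseline SDs to count as a response.
NOISE_FLOOR_SD = 3.0

_TOL = 1e-9


class InconsistentPeakError(ChromodynError):
    """The declared peak is not reachable through the threshold sequence."""


@dataclass
class BaselineStats:
    """Pre-flash baseline area statistics (BCSA)."""

    bcsa_mean: float
    bcsa_sd: float
    window: tuple  # (start_frame, stop_frame), stop exclusive

    def __post_init__(self):
        if self.bcsa_mean <= 0:
            raise ChromodynError("bcsa_mean must be > 0")


@dataclass
class ResponsePeak:
    """Post-flash response extremum (RCSA)."""

    rcsa_peak: float
    peak_frame: int
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ChromodynError(f"direction must be one of {DIRECTIONS}")


@dataclass
class DynamicsMetrics:
    """Timing (exact ms) and magnitude of one organ's response.

    Times are exact multiples of the inter-frame interval; use
    :meth:`report` for the integer-millisecond form.
    """

    trial_id: str
    organ_id: int
    region: str
    direction: str
    tR_ms: float
    tD_ms: float
    tRt_ms: float
    rD_ms: float  # NaN when valid_rD is False
    valid_rD: bool
    magnitude_pct: float
    bcsa_mean: float
    rcsa_peak: float
    peak_frame: int

    def report(self) -> dict:
        """Times rounded half-up to integer ms, as printed in summaries."""
        return {
            "trial_id": self.trial_id,
            "organ_id": self.organ_id,
            "region": self.region,
            "direction": self.direction,
            "tR_ms": round_half_up(self.tR_ms),
            "tD_ms": round_half_up(self.tD_ms),
            "tRt_ms": round_half_up(self.tRt_ms),
            "rD_ms": round_half_up(self.rD_ms) if self.valid_rD else None,
            "valid_rD": self.valid_rD,
            "magnitude_pct": self.magnitude_pct,
            "bcsa_mean": self.bcsa_mean,
            "rcsa_peak": self.rcsa_peak,
        }


def baseline_stats(trace: AreaTrace, window: tuple | None = None) -> BaselineStats:
    """BCSA mean and sample SD over a pre-flash frame window.

    ``window`` is ``(start, stop)`` with exclusive stop, defaulting to the
    whole pre-flash span; it must lie entirely before the flash and contain
    at least 5 present values.
    """
    flash = trace.timeline.flash_frame_index
    if window is None:
        window = (0, flash)
    start, stop = window
    if stop > flash or start < 0 or start >= stop:
        raise ChromodynError("baseline window must lie entirely pre-flash")
    v = trace.areas[start:stop]
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ChromodynError("baseline window needs >= 5 present values")
    return BaselineStats(
        bcsa_mean=float(v.mean()),
        bcsa_sd=float(v.std(ddof=1)),
        window=(start, stop),
    )


def find_peak(
    trace: AreaTrace,
    baseline: BaselineStats,
    window: tuple | None = None,
) -> ResponsePeak | None:
    """Locate the post-flash response extremum (RCSA).

    The expansion candidate is the maximum present value in the window, the
    retraction candidate the minimum; the direction with the larger absolute
    deviation from BCSA wins and must exceed ``3 × baseline SD`` (the noise
    floor), otherwise ``None`` is returned ("no response" — not an error).
    """
    tl = trace.timeline
    post = tl.post_flash_frames()
    if window is not None:
        post = post[(post >= window[0]) & (post < window[1])]
    post = post[~np.isnan(trace.areas[post])]
    if post.size == 0:
        raise ChromodynError("post-flash window is empty")
    vals = trace.areas[post]
    k_max, k_min = post[int(vals.argmax())], post[int(vals.argmin())]
    dev_up = trace.areas[k_max] - baseline.bcsa_mean
    dev_down = baseline.bcsa_mean - trace.areas[k_min]
    if dev_up >= dev_down:
        dev, k, direction = dev_up, k_max, EXPANSION
    else:
        dev, k, direction = dev_down, k_min, RETRACTION
    if dev <= NOISE_FLOOR_SD * baseline.bcsa_sd or dev <= 0:
        return None
    return ResponsePeak(
        rcsa_peak=float(trace.areas[k]), peak_frame=int(k), direction=direction
    )


def magnitude(baseline: BaselineStats, peak: ResponsePeak) -> float:
    """Percent magnitude of the response, positive for both directions.

    Expansion: ``100 × (RCSA - BCSA) / BCSA``; retraction:
    ``100 × (BCSA - RCSA) / BCSA``.
    """
    if baseline.bcsa_mean <= 0:
        raise ChromodynError("bcsa_mean must be > 0")
    if peak.direction == EXPANSION:
        return 100.0 * (peak.rcsa_peak - baseline.bcsa_mean) / baseline.bcsa_mean
    return 100.0 * (baseline.bcsa_mean - peak.rcsa_peak) / baseline.bcsa_mean


def compute_metrics(
    trace: AreaTrace,
    baseline: BaselineStats,
    peak: ResponsePeak,
) -> DynamicsMetrics:
    """Timing metrics from threshold crossings of the response levels.

    Thresholds are ``BCSA + f × (RCSA - BCSA)`` for f in {0.05, 0.50, 1.0},
    with the deviation signed by the response direction.  ``tR``/``tD`` are
    the times of the first post-flash frames at or beyond the 5%/50%
    thresholds, ``tRt`` the peak-frame time, and ``rD`` the time from the
    rising 5% point to the first post-peak frame back at or inside the 5%
    threshold (``valid_rD`` is False when the trace never returns inside it).
    """
    tl = trace.timeline
    b = baseline.bcsa_mean
    dev = peak.rcsa_peak - b
    sign = 1.0 if peak.direction == EXPANSION else -1.0
    if sign * dev <= 0:
        raise InconsistentPeakError("peak deviation inconsistent with direction")
    scale = max(abs(peak.rcsa_peak), abs(b), 1.0)

    post = tl.post_flash_frames()
    post = post[~np.isnan(trace.areas[post])]
    rising = post[post <= peak.peak_frame]

    def first_at_or_past(frames, level):
        thr = b + level * dev
        for k in frames:
            if sign * (trace.areas[k] - thr) >= -_TOL * scale:
                return int(k)
        return None

    k5 = first_at_or_past(rising, 0.05)
    k50 = first_at_or_past(rising, 0.50)
    if k5 is None or k50 is None:
        raise InconsistentPeakError(
            "thresholds never crossed before the declared peak"
        )
    tR = tl.frame_time(k5)
    tD = tl.frame_time(k50)
    tRt = tl.frame_time(peak.peak_frame)

    falling = post[post > peak.peak_frame]
    thr5 = b + 0.05 * dev
    k_fall = None
    for k in falling:
        if sign * (trace.areas[k] - thr5) <= _TOL * scale:
            k_fall = int(k)
            break
    valid_rD = k_fall is not None
    rD = tl.frame_time(k_fall) - tR if valid_rD else float("nan")

    return DynamicsMetrics(
        trial_id=trace.trial_id,
        organ_id=trace.organ_id,
        region=trace.region,
        direction=peak.direction,
        tR_ms=tR,
        tD_ms=tD,
        tRt_ms=tRt,
        rD_ms=rD,
        valid_rD=valid_rD,
        magnitude_pct=magnitude(baseline, peak),
        bcsa_mean=b,
        rcsa_peak=peak.rcsa_peak,
        peak_frame=peak.peak_frame,
    )


def analyze_trace(
    trace: AreaTrace,
    baseline_window: tuple | None = None,
    response_window: tuple | None = None,
) -> DynamicsMetrics | None:
    """Baseline → peak → metrics for one trace; None when no response."""
    baseline = baseline_stats(trace, baseline_window)
    peak = find_peak(trace, baseline, response_window)
    if peak is None:
        return None
    return compute_metrics(trace, baseline, peak)


METRIC_COLUMNS = [
    "trial_id",
    "organ_id",
    "region",
    "direction",
    "tR_ms",
    "tD_ms",
    "tRt_ms",
    "rD_ms",
    "valid_rD",
    "magnitude_pct",
    "bcsa_mean",
    "rcsa_peak",
]


def metrics_to_frame(metrics: list, rounded: bool = False) -> pd.DataFrame:
    """Metrics as a DataFrame.

    By default times are the exact fractional milliseconds; rounding to
    integer ms happens once, at summary reporting (``rounded=True`` gives
    the printed form).
    """
    if rounded:
        rows = [m.report() for m in metrics]
    else:
        rows = [
            {
                "trial_id": m.trial_id,
                "organ_id": m.organ_id,
                "region": m.region,
                "direction": m.direction,
                "tR_ms": m.tR_ms,
                "tD_ms": m.tD_ms,
                "tRt_ms": m.tRt_ms,
                "rD_ms": m.rD_ms,
                "valid_rD": m.valid_rD,
                "magnitude_pct": m.magnitude_pct,
                "bcsa_mean": m.bcsa_mean,
                "rcsa_peak": m.rcsa_peak,
            }
            for m in metrics
        ]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics(metrics: list, path) -> None:
    metrics_to_frame(metrics).to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ChromodynError(f"metrics CSV missing columns: {sorted(missing)}")
    return df
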