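"""CUSUM change-point analysis with bootstrap significance.

This is the inclusion gate of the pipeline: an organ's area trace counts as
a response only if a change-point analysis (CPA) finds a significant mean
shift located after the flash.

The statistic is the classic CUSUM of deviations from the series mean,
``S_i = S_{i-1} + (x_i - mean)`` with ``S_0 = 0``, whose range
``s_diff = max(S) - min(S)`` measures how far the running mass of the
series departs from homogeneity.  Significance is assessed by a permutation
bootstrap: the confidence level is the fraction of random reorderings of
the series whose ``s_diff`` falls strictly below the observed one.  The
estimated change point is the index of max |S|; the new regime starts at
that observation.

For a flash-locked transient (baseline, ramp up, return) the dominant CUSUM
extremum sits at the response onset whenever the pre-flash baseline is at
least as long as the response, which the default trial windows guarantee.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import AreaTrace, ChromodynError

__all__ = [
    "CusumProfile",
    "ChangePointConfig",
    "ChangePointResult",
    "cusum",
    "bootstrap_confidence",
    "detect_change",
    "detect_changes",
    "write_changepoints",
    "read_changepoints",
]

MIN_SERIES = 4


@dataclass
class CusumProfile:
    """Cumulative-sum profile of a series."""

    S: np.ndarray  # length n+1, S[0] = 0
    s_diff: float  # max(S) - min(S)
    argmax_abs: int  # index of max |S| (first on ties)


@dataclass
class ChangePointConfig:
    threshold: float = 0.95  # bootstrap confidence needed for significance
    n_boot: int = 1000
    window_frames: int = 30  # post-flash acceptance window for the change
    seed: int = 0


@dataclass
class ChangePointResult:
    trial_id: str
    organ_id: int
    confidence: float
    significant: bool
    change_frame: int
    direction_hint: float  # sign of (post-change mean - pre-change mean)


def _clean(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ChromodynError("series must be 1-D")
    if np.isnan(x).any():
        raise ChromodynError("series contains missing values; drop them first")
    if x.size < MIN_SERIES:
        raise ChromodynError(f"series needs >= {MIN_SERIES} values, got {x.size}")
    return x


def cusum(series) -> CusumProfile:
    """CUSUM profile of a series (missing values must be dropped first)."""
    x = _clean(series)
    S = np.concatenate([[0.0], np.cumsum(x - x.mean())])
    return CusumProfile(
        S=S,
        s_diff=float(S.max() - S.min()),
        argmax_abs=int(np.argmax(np.abs(S))),
    )


def _sdiff_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise s_diff for a matrix of series (S_0 = 0 included)."""
    dev = mat - mat.mean(axis=1, keepdims=True)
    S = np.cumsum(dev, axis=1)
    return np.maximum(S.max(axis=1), 0.0) - np.minimum(S.min(axis=1), 0.0)


def bootstrap_confidence(
    series, n_boot: int = 1000, seed=None, rng=None
) -> float:
    """Bootstrap confidence that the series contains a change.

    The fraction of ``n_boot`` random permutations (without replacement) of
    the series whose CUSUM range is strictly less than the observed range.
    A constant series has observed range 0, hence confidence 0.
    """
    if n_boot < 100:
        raise ChromodynError("n_boot must be >= 100")
    x = _clean(series)
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = cusum(x).s_diff
    perms = rng.permuted(np.tile(x, (n_boot, 1)), axis=1)
    return float(np.mean(_sdiff_rows(perms) < obs))


def _trace_rng(config: ChangePointConfig, trace: AreaTrace):
    # stable per-trace stream: crc32 keeps the derived key reproducible
    # across processes (unlike hash())
    key = zlib.crc32(f"{trace.trial_id}/{trace.organ_id}".encode())
    return np.random.default_rng([config.seed, key])


def detect_change(
    trace: AreaTrace, config: ChangePointConfig | None = None, rng=None
) -> ChangePointResult:
    """Run CPA on one area trace.

    Missing values (flash frames, undetected frames) are removed before the
    CUSUM; the change frame is reported in original frame indexing as the
    first frame of the new regime.  The result is significant only if the
    bootstrap confidence reaches the threshold *and* the change frame falls
    after the flash, within the acceptance window.
    """
    config = config or ChangePointConfig()
    frames = trace.present_frames()
    x = trace.areas[frames]
    if x.size < MIN_SERIES:
        raise ChromodynError("trace too short for change-point analysis")
    profile = cusum(x)
    if rng is None:
        rng = _trace_rng(config, trace)
    confidence = bootstrap_confidence(x, config.n_boot, rng=rng)
    i = int(np.clip(profile.argmax_abs, 1, x.size - 1))
    change_frame = int(frames[i])
    pre, post = x[:i], x[i:]
    direction_hint = float(np.sign(post.mean() - pre.mean()))
    flash = trace.timeline.flash_frame_index
    in_window = flash < change_frame <= flash + config.window_frames
    return ChangePointResult(
        trial_id=trace.trial_id,
        organ_id=trace.organ_id,
        confidence=confidence,
        significant=bool(confidence >= config.threshold and in_window),
        change_frame=change_frame,
        direction_hint=direction_hint,
    )


def detect_changes(traces, config: ChangePointConfig | None = None) -> list:
    """CPA over a list of traces with independent per-trace random streams."""
    config = config or ChangePointConfig()
    return [detect_change(tr, config) for tr in traces]


CP_COLUMNS = [
    "trial_id",
    "organ_id",
    "confidence",
    "significant",
    "change_frame",
    "direction_hint",
]


def write_changepoints(results, path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "organ_id": r.organ_id,
                "confidence": r.confidence,
                "significant": int(r.significant),
                "change_frame": r.change_frame,
                "direction_hint": r.direction_hint,
            }
            for r in results
        ],
        columns=CP_COLUMNS,
    ).to_csv(path, index=False)


def read_changepoints(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ChangePointResult(
            trial_id=str(r.trial_id),
            organ_id=int(r.organ_id),
            confidence=float(r.confidence),
            significant=bool(r.significant),
            change_frame=int(r.change_frame),
            direction_hint=float(r.direction_hint),
        )
        for r in df.itertuples()
    ]
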