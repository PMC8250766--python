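"""Core containers shared across the pipeline.

A trial is a fixed-length grayscale frame sequence recorded at a known frame
rate, containing a block of one or more flash-saturated frames.  The
:class:`TrialTimeline` pins every frame index ``k`` to an exact time
``(k - flash_frame_index) * 1000 / frame_rate`` milliseconds, so the first
flash frame is ``t = 0`` by definition.  Flash frames (and any other frames a
stage decides to drop) live in ``excluded_frames`` and carry no area values.

An :class:`AreaTrace` is one chromatophore organ's per-frame surface area, in
pixels squared, across a trial.  Missing values (excluded or undetected
frames) are stored as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: Canonical body-region labels: head/arms, mantle and dorsal fin are the
#: three recorded skin areas, innervated by different brain chromatophore
#: lobes.
REGIONS = ("head_arms", "mantle", "fin")

EXPANSION = "expansion"
RETRACTION = "retraction"
DIRECTIONS = (EXPANSION, RETRACTION)


class ChromodynError(ValueError):
    """Raised for invalid inputs or impossible configurations."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with ties going away from zero upward.

    Reported times are exact multiples of 1000/frame_rate ms internally and
    are quantized to integer milliseconds only at output; half-up rounding
    maps 116.67 -> 117 and 216.67 -> 217.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TrialTimeline:
    """Frame-index to exact-time mapping for one trial.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames per second (default experiments: 60).
    n_frames : int
        Total frame count of the trial.
    flash_frame_index : int
        Index of the first flash-saturated frame; defines ``t = 0``.
    excluded_frames : frozenset of int
        Frames removed from analysis.  The flash frames are always members.
    """

    frame_rate: float
    n_frames: int
    flash_frame_index: int
    excluded_frames: frozenset = frozenset()

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ChromodynError("frame_rate must be positive")
        if not 0 <= self.flash_frame_index < self.n_frames:
            raise ChromodynError("flash_frame_index outside trial")
        excl = frozenset(int(k) for k in self.excluded_frames)
        excl |= {self.flash_frame_index}
        if any(k < 0 or k >= self.n_frames for k in excl):
            raise ChromodynError("excluded frame outside trial")
        object.__setattr__(self, "excluded_frames", excl)

    @property
    def dt_ms(self) -> float:
        """Exact inter-frame interval in milliseconds (16.67 ms at 60 fps)."""
        return 1000.0 / self.frame_rate

    def frame_time(self, k: int) -> float:
        """Exact time of frame ``k`` in ms relative to the flash."""
        return (k - self.flash_frame_index) * 1000.0 / self.frame_rate

    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) - self.flash_frame_index) * (
            1000.0 / self.frame_rate
        )

    def pre_flash_frames(self) -> np.ndarray:
        """Indices strictly before the flash, excluded frames removed."""
        k = np.arange(0, self.flash_frame_index)
        return k[~np.isin(k, sorted(self.excluded_frames))]

    def post_flash_frames(self) -> np.ndarray:
        """Indices after the flash block, excluded frames removed."""
        k = np.arange(self.flash_frame_index + 1, self.n_frames)
        return k[~np.isin(k, sorted(self.excluded_frames))]


@dataclass
class AreaTrace:
    """One organ's surface-area time series across a trial.

    ``areas`` has one entry per frame; NaN marks excluded or undetected
    frames.  All present areas must be strictly positive.
    """

    trial_id: str
    organ_id: int
    region: str
    timeline: TrialTimeline
    areas: np.ndarray
    centroid: tuple | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ChromodynError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        areas = np.asarray(self.areas, dtype=float).copy()
        if areas.ndim != 1 or len(areas) != self.timeline.n_frames:
            raise ChromodynError(
                "areas length must equal the trial frame count "
                f"({len(areas)} != {self.timeline.n_frames})"
            )
        excl = sorted(self.timeline.excluded_frames)
        areas[excl] = np.nan
        present = ~np.isnan(areas)
        if np.any(areas[present] <= 0):
            raise ChromodynError("all present areas must be > 0")
        self.areas = areas

    # -- convenience views -------------------------------------------------

    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.areas)

    def present_frames(self) -> np.ndarray:
        return np.flatnonzero(self.present_mask)

    def pre_flash_values(self) -> np.ndarray:
        k = self.timeline.pre_flash_frames()
        v = self.areas[k]
        return v[~np.isnan(v)]

    def pre_flash_mean(self) -> float:
        v = self.pre_flash_values()
        if v.size == 0:
            raise ChromodynError("trace has no present pre-flash values")
        return float(v.mean())

    def normalized(self) -> "AreaTrace":
        """Rescale so the pre-flash mean area is exactly 1.

        This is the plotting convention for relative surface area (1 = mean
        pre-flash area; values above 1 = expansion, below 1 = retraction).
        Idempotent: normalizing a normalized trace is the identity.
        """
        return replace(self, areas=self.areas / self.pre_flash_mean())
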