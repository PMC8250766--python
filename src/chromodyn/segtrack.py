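"""Flash detection, per-frame segmentation, and track linking.

Chromatophores appear as dark regions on the light tank background, so
segmentation thresholds each frame (Otsu by default, a fixed threshold for
controlled tests), labels connected components and filters them by area.
Tracks are built by greedy nearest-centroid assignment frame to frame;
flash frames are skipped without a gap penalty.  Every track becomes an
:class:`~chromodyn.trace.AreaTrace` with NaN at frames where the organ was
not detected.

Coordinate conventions: 0-based frame indices, pixel centers at integer
coordinates, blob centroids as (x, y), areas in pixels^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .trace import AreaTrace, ChromodynError, TrialTimeline

__all__ = [
    "Blob",
    "SegmentationParams",
    "LinkParams",
    "detect_flash_onset",
    "segment_frame",
    "segment_stack",
    "link_tracks",
    "filter_usable",
    "read_traces",
    "write_traces",
]

TRACE_COLUMNS = [
    "trial_id",
    "organ_id",
    "region",
    "frame",
    "time_ms",
    "area_px2",
    "excluded",
]


@dataclass(frozen=True)
class Blob:
    """One connected dark component in one frame."""

    centroid: tuple  # (x, y) pixels
    area: float  # pixels^2
    frame: int


@dataclass
class SegmentationParams:
    method: str = "otsu"  # {"otsu", "fixed"}
    fixed_threshold: float | None = None
    min_area: float = 20.0
    max_area: float = math.inf

    def __post_init__(self):
        if self.method not in ("otsu", "fixed"):
            raise ChromodynError("threshold method must be 'otsu' or 'fixed'")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ChromodynError("fixed method requires fixed_threshold")


@dataclass
class LinkParams:
    max_displacement: float = 10.0  # pixels/frame
    max_gap: int = 3  # consecutive undetected (non-excluded) frames


def detect_flash_onset(
    stack: np.ndarray,
    saturation_frac: float = 0.98,
    coverage_frac: float = 0.90,
):
    """Locate the flash-saturated frame block.

    A frame qualifies when at least ``coverage_frac`` of its pixels are at
    or above ``saturation_frac`` of the maximum pixel value.  Returns
    ``(flash_frame_index, excluded_frames)`` where the excluded set is the
    contiguous run of qualifying frames.  Raises if no frame qualifies or
    the qualifying frames are non-contiguous.
    """
    stack = np.asarray(stack)
    if stack.size == 0:
        raise ChromodynError("empty stack")
    if np.issubdtype(stack.dtype, np.integer):
        maxval = np.iinfo(stack.dtype).max
    else:
        maxval = 1.0
    sat = (stack >= saturation_frac * maxval).mean(axis=(1, 2))
    idx = np.flatnonzero(sat >= coverage_frac)
    if idx.size == 0:
        raise ChromodynError("no flash detected")
    if not np.all(np.diff(idx) == 1):
        raise ChromodynError("saturated frames are non-contiguous")
    return int(idx[0]), frozenset(int(k) for k in idx)


def segment_frame(frame: np.ndarray, params: SegmentationParams) -> list:
    """Segment dark organs in one grayscale frame.

    Pixels below the threshold are foreground; connected components outside
    ``[min_area, max_area]`` are discarded.  Returns a list of
    :class:`Blob` (frame index is filled by the caller via ``Blob.frame``
    when segmenting a stack; here it is set to -1).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or 0 in frame.shape:
        raise ChromodynError("frame must be a non-empty 2-D array")
    if frame.min() == frame.max():
        return []
    if params.method == "otsu":
        thr = threshold_otsu(frame)
    else:
        thr = params.fixed_threshold
    # dark organs: foreground at or below the threshold (Otsu assigns the
    # threshold value itself to the dark class)
    mask = frame <= thr
    labels = label(mask, connectivity=2)
    blobs = []
    for rp in regionprops(labels):
        if params.min_area <= rp.area <= params.max_area:
            cy, cx = rp.centroid
            blobs.append(Blob(centroid=(cx, cy), area=float(rp.area), frame=-1))
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def segment_stack(
    stack: np.ndarray,
    params: SegmentationParams,
    excluded_frames=frozenset(),
) -> list:
    """Per-frame blob lists for a stack; excluded frames yield empty lists."""
    out = []
    for k, frame in enumerate(stack):
        if k in excluded_frames:
            out.append([])
        else:
            out.append(
                [
                    Blob(centroid=b.centroid, area=b.area, frame=k)
                    for b in segment_frame(frame, params)
                ]
            )
    return out


class _Track:
    __slots__ = ("track_id", "frames", "last_centroid", "last_frame", "gap", "alive")

    def __init__(self, track_id, frame, blob):
        self.track_id = track_id
        self.frames = {frame: blob}
        self.last_centroid = blob.centroid
        self.last_frame = frame
        self.gap = 0
        self.alive = True


def link_tracks(
    blob_lists: list,
    timeline: TrialTimeline,
    params: LinkParams,
    trial_id: str = "trial",
    region: str = "mantle",
) -> list:
    """Link per-frame blobs into per-organ area traces.

    Greedy nearest-centroid assignment between each non-excluded frame and
    the previous state of each live track: candidate (track, blob) pairs
    within ``max_displacement`` are processed in order of increasing
    distance (ties broken by smaller track id, then blob order).  Unmatched
    blobs start new tracks; a track undetected for more than ``max_gap``
    consecutive non-excluded frames is terminated; excluded frames are
    skipped without penalty.  A merge (two tracks competing for one blob,
    with the loser left unmatched) terminates both parents and restarts the
    blob as a new track.
    """
    if len(blob_lists) != timeline.n_frames:
        raise ChromodynError("blob_lists length must equal the frame count")
    tracks: list[_Track] = []
    next_id = 0
    for k in range(timeline.n_frames):
        if k in timeline.excluded_frames:
            continue
        blobs = blob_lists[k]
        live = [t for t in tracks if t.alive]
        pairs = []
        for t in live:
            for j, b in enumerate(blobs):
                d = math.hypot(
                    t.last_centroid[0] - b.centroid[0],
                    t.last_centroid[1] - b.centroid[1],
                )
                if d <= params.max_displacement:
                    pairs.append((d, t.track_id, j))
        pairs.sort()
        assigned_tracks: dict[int, int] = {}
        assigned_blobs: dict[int, int] = {}
        for d, tid, j in pairs:
            if tid in assigned_tracks or j in assigned_blobs:
                continue
            assigned_tracks[tid] = j
            assigned_blobs[j] = tid
        # merge rule: an unmatched track whose nearest in-range blob went to
        # another track kills both tracks; the blob restarts as a new track
        merged_blobs = set()
        for t in live:
            if t.track_id in assigned_tracks:
                continue
            best = None
            for d, tid, j in pairs:
                if tid == t.track_id:
                    best = j
                    break
            if best is not None and best in assigned_blobs:
                other = assigned_blobs[best]
                for tt in live:
                    if tt.track_id in (t.track_id, other):
                        tt.alive = False
                if tt := next(
                    (x for x in live if x.track_id == other), None
                ):
                    tt.frames.pop(k, None)
                assigned_tracks.pop(other, None)
                merged_blobs.add(best)
        by_id = {t.track_id: t for t in live}
        for tid, j in assigned_tracks.items():
            t = by_id[tid]
            if not t.alive:
                continue
            b = blobs[j]
            t.frames[k] = b
            t.last_centroid = b.centroid
            t.last_frame = k
            t.gap = 0
        for t in live:
            if t.alive and t.track_id not in assigned_tracks:
                t.gap += 1
                if t.gap > params.max_gap:
                    t.alive = False
        for j, b in enumerate(blobs):
            if j not in assigned_blobs or j in merged_blobs:
                tracks.append(_Track(next_id, k, b))
                next_id += 1

    traces = []
    for t in tracks:
        areas = np.full(timeline.n_frames, np.nan)
        cents = []
        for k, b in t.frames.items():
            areas[k] = b.area
            cents.append(b.centroid)
        centroid = tuple(np.mean(cents, axis=0)) if cents else None
        traces.append(
            AreaTrace(
                trial_id=trial_id,
                organ_id=t.track_id,
                region=region,
                timeline=timeline,
                areas=areas,
                centroid=centroid,
            )
        )
    return traces


def filter_usable(
    traces: list,
    baseline_start: int = 0,
    min_post_fraction: float = 0.5,
    min_baseline_values: int = 5,
) -> list:
    """Keep tracks that span the pre-flash baseline window and at least
    ``min_post_fraction`` of the post-flash window.

    This is the suitability gate applied before change-point analysis:
    short or late-starting tracks cannot provide a baseline or a response
    window and are dropped.
    """
    out = []
    for tr in traces:
        present = tr.present_frames()
        if present.size == 0:
            continue
        tl = tr.timeline
        post = tl.post_flash_frames()
        if post.size == 0:
            continue
        span_needed = post[0] + min_post_fraction * (post[-1] - post[0])
        if (
            present[0] <= baseline_start
            and present[-1] >= span_needed
            and tr.pre_flash_values().size >= min_baseline_values
        ):
            out.append(tr)
    return out


# ---------------------------------------------------------------------------
# CSV round trip


def write_traces(traces: list, path) -> None:
    """Write traces to CSV (schema: trial_id, organ_id, region, frame,
    time_ms, area_px2, excluded).  Missing areas are written as empty cells;
    ``excluded`` marks flash/excluded frames with 1."""
    rows = []
    for tr in traces:
        tl = tr.timeline
        for k in range(tl.n_frames):
            a = tr.areas[k]
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "organ_id": tr.organ_id,
                    "region": tr.region,
                    "frame": k,
                    "time_ms": tl.frame_time(k),
                    "area_px2": a if not np.isnan(a) else np.nan,
                    "excluded": int(k in tl.excluded_frames),
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces(path) -> list:
    """Read traces back from CSV; the exact inverse of :func:`write_traces`.

    Raises on malformed rows (with the offending row number) and on
    negative areas.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ChromodynError(f"trace CSV missing columns: {sorted(missing)}")
    if df.empty:
        return []
    bad = df.index[df["area_px2"].notna() & (df["area_px2"] <= 0)]
    if len(bad):
        raise ChromodynError(
            f"row {int(bad[0]) + 2}: non-positive area {df.loc[bad[0], 'area_px2']}"
        )
    traces = []
    for (trial_id, organ_id), g in df.groupby(["trial_id", "organ_id"], sort=True):
        g = g.sort_values("frame")
        n = int(g["frame"].max()) + 1
        if len(g) != n or not np.array_equal(g["frame"].to_numpy(), np.arange(n)):
            raise ChromodynError(
                f"trace ({trial_id}, {organ_id}) has missing or duplicate frames"
            )
        excl = g.loc[g["excluded"] == 1, "frame"].to_numpy(dtype=int)
        if excl.size == 0:
            raise ChromodynError(
                f"trace ({trial_id}, {organ_id}) has no flash (excluded) frames"
            )
        zero = g.loc[np.isclose(g["time_ms"], 0.0), "frame"]
        if zero.empty:
            raise ChromodynError(
                f"trace ({trial_id}, {organ_id}) has no t=0 frame"
            )
        flash = int(zero.iloc[0])
        ref = g[(g["frame"] != flash)].iloc[-1]
        frame_rate = round(
            (ref["frame"] - flash) * 1000.0 / ref["time_ms"], 6
        )
        timeline = TrialTimeline(
            frame_rate=frame_rate,
            n_frames=n,
            flash_frame_index=flash,
            excluded_frames=frozenset(int(k) for k in excl),
        )
        areas = g["area_px2"].to_numpy(dtype=float)
        traces.append(
            AreaTrace(
                trial_id=str(trial_id),
                organ_id=int(organ_id),
                region=str(g["region"].iloc[0]),
                timeline=timeline,
                areas=areas,
            )
        )
    return traces
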