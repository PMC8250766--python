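"""Mean relative-area plot of a set of traces (non-core convenience)."""

from __future__ import annotations

import numpy as np


def plot_mean_response(traces, ax=None, label=None):
    """Plot the mean normalized area trace against time.

    Each trace is rescaled so its pre-flash mean is 1 (relative surface
    area); the per-frame mean over traces is drawn against time in ms
    (flash at 0).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if not traces:
        return ax
    tl = traces[0].timeline
    mat = np.vstack([t.normalized().areas for t in traces])
    mean = np.nanmean(mat, axis=0)
    ax.plot(tl.frame_times(), mean, label=label)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.axhline(1.0, color="gray", lw=0.8)
    ax.set_xlabel("time relative to flash (ms)")
    ax.set_ylabel("relative surface area (pre-flash mean = 1)")
    if label:
        ax.legend()
    return ax
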