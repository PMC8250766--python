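"""Shared harnesses: rendered parameter-recovery trials and ground truth."""

import math
import warnings

import numpy as np

import chromodyn as cd


def grid_specs(rng, magnitude=150.0, direction="expansion", n_organs=10):
    """Well-separated organs on a jittered grid in a 240x240 field."""
    centers = [(40 + 70 * i, 40 + 55 * j) for j in range(3) for i in range(3)]
    centers.append((110, 205))
    specs = []
    for k, c in enumerate(centers[:n_organs]):
        specs.append(
            cd.ChromatophoreSpec(
                organ_id=k,
                center=c,
                aspect_ratio=float(rng.uniform(1.0, 1.3)),
                baseline_area=float(rng.uniform(450, 750)),
                direction=direction,
                magnitude_pct=magnitude,
                onset_ms=float(rng.uniform(35, 60)),
                rise_ms=float(rng.uniform(80, 120)),
                return_ms=float(rng.uniform(150, 250)),
                orientation=float(rng.uniform(0, math.pi)),
            )
        )
    return specs


def continuous_crossings(spec):
    """Exact threshold-crossing times of the piecewise-linear trajectory.

    Returns (t5, t50, t_peak, rD) in ms: 5% and 50% rising crossings, the
    peak time, and the duration between the rising and falling 5% points.
    """
    t5 = spec.onset_ms + 0.05 * spec.rise_ms
    t50 = spec.onset_ms + 0.50 * spec.rise_ms
    t_peak = spec.onset_ms + spec.rise_ms
    fall5 = spec.onset_ms + spec.rise_ms + 0.95 * spec.return_ms
    return t5, t50, t_peak, fall5 - t5


def onset_frame(spec, config):
    """First frame index with area above baseline (ground-truth onset)."""
    dt = 1000.0 / config.frame_rate
    return config.flash_frame_index + math.ceil(spec.onset_ms / dt)


def run_rendered_trial(trial_seed, noise_sd=20.0, magnitude=150.0,
                       direction="expansion"):
    """Render one trial of grid organs and run the tracking front end.

    Returns (config, specs, matches) where matches maps each ground-truth
    spec to its recovered trace (or None), matched by centroid proximity.
    """
    config = cd.SimConfig(
        seed=trial_seed,
        image_size=(240, 240),
        organ_density=0,
        noise_sd=noise_sd,
    )
    rng = np.random.default_rng(trial_seed + 1000)
    specs = grid_specs(rng, magnitude=magnitude, direction=direction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, _ = cd.render_trial(config, specs)
    flash, excluded = cd.detect_flash_onset(stack)
    timeline = config.timeline()
    blobs = cd.segment_stack(
        stack, cd.SegmentationParams(min_area=50), excluded
    )
    traces = cd.link_tracks(
        blobs,
        timeline,
        cd.LinkParams(max_displacement=8.0),
        trial_id=f"trial{trial_seed}",
    )
    usable = cd.filter_usable(traces)
    matches = {}
    for s in specs:
        best, best_d = None, np.inf
        for tr in usable:
            d = math.hypot(
                tr.centroid[0] - s.center[0], tr.centroid[1] - s.center[1]
            )
            if d < best_d:
                best_d, best = d, tr
        matches[s.organ_id] = best if best_d <= 8.0 else None
    return config, specs, matches
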