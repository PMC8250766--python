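import numpy as np
import pytest

import chromodyn as cd


@pytest.fixture
def expansion_spec():
    """Canonical worked-example organ: baseline 100 px^2, +168% expansion."""
    return cd.ChromatophoreSpec(
        organ_id=0,
        center=(50.0, 50.0),
        aspect_ratio=1.2,
        baseline_area=100.0,
        direction="expansion",
        magnitude_pct=168.0,
        onset_ms=50.0,
        rise_ms=100.0,
        return_ms=200.0,
    )


@pytest.fixture
def small_timeline():
    return cd.TrialTimeline(
        frame_rate=60.0,
        n_frames=72,
        flash_frame_index=30,
        excluded_frames=frozenset({30, 31}),
    )


def make_trace(areas, timeline, trial_id="t", organ_id=0, region="mantle"):
    return cd.AreaTrace(
        trial_id=trial_id,
        organ_id=organ_id,
        region=region,
        timeline=timeline,
        areas=np.asarray(areas, dtype=float),
    )
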