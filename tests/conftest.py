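"""Shared fixtures: a small simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mernav.pipeline import borders_stage, features_stage
from mernav.simulate import CohortSpec, GROUPS, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

FS_TEST = 20_000.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_cohort():
    """Six trajectories (two per group) with features and detected borders.

    Kept small (short pre-segment, 3-4 mm STN) so the whole suite stays
    fast; parameter-recovery at scale lives in the acceptance tests.
    """
    spec = CohortSpec(
        n_patients={g: 2 for g in GROUPS},
        n_trajectories={g: 2 for g in GROUPS},
        stn_length_range=(3.0, 4.0),
        pre_length_mm=4.0, post_length_mm=0.5,
        sampling_rate_hz=FS_TEST, seed=20_240_501)
    manifest, stream = simulate_cohort(spec)
    recordings = {rec.trajectory_id: rec for rec in stream}
    features = {tid: features_stage(rec) for tid, rec in recordings.items()}
    annotations = {tid: borders_stage(tf) for tid, tf in features.items()}
    return {"spec": spec, "manifest": manifest, "recordings": recordings,
            "features": features, "annotations": annotations}
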