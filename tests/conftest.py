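import numpy as np
import pytest

from saccdecode.config import Geometry, desk_scale_config
from saccdecode.eeg import (
    GroundTruthConfig,
    draw_cohort_base_topo,
    draw_subject_truth,
    generate_epochs,
)
from saccdecode.schedule import build_session_schedule


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def tiny_config():
    """A very small single-block session for fast end-to-end tests."""
    return desk_scale_config(
        seed=11,
        trials_per_block=96,
        n_fixation_per_block=48,
        n_saccade_per_block=32,
        n_control_per_block=16,
    )


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruthConfig(subject_onset_jitter_samples=0)


@pytest.fixture(scope="session")
def subject_truth(default_truth):
    base = draw_cohort_base_topo(8, seed=77)
    return draw_subject_truth(
        default_truth, list(range(1, 9)), np.random.default_rng(3), base
    )


@pytest.fixture(scope="session")
def demo_epochs(subject_truth):
    """One desk-scale subject with embedded signal (epoch route)."""
    cfg = desk_scale_config(seed=5)
    sched = build_session_schedule(cfg)
    return generate_epochs(sched, subject_truth, cfg, subject_id="demo", seed=13)
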