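import numpy as np
import pytest

from posture_entropy import CohortDesign, ForcePlateRecording, TrialMeta


@pytest.fixture
def rng():
    # function-scoped: every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20220503)


@pytest.fixture
def meta():
    return TrialMeta("s01", "control", "QS", 1)


@pytest.fixture
def constant_recording(meta):
    """700 N load, constant moments -> COP fixed at (ml, ap) = (0.05, 0.10) m."""
    n = 200
    return ForcePlateRecording(
        fx=np.zeros(n),
        fy=np.zeros(n),
        fz=np.full(n, 700.0),
        mx=np.full(n, 70.0),
        my=np.full(n, -35.0),
        mz=np.zeros(n),
        fs=50.0,
        meta=meta,
    )


@pytest.fixture
def random_recording(meta, rng):
    """Fully random, well-loaded recording for oracle-style checks."""
    n = 300
    return ForcePlateRecording(
        fx=rng.normal(0, 5, n),
        fy=rng.normal(0, 5, n),
        fz=700 + rng.normal(0, 20, n),
        mx=rng.normal(30, 10, n),
        my=rng.normal(-30, 10, n),
        mz=rng.normal(0, 2, n),
        fs=50.0,
        meta=meta,
    )


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down cohort (4/4/3 subjects, 10 s trials) for fast end-to-end tests."""
    return CohortDesign(
        group_sizes={"control": 4, "beginner": 4, "biathlete": 3},
        trial_seconds=10.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_design():
    return CohortDesign(seed=42)
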