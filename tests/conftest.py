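import numpy as np
import pytest

from pinprick_tfr.synth import CohortSpec, StimulusProtocol, SubjectSpec


@pytest.fixture(scope="session")
def short_protocol() -> StimulusProtocol:
    """Reduced schedule (2 sets x 8 x 1 round = 16/hand) for fast unit tests."""
    return StimulusProtocol(n_sets=2, n_rounds=1)


@pytest.fixture(scope="session")
def small_cohort(short_protocol) -> CohortSpec:
    return CohortSpec(group_sizes={"healthy": 2, "motor": 1, "sensorimotor": 2},
                      protocol=short_protocol, seed=7)


@pytest.fixture()
def quiet_cohort(short_protocol) -> CohortSpec:
    """Near-noise-free background for exact injection-recovery checks."""
    return CohortSpec(group_sizes={"healthy": 1, "motor": 1, "sensorimotor": 1},
                      protocol=short_protocol, background_rms=1e-4, seed=3)


@pytest.fixture()
def reference_subject() -> SubjectSpec:
    """Healthy subject carrying the canonical SEP parameters."""
    return SubjectSpec(participant_id="sub-ref", group="healthy",
                       lesion_side="none", erp_np_amplitude=2.81,
                       erp_pos_latency=0.20269, roi_gains={})


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
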