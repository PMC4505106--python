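import numpy as np
import pytest

from nirslat.nirs_io import (
    ChannelLayout,
    ParticipantRecord,
    Recording,
    canonical_block_design,
)


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def design():
    return canonical_block_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, participant_id="p000", dt=0.65):
    return Recording(
        participant_id=participant_id, data=np.asarray(data, dtype=float),
        sampling_interval_s=dt,
    )


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def participant():
    return ParticipantRecord(participant_id="p000", age_months=140, sex="F")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-participant synthetic dataset on disk (stratified so every
    group is populated), shared across tests in a session."""
    from nirslat.synthetic_cohort import GeneratorConfig, simulate_cohort

    out = tmp_path_factory.mktemp("cohort") / "data"
    cfg = GeneratorConfig(n_participants=12, seed=11, group_stratified=True)
    simulate_cohort(cfg, out)
    return out, cfg
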