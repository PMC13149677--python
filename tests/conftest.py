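import pytest
from hypothesis import settings

from chemtrace import StudyConfig, generate_study

settings.register_profile("chemtrace", derandomize=True, deadline=None)
settings.load_profile("chemtrace")
from chemtrace.io import features_from_frame
from chemtrace.reference import index_from_frames
from chemtrace.simulate import Study


@pytest.fixture(scope="session")
def study() -> Study:
    """Default desk-scale synthetic study, shared read-only across tests."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> str:
    """The same study written to disk for I/O and CLI tests."""
    out = tmp_path_factory.mktemp("study")
    generate_study(StudyConfig(seed=11), out_dir=out)
    return str(out)


@pytest.fixture(scope="session")
def study_index(study):
    return index_from_frames(study.reference_tables)


@pytest.fixture(scope="session")
def study_features(study):
    return features_from_frame(study.annotations)
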