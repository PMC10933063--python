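import pytest
from hypothesis import HealthCheck, settings

import injurysignals as isg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_spec():
    """Canonical study-scale spec: 10 years x 200 incidents/year, 30 planted
    terms per trajectory kind, three recoverable co-occurrence blocks."""
    return isg.make_study_spec(seed=1)


@pytest.fixture(scope="session")
def study_records(study_spec):
    return isg.generate_corpus(study_spec)


@pytest.fixture()
def toy_records():
    """Six-document single-year toy corpus used for TF-IDF hand checks."""
    texts = [
        "fall ladder roof fall",
        "fall bathroom floor slip",
        "ladder paint bucket fall",
        "bee sting arm swelling",
        "fall stairs night fall fall",
        "slip icy road fracture",
    ]
    return [
        isg.IncidentRecord(id=f"d{i}", year=2020, text=t)
        for i, t in enumerate(texts)
    ]


@pytest.fixture()
def toy_matrix(toy_records):
    (matrix,) = isg.build_matrix(toy_records)
    return matrix
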