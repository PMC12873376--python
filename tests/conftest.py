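from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import condx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def npm1_fasta_path() -> Path:
    """Canonical human nucleophosmin sequence (UniProt P06748, 294 aa)."""
    return DATA_DIR / "npm1_P06748.fasta"


@pytest.fixture(scope="session")
def npm1_sequence(npm1_fasta_path) -> str:
    records = condx.read_fasta(npm1_fasta_path)
    assert len(records) == 1
    return records[0][1]


@pytest.fixture(scope="session")
def early():
    return condx.aging_preset("early").rates


@pytest.fixture(scope="session")
def intermediate():
    return condx.aging_preset("intermediate").rates


@pytest.fixture(scope="session")
def late():
    return condx.aging_preset("late").rates
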