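import pytest
from hypothesis import HealthCheck, settings

from ppstall import ProteinRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def make_records():
    """Build ProteinRecord lists from {id: sequence} mappings."""

    def _make(seqs: dict[str, str]) -> list[ProteinRecord]:
        return [ProteinRecord(id=k, sequence=v) for k, v in seqs.items()]

    return _make


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
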