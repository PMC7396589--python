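import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def fastq_writer(tmp_path):
    """Write (id, seq, qual) triples to a FASTQ file under tmp_path."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as out:
            for rid, seq, qual in records:
                out.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return path

    return _write


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(entries, name="refs.fasta"):
        path = tmp_path / name
        with open(path, "w") as out:
            for header, seq in entries:
                out.write(f">{header}\n{seq}\n")
        return path

    return _write
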