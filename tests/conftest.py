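import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def write_reactions(tmp_path):
    """Write reaction lines to a temp TSV and return the path."""

    def _write(lines):
        path = tmp_path / "reactions.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
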