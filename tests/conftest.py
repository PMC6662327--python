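import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatable",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repeatable")


@pytest.fixture
def outdir(tmp_path):
    """Scratch directory for rendered files."""
    d = tmp_path / "out"
    d.mkdir()
    return d
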