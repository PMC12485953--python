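import sys, pathlib
sys.path.insert(0, str(pathlib.Path(__file__).parent))
import pytest
from hypothesis import HealthCheck, settings

from tailskit.nterm import ProteinRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def mep1_like() -> ProteinRecord:
    """A protein whose N-terminal residues mirror the canonical worked example:
    Met1, then V-T-A, so iMet excision puts the mature N-terminus at V2 and one
    dipeptidyl cleavage yields a product starting at A4."""
    return ProteinRecord(
        "MEP-1like",
        "MVTAQHEILSDFKLLNRAAAPQESTVWYACDEFGHIKWYR",
        description="synthetic stand-in for the worked example",
    )
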