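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

from flymeio.markers import MarkerMap, ProgenyRecord


@pytest.fixture
def chr2_map() -> MarkerMap:
    return MarkerMap("2L-2R", ("net", "dpp", "dpy", "b", "pr", "cn"))


@pytest.fixture
def make_record(chr2_map):
    """Factory: build a female ProgenyRecord from a call string like 'PPPRRR'."""

    def _make(calls: str, progeny_id: str = "p1", sex: str = "female"):
        call_map = {
            locus: {"P": "P", "R": "R", "N": "NA"}[c]
            for locus, c in zip(chr2_map.loci, calls)
        }
        return ProgenyRecord(progeny_id=progeny_id, sex=sex, calls=call_map)

    return _make
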