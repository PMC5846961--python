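import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bcsdecision import (  # noqa: E402
    HealthStateUtilities,
    TumorLocation,
    calibrate_from_printed_values,
)

#: Published per-location TV/BV ratio cut-offs at the 35.8% threshold.
PRINTED_CUTOFFS = {
    TumorLocation.UPPER_LATERAL: 21.6,
    TumorLocation.UPPER_MEDIAL: 15.1,
    TumorLocation.LOWER_LATERAL: 4.1,
    TumorLocation.LOWER_MEDIAL: 3.2,
    TumorLocation.CENTRAL: 14.7,
}
PRINTED_THRESHOLD = 0.358
ANCHOR = (TumorLocation.UPPER_MEDIAL, 5.6, 0.71)


@pytest.fixture(scope="session")
def default_model():
    return calibrate_from_printed_values(PRINTED_CUTOFFS, PRINTED_THRESHOLD, ANCHOR)


@pytest.fixture(scope="session")
def default_utils():
    return HealthStateUtilities(
        u_bcs_good=0.908,
        u_bcs_poor=0.843,
        u_mst_only=0.859,
        u_mst_recon=0.876,
        p_recon=7 / 17,
    )
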