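import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_acoustic():
    """One modest acoustic recording run through the full chain."""
    import icspread as ic

    truth = ic.default_truth("acoustic", seed=7)
    proto = ic.default_protocol("acoustic")
    rec = ic.generate_recording(truth, proto)
    amua = ic.compute_amua(rec)
    dp = ic.cumulative_dprime(amua)
    stc = ic.build_stc(dp)
    return dict(truth=truth, protocol=proto, rec=rec, amua=amua, dp=dp, stc=stc)
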