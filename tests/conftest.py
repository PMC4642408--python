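import numpy as np
import pytest

from tempotrain import LoudnessFun, ParticipantProfile, PsychFun


def make_profile(
    mu: float = 120.0,
    spread: float = 25.0,
    improvement_rate: float = 0.0,
    group: str = "A_temporal",
    delta75: float = 0.005,
    loudness_spread: float = 0.0015,
    **kwargs,
) -> ParticipantProfile:
    return ParticipantProfile(
        id="test",
        group=group,
        order_pf=PsychFun(mu=mu, spread=spread),
        loudness_fun=LoudnessFun(delta75=delta75, spread=loudness_spread),
        improvement_rate=improvement_rate,
        **kwargs,
    )


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
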