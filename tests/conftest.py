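import numpy as np
import pytest

from divscan import Consensus, build_pwm, transform_pwm, random_consensus


@pytest.fixture(scope="session")
def synthetic_template():
    """A 293-nt i.i.d. synthetic family consensus (fixed seed)."""
    return random_consensus(293, 20210202)


@pytest.fixture(scope="session")
def synthetic_pwm(synthetic_template):
    return transform_pwm(build_pwm(Consensus("syn293", synthetic_template)), -1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pwm(rng, length, kd_target=None):
    """A PWM for a random uniform-composition consensus."""
    seq = "".join("atcg"[i] for i in rng.integers(0, 4, size=length))
    pwm = build_pwm(Consensus(f"rnd{length}", seq))
    if kd_target is not None:
        pwm = transform_pwm(pwm, kd_target)
    return pwm
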