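import numpy as np
import pytest

from tasscat import evolution, simulate


@pytest.fixture(scope="session")
def donor_map():
    """Consensus map trained on PWM-drawn constitutive donor windows."""
    rng = np.random.default_rng(20_260_921)
    train = simulate.draw_sites_from_pwm(simulate.donor_pwm_probs(), 2000,
                                         rng)
    return evolution.build_consensus_map(train, "donor")


@pytest.fixture(scope="session")
def acceptor_map():
    rng = np.random.default_rng(20_260_922)
    train = simulate.draw_sites_from_pwm(simulate.acceptor_pwm_probs(),
                                         2000, rng)
    return evolution.build_consensus_map(train, "acceptor")
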