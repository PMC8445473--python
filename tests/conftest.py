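import numpy as np
import pytest

import poprime as pp
from poprime.ea import LATERParams
from poprime.synth import GenerativeSpec, weighted_rate_color_spec


@pytest.fixture(scope="session")
def fast_config():
    """Reduced optimizer budgets for tests that fit many models."""
    return pp.FitConfig(inner_restarts=2, outer_restarts=1, outer_maxfev_per_dim=45, seed=0)


@pytest.fixture(scope="session")
def later_color_gen():
    """Ground truth used throughout: LATER + weighted-rate color rule."""
    return GenerativeSpec(
        model=weighted_rate_color_spec("LATER"),
        ea_params=LATERParams(theta=1.0, s0_base=0.0, mu_r=5.0, sigma_r=1.0, tau=0.3),
        rule_params={"color": {"alpha": 0.8, "delta": 0.2}},
        lapse_probability=0.02,
    )


@pytest.fixture(scope="session")
def later_color_sessions(later_color_gen):
    """Two full-size sessions (8 blocks x 112 trials) from the ground truth."""
    out = []
    for k in range(2):
        design = pp.generate_design(pp.DesignConstraints(seed=100 + k))
        out.append(
            pp.simulate_session(
                design, later_color_gen, seed=200 + k, participant="p01", session=str(k + 1)
            )
        )
    return out


@pytest.fixture(scope="session")
def small_design():
    return pp.generate_design(pp.DesignConstraints(n_blocks=2, trials_per_block=56, seed=7))


@pytest.fixture(scope="session")
def no_update_session(small_design):
    gen = GenerativeSpec(
        model=pp.no_update_spec("LATER"),
        ea_params=LATERParams(theta=1.0, s0_base=0.0, mu_r=5.0, sigma_r=1.0, tau=0.3),
    )
    return pp.simulate_session(small_design, gen, seed=11)
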