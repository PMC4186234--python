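import numpy as np
import pytest

from actinfer import (
    GenerativeModel,
    LimitedOfferConfig,
    build_limited_offer,
    make_policy_set,
    random_model,
)


@pytest.fixture
def identity_model():
    """Fully observable 3-state model with identity likelihood and dynamics."""
    J = 3
    return GenerativeModel(
        A=np.eye(J),
        B=np.stack([np.eye(J), np.eye(J)]),
        c=np.full(J, 1 / 3),
        d=np.full(J, 1 / 3),
        horizon=4,
    )


@pytest.fixture
def small_random():
    """Seeded random 3-state, 2-control model with its environment."""
    return random_model(n_states=3, n_controls=2, n_obs=3, horizon=4, seed=7)


@pytest.fixture
def fig3_setup():
    """Scripted 16-trial limited-offer game: high offer forced on trial 11."""
    cfg = LimitedOfferConfig(scripted_high_offer_trial=11)
    model, proc = build_limited_offer(cfg)
    policies = make_policy_set(cfg.horizon, 2, "stay_then_shift")
    return model, proc, policies
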