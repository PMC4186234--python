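"""Policy valuation by relative entropy to the goal distribution.

The value of policy k from hidden state j at trial t is the negative
Kullback-Leibler divergence between the distribution over final states it
induces and the goal prior c:

    Q[k, j] = -KL( T(pi_k) d_j || c )
            = H[ T(pi_k) d_j ] + sum_f (T(pi_k) d_j)_f * ln c_f

where T(pi_k) is the composition of the controlled transition matrices from
the current trial to the horizon and d_j the point mass on state j.  The two
terms of the decomposition are the entropy of the predicted final-state
distribution (an intrinsic, exploratory reward that keeps options open) and
the expected utility of the final state (the extrinsic reward ln c averaged
under the prediction).  With a flat goal prior the utility term is constant
and policies are ranked purely by entropy; as c concentrates, expected
utility dominates.

Zero goal-prior entries contribute ``log_floor`` instead of -inf so that
values remain usable inside softmax functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import entropy, floored_log
from .model import GenerativeModel, PolicySet

__all__ = [
    "FinalStateMap",
    "PolicyValueMatrix",
    "compose_transitions",
    "policy_value_matrix",
    "value_decomposition",
]


@dataclass(frozen=True)
class FinalStateMap:
    """Column-stochastic map from current-state to final-state distributions."""

    Tpi: np.ndarray  # (n_states, n_states)


@dataclass(frozen=True)
class PolicyValueMatrix:
    """Q[k, j]: value (non-positive, in nats) of policy k from state j at trial t."""

    Q: np.ndarray  # (K, n_states)
    t: int


def compose_transitions(model: GenerativeModel, policy: np.ndarray, t: int) -> FinalStateMap:
    """Iterated composition B(u_{T-1}) ... B(u_t) of a policy's transitions.

    ``t`` is the (1-based) current trial; the empty product at ``t == horizon``
    is the identity.  Policy steps before ``t`` are already in the past and
    are ignored.
    """
    T = model.horizon
    if not 1 <= t <= T:
        raise ValueError(f"trial index t={t} out of range 1..{T}")
    policy = np.asarray(policy, dtype=np.intp)
    if policy.shape != (T - 1,):
        raise ValueError(f"policy must have length horizon-1={T - 1}, got {policy.shape}")
    M = np.eye(model.n_states)
    for step in range(t, T):  # steps t..T-1, 1-based
        M = model.B[policy[step - 1]] @ M
    return FinalStateMap(Tpi=M)


def value_decomposition(
    model: GenerativeModel, policy: np.ndarray, state: int, t: int
) -> tuple[float, float]:
    """Split the value of a policy from a state into (entropy, expected_utility).

    Their sum is exactly the corresponding entry of
    :func:`policy_value_matrix` (the same floating-point expression).
    """
    p = compose_transitions(model, policy, t).Tpi[:, state]
    ln_c = floored_log(model.c, model.log_floor)
    return entropy(p), float(p @ ln_c)


def policy_value_matrix(model: GenerativeModel, policies: PolicySet, t: int) -> PolicyValueMatrix:
    """Value of every allowable policy from every hidden state at trial ``t``."""
    model.require_valid()
    ln_c = floored_log(model.c, model.log_floor)
    K = policies.n_policies
    Q = np.empty((K, model.n_states))
    for k in range(K):
        Tpi = compose_transitions(model, policies.policies[k], t).Tpi
        for j in range(model.n_states):
            p = Tpi[:, j]
            Q[k, j] = entropy(p) + p @ ln_c
    # Gibbs' inequality guarantees Q <= 0 analytically; clip the few-ulp
    # positive residue that appears when the prediction equals c exactly.
    np.minimum(Q, 0.0, out=Q)
    return PolicyValueMatrix(Q=Q, t=t)
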