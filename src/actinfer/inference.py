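"""Mean-field variational updates for states, policies and precision.

The approximate posterior factorizes over (past) hidden states, (future)
policies and the precision of beliefs about policies.  Precision carries a
gamma prior with shape ``alpha`` and rate ``beta``; its posterior is a gamma
distribution with the same shape and an optimized rate ``beta_hat``, so the
expected precision is ``gamma_hat = alpha / beta_hat``.

One fixed-point iteration applies, in order,

1. state update:     s_hat  = softmax( ln(A^T o) + ln(B(a) s_prev) + gamma_hat * Q^T pi_hat )
2. policy update:    pi_hat = softmax( gamma_hat * Q s_hat )
3. precision update: beta_hat = beta - pi_hat^T Q s_hat,  gamma_hat = alpha / beta_hat

until the largest absolute change across all expectation components falls
below ``tol``.  The first trial uses the initial-state prior ``ln d`` in
place of the transition term.  The value-weighted third term of the state
update biases perception towards states that support valuable policies (an
optimism bias); since Q <= 0, the precision update can only add a
non-negative quantity to the prior rate, bounding the expected precision by
its prior mean ``alpha / beta``.

Only the current trial's state expectation is re-estimated during iteration;
converged expectations from earlier trials are frozen (past observations and
actions are known).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import floored_log, softmax
from .model import GenerativeModel, PolicySet
from .valuation import PolicyValueMatrix, policy_value_matrix

__all__ = [
    "BeliefState",
    "InferenceTrace",
    "init_beliefs",
    "update_state_expectation",
    "update_policy_expectation",
    "update_precision",
    "infer",
]

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 64


@dataclass
class BeliefState:
    """Sufficient statistics of the mean-field posterior."""

    s_hat: list[np.ndarray]   # state expectations for trials 1..t
    pi_hat: np.ndarray        # policy expectations, length K
    beta_hat: float           # posterior rate of the precision gamma-distribution
    alpha: float              # shape (fixed, inherited from the prior)

    @property
    def gamma_hat(self) -> float:
        """Expected precision alpha / beta_hat."""
        return self.alpha / self.beta_hat


@dataclass
class InferenceTrace:
    """Per-iteration record of one trial's fixed-point iteration."""

    gamma_hat: list[float] = field(default_factory=list)
    s_hat: list[np.ndarray] = field(default_factory=list)
    pi_hat: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    final_max_change: float = np.inf

    @property
    def n_iterations(self) -> int:
        return len(self.gamma_hat)


def init_beliefs(model: GenerativeModel, policies: PolicySet) -> BeliefState:
    """Uniform state and policy expectations; precision at its prior mean."""
    J, K = model.n_states, policies.n_policies
    return BeliefState(
        s_hat=[np.full(J, 1.0 / J)],
        pi_hat=np.full(K, 1.0 / K),
        beta_hat=model.beta,
        alpha=model.alpha,
    )


def update_state_expectation(
    model: GenerativeModel,
    Q: PolicyValueMatrix,
    obs: np.ndarray,
    prev_s_hat: np.ndarray | None,
    prev_action: int | None,
    pi_hat: np.ndarray,
    gamma_hat: float,
) -> np.ndarray:
    """Posterior expectation over the current hidden state.

    Combines the log-likelihood of the observation, the log prior prediction
    from the previous state and action (``ln d`` on the first trial), and the
    policy-averaged value of each state scaled by expected precision.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.shape != (model.n_obs,):
        raise ValueError(f"obs must have length {model.n_obs}, got {obs.shape}")
    if not (np.count_nonzero(obs == 1.0) == 1 and np.count_nonzero(obs) == 1):
        raise ValueError("obs must be a one-hot outcome vector")
    log_lik = floored_log(model.A.T @ obs, model.log_floor)
    if prev_s_hat is None:
        log_prior = floored_log(model.d, model.log_floor)
    else:
        if prev_action is None:
            raise ValueError("prev_action required when prev_s_hat is given")
        log_prior = floored_log(model.B[prev_action] @ prev_s_hat, model.log_floor)
    return softmax(log_lik + log_prior + gamma_hat * (Q.Q.T @ pi_hat))


def update_policy_expectation(
    Q: PolicyValueMatrix, s_hat: np.ndarray, gamma_hat: float
) -> np.ndarray:
    """Softmax over policies of their precision-weighted expected value."""
    if Q.Q.shape[1] != len(s_hat):
        raise ValueError("state expectation length does not match Q")
    return softmax(gamma_hat * (Q.Q @ s_hat))


def update_precision(
    model: GenerativeModel,
    Q: PolicyValueMatrix,
    s_hat: np.ndarray,
    pi_hat: np.ndarray,
) -> tuple[float, float]:
    """Optimize the precision rate from the expected value under beliefs.

    Returns ``(beta_hat, gamma_hat)`` with
    ``beta_hat = beta - pi_hat^T Q s_hat``.  Values are non-positive, so the
    expected precision is an increasing function of expected value, bounded
    above by the prior mean ``alpha / beta``.
    """
    expected_value = float(pi_hat @ Q.Q @ s_hat)
    beta_hat = model.beta - expected_value
    if beta_hat <= 0:
        raise ValueError(
            f"non-positive precision rate {beta_hat}; Q must be non-positive"
        )
    return beta_hat, model.alpha / beta_hat


def infer(
    model: GenerativeModel,
    policies: PolicySet,
    obs_history: list[np.ndarray],
    action_history: list[int],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    prior: BeliefState | None = None,
) -> tuple[BeliefState, InferenceTrace]:
    """Converge the coupled updates for the current trial.

    ``obs_history`` holds one-hot outcomes for trials 1..t and
    ``action_history`` the t-1 actions taken between them.  If ``prior`` is
    given it must contain the frozen, converged state expectations of trials
    1..t-1 (as produced by inferring the previous trial); otherwise those
    trials are re-inferred sequentially with the same settings.

    Returns the converged beliefs and the per-iteration trace of the current
    trial.  Non-convergence within ``max_iter`` is flagged on the trace, not
    raised.
    """
    t = len(obs_history)
    if t < 1:
        raise ValueError("obs_history must contain at least one observation")
    if len(action_history) != t - 1:
        raise ValueError("action_history must have length len(obs_history) - 1")

    if prior is None:
        past: list[np.ndarray] = []
        for tau in range(1, t):
            boot = BeliefState(
                s_hat=list(past), pi_hat=np.empty(0), beta_hat=model.beta, alpha=model.alpha
            )
            belief, _ = infer(
                model, policies, obs_history[:tau], action_history[: tau - 1],
                tol=tol, max_iter=max_iter,
                prior=boot if past else None,
            )
            past = belief.s_hat
    else:
        past = list(prior.s_hat[: t - 1])
        if len(past) != t - 1:
            raise ValueError("prior beliefs do not cover trials 1..t-1")

    Q = policy_value_matrix(model, policies, t)
    J, K = model.n_states, policies.n_policies
    s = np.full(J, 1.0 / J)
    pi = np.full(K, 1.0 / K)
    beta_hat = model.beta
    gamma = model.alpha / model.beta
    prev_s = past[-1] if past else None
    prev_a = action_history[-1] if action_history else None

    trace = InferenceTrace()
    for _ in range(max_iter):
        s_new = update_state_expectation(model, Q, obs_history[-1], prev_s, prev_a, pi, gamma)
        pi_new = update_policy_expectation(Q, s_new, gamma)
        beta_new, gamma_new = update_precision(model, Q, s_new, pi_new)
        change = max(
            float(np.abs(s_new - s).max()),
            float(np.abs(pi_new - pi).max()),
            abs(gamma_new - gamma),
        )
        s, pi, beta_hat, gamma = s_new, pi_new, beta_new, gamma_new
        trace.gamma_hat.append(gamma)
        trace.s_hat.append(s.copy())
        trace.pi_hat.append(pi.copy())
        trace.final_max_change = change
        if change < tol:
            trace.converged = True
            break

    belief = BeliefState(s_hat=past + [s], pi_hat=pi, beta_hat=beta_hat, alpha=model.alpha)
    return belief, trace
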