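"""Agent-environment loop, the limited-offer task, and fixture generators.

The simulation couples an inferring agent to a generative *process* — the
real dynamics of the environment, which may differ from the agent's model.
Each trial the agent observes an outcome, converges its variational beliefs,
samples an action from the posterior marginal over next-step controls
(Thompson sampling), and the environment transitions.  RNG draws are
consumed in a fixed order: one observation draw for the first trial, then
per trial an action draw, a state draw and an observation draw — so runs
are bit-reproducible from (config, seed).

The limited-offer game: a low offer stands at the outset and may be
withdrawn (hazard ``r``) or replaced by a high offer (probability ``q``) on
any trial the agent waits.  The high offer is fleeting: if it is not
accepted it is withdrawn with probability ``high_offer_withdrawal`` (default
1 — a take-it-or-leave-it opportunity; 0 makes it persistent).  Accepting
an offer enters an absorbing accepted state.  The agent must therefore
decide how long to wait: too long and it may end with nothing, too short
and it forgoes the chance of the high offer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .inference import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    BeliefState,
    InferenceTrace,
    infer,
)
from .model import GenerativeModel, PolicySet, make_policy_set

__all__ = [
    "EnvironmentProcess",
    "TrialRecord",
    "GameTrace",
    "LimitedOfferConfig",
    "select_action",
    "step_process",
    "run_game",
    "build_limited_offer",
    "random_model",
    "LOW", "HIGH", "NO_OFFER", "ACCEPTED_LOW", "ACCEPTED_HIGH",
    "STAY", "ACCEPT",
]

# Hidden-state and control labels of the limited-offer game (0-based).
LOW, HIGH, NO_OFFER, ACCEPTED_LOW, ACCEPTED_HIGH = range(5)
STAY, ACCEPT = 0, 1


@dataclass(frozen=True)
class EnvironmentProcess:
    """True dynamics generating states and outcomes.

    ``script`` maps a (1-based) trial index to the state forced at that
    trial, overriding the stochastic draw — used to pin exogenous events
    such as "the high offer appears at trial 11".  Script entries never fire
    while the process sits in one of ``frozen_states`` (absorbing states are
    irreversible even under a script).
    """

    B_true: np.ndarray                      # (n_actions, J, J) column-stochastic
    A_true: np.ndarray                      # (n_obs, J); identity => obs == state
    initial_state: int
    script: dict[int, int] = field(default_factory=dict)
    frozen_states: frozenset[int] = frozenset()


@dataclass
class TrialRecord:
    """One trial of a game: ground truth, observation, beliefs and action.

    ``action`` is the control sampled *during* this trial; it takes effect
    on the next trial's state.  The final trial has no action (None).
    """

    trial: int                   # 1-based
    true_state: int
    observation: int
    action: int | None
    belief: BeliefState
    gamma_iterations: list[float]
    converged: bool


@dataclass
class GameTrace:
    """Complete record of one simulated game."""

    records: list[TrialRecord]
    gamma_sequence: np.ndarray   # per-iteration gamma_hat, concatenated in trial order
    seed: int
    config: dict[str, Any]

    @property
    def actions(self) -> list[int | None]:
        return [r.action for r in self.records]

    @property
    def true_states(self) -> list[int]:
        return [r.true_state for r in self.records]

    def first_trial_in(self, states: set[int]) -> int | None:
        """First (1-based) trial whose true state lies in ``states``."""
        for r in self.records:
            if r.true_state in states:
                return r.trial
        return None


def select_action(
    pi_hat: np.ndarray, policies: PolicySet, t: int, rng: np.random.Generator
) -> int:
    """Sample an action from the posterior marginal over next-step controls.

    The marginal assigns to control u the total posterior mass of policies
    prescribing u at trial ``t`` (Thompson sampling).
    """
    controls = policies.control_at(t)
    n_controls = int(controls.max()) + 1
    marginal = np.zeros(max(n_controls, 1))
    np.add.at(marginal, controls, pi_hat)
    total = marginal.sum()
    if total <= 0:
        raise ValueError("policy expectations sum to zero")
    return int(rng.choice(len(marginal), p=marginal / total))


def step_process(
    proc: EnvironmentProcess,
    state: int,
    action: int,
    t: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Advance the true process by one action.

    ``t`` is the (1-based) trial index the *returned* state will occupy; a
    script entry for ``t`` forces that state (unless the current state is
    frozen).  Returns ``(next_state, observation)`` with the observation
    sampled from the true observation matrix at the next state.
    """
    J = proc.B_true.shape[1]
    column = proc.B_true[action][:, state]
    next_state = int(rng.choice(J, p=column))
    if t in proc.script and state not in proc.frozen_states:
        next_state = int(proc.script[t])
    obs = int(rng.choice(proc.A_true.shape[0], p=proc.A_true[:, next_state]))
    return next_state, obs


def run_game(
    model: GenerativeModel,
    policies: PolicySet,
    proc: EnvironmentProcess,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    config: dict[str, Any] | None = None,
) -> GameTrace:
    """Play one full game of ``model.horizon`` trials.

    Per trial: observe, converge beliefs, sample an action, step the
    environment.  The action sampled at trial t produces the state of trial
    t+1; no action is sampled on the final trial.
    """
    model.require_valid()
    rng = np.random.default_rng(seed)
    T = model.horizon
    true_state = proc.initial_state
    obs = int(rng.choice(proc.A_true.shape[0], p=proc.A_true[:, true_state]))

    records: list[TrialRecord] = []
    obs_history: list[np.ndarray] = []
    action_history: list[int] = []
    belief: BeliefState | None = None
    gamma_all: list[float] = []

    for t in range(1, T + 1):
        one_hot = np.zeros(model.n_obs)
        one_hot[obs] = 1.0
        obs_history.append(one_hot)
        belief, trace = infer(
            model, policies, obs_history, action_history,
            tol=tol, max_iter=max_iter, prior=belief,
        )
        gamma_all.extend(trace.gamma_hat)
        action: int | None = None
        if t < T:
            action = select_action(belief.pi_hat, policies, t, rng)
        records.append(
            TrialRecord(
                trial=t,
                true_state=true_state,
                observation=obs,
                action=action,
                belief=belief,
                gamma_iterations=list(trace.gamma_hat),
                converged=trace.converged,
            )
        )
        if t < T:
            action_history.append(action)
            true_state, obs = step_process(proc, true_state, action, t + 1, rng)

    return GameTrace(
        records=records,
        gamma_sequence=np.asarray(gamma_all),
        seed=seed,
        config=dict(config or {}),
    )


@dataclass(frozen=True)
class LimitedOfferConfig:
    """Parameters of the limited-offer game.

    The numeric defaults are this package's calibration of the task: they
    are chosen so that the canonical behaviour — wait while the low offer
    stands, accept a high offer as soon as it appears — is reproduced, and
    every one of them is exposed here for experimentation.
    """

    horizon: int = 16
    hazard_rate: float = 0.08            # r: per-trial low-offer withdrawal
    replacement_prob: float = 0.0625     # q: low offer replaced by high offer
    high_offer_withdrawal: float = 1.0   # unaccepted high offer withdrawn (0 = persistent)
    goal_prior: tuple[float, ...] = (0.09, 0.09, 0.09, 0.03, 0.70)
    scripted_high_offer_trial: int | None = None
    alpha: float = 8.0
    beta: float = 1.0

    def validate(self) -> None:
        r, q, w = self.hazard_rate, self.replacement_prob, self.high_offer_withdrawal
        if r < 0 or q < 0 or r + q > 1:
            raise ValueError(f"require r >= 0, q >= 0, r + q <= 1; got r={r}, q={q}")
        if not 0 <= w <= 1:
            raise ValueError(f"high_offer_withdrawal must lie in [0, 1], got {w}")
        c = np.asarray(self.goal_prior, dtype=float)
        if c.shape != (5,) or (c < 0).any() or abs(c.sum() - 1.0) > 1e-10:
            raise ValueError("goal_prior must be a length-5 simplex")
        if self.horizon < 2:
            raise ValueError("horizon must be >= 2")
        s = self.scripted_high_offer_trial
        if s is not None and not 2 <= s <= self.horizon:
            raise ValueError("scripted_high_offer_trial must lie in 2..horizon")


def build_limited_offer(
    cfg: LimitedOfferConfig = LimitedOfferConfig(),
) -> tuple[GenerativeModel, EnvironmentProcess]:
    """Construct the 5-state, 2-control limited-offer model and its process.

    States: low offer, high offer, no offer, accepted-low, accepted-high;
    the accepted states re-enter themselves with unit probability under both
    controls.  Under *stay* the low offer is withdrawn with probability r,
    upgraded with probability q, and the high offer is withdrawn with
    probability ``high_offer_withdrawal``.  Under *accept* each standing
    offer leads to its accepted state; accepting in the no-offer state is a
    self-transition (there is nothing to accept).

    The environment mirrors the model (a well-specified agent).  If
    ``scripted_high_offer_trial`` is set, the process is additionally
    scripted to hold the low offer until that trial and force the high offer
    on it, pinning the exogenous course of the game for replication.
    """
    cfg.validate()
    r, q, w = cfg.hazard_rate, cfg.replacement_prob, cfg.high_offer_withdrawal
    J = 5
    B = np.zeros((2, J, J))
    stay = B[STAY]
    stay[LOW, LOW] = 1.0 - r - q
    stay[HIGH, LOW] = q
    stay[NO_OFFER, LOW] = r
    stay[HIGH, HIGH] = 1.0 - w
    stay[NO_OFFER, HIGH] = w
    stay[NO_OFFER, NO_OFFER] = 1.0
    stay[ACCEPTED_LOW, ACCEPTED_LOW] = 1.0
    stay[ACCEPTED_HIGH, ACCEPTED_HIGH] = 1.0
    accept = B[ACCEPT]
    accept[ACCEPTED_LOW, LOW] = 1.0
    accept[ACCEPTED_HIGH, HIGH] = 1.0
    accept[NO_OFFER, NO_OFFER] = 1.0
    accept[ACCEPTED_LOW, ACCEPTED_LOW] = 1.0
    accept[ACCEPTED_HIGH, ACCEPTED_HIGH] = 1.0

    d = np.zeros(J)
    d[LOW] = 1.0
    model = GenerativeModel(
        A=np.eye(J),
        B=B,
        c=np.asarray(cfg.goal_prior, dtype=float),
        d=d,
        horizon=cfg.horizon,
        alpha=cfg.alpha,
        beta=cfg.beta,
    )
    script: dict[int, int] = {}
    if cfg.scripted_high_offer_trial is not None:
        s = cfg.scripted_high_offer_trial
        script = {t: LOW for t in range(2, s)}
        script[s] = HIGH
    proc = EnvironmentProcess(
        B_true=B.copy(),
        A_true=np.eye(J),
        initial_state=LOW,
        script=script,
        frozen_states=frozenset({ACCEPTED_LOW, ACCEPTED_HIGH}),
    )
    return model, proc


def random_model(
    n_states: int,
    n_controls: int,
    n_obs: int,
    horizon: int,
    seed: int,
) -> tuple[GenerativeModel, EnvironmentProcess]:
    """Random valid model (and mirroring process) for fixtures and tests.

    Columns of A and B and the vectors c and d are normalized positive
    draws, so every entry is strictly positive and every invariant holds by
    construction.  The same seed reproduces the model bitwise.
    """
    if min(n_states, n_controls, n_obs, horizon) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)

    def _stochastic(shape: tuple[int, ...]) -> np.ndarray:
        M = rng.uniform(0.05, 1.0, size=shape)
        return M / M.sum(axis=-2, keepdims=True)

    A = _stochastic((n_obs, n_states))
    B = _stochastic((n_controls, n_states, n_states))
    c = rng.uniform(0.05, 1.0, size=n_states)
    c /= c.sum()
    d = rng.uniform(0.05, 1.0, size=n_states)
    d /= d.sum()
    model = GenerativeModel(A=A, B=B, c=c, d=d, horizon=horizon)
    proc = EnvironmentProcess(
        B_true=B.copy(),
        A_true=A.copy(),
        initial_state=int(rng.integers(n_states)),
    )
    return model, proc


def default_policies(cfg: LimitedOfferConfig) -> PolicySet:
    """Stay-then-shift policy set matching a limited-offer configuration."""
    return make_policy_set(cfg.horizon, 2, "stay_then_shift")
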