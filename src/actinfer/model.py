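"""Generative model and policy-set definitions for discrete active inference.

The agent's world model is a finite-horizon, partially observed Markov
decision process in which a subset of hidden variables — control states —
parametrize the transition dynamics:

* ``A`` (likelihood): column-stochastic map from hidden states to outcomes,
  ``A[o, s] = P(o | s)``.
* ``B[u]`` (controlled transitions): one column-stochastic matrix per
  control state, ``B[u][s', s] = P(s' | s, u)``.
* ``d``: prior over the initial hidden state.
* ``c``: prior over the *final* hidden state.  This vector encodes the
  agent's goals; its elementwise log is the utility of ending in each state.
* ``alpha, beta``: shape and rate of the gamma prior over the precision of
  beliefs about policies (defaults 8 and 1, so the prior mean precision
  is 8).

A *policy* is a full sequence of control states from the first trial to the
horizon.  Policies are evaluated — never learned — and the allowable set is
constructed by a named scheme.

Trials are numbered 1..horizon in all reports and file formats; array
indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._utils import DEFAULT_LOG_FLOOR

__all__ = [
    "GenerativeModel",
    "PolicySet",
    "ValidationReport",
    "validate_model",
    "make_policy_set",
    "read_model",
    "write_model",
]

_STOCHASTIC_TOL = 1e-10


@dataclass(frozen=True)
class GenerativeModel:
    """Fixed parameters of the agent's generative model."""

    A: np.ndarray            # (n_obs, n_states), column-stochastic
    B: np.ndarray            # (n_controls, n_states, n_states), each column-stochastic
    c: np.ndarray            # (n_states,) goal prior over final states
    d: np.ndarray            # (n_states,) prior over initial state
    horizon: int             # number of trials T
    alpha: float = 8.0       # gamma-prior shape of precision
    beta: float = 1.0        # gamma-prior rate of precision
    log_floor: float = DEFAULT_LOG_FLOOR

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))

    @property
    def n_obs(self) -> int:
        return self.A.shape[0]

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_controls(self) -> int:
        return self.B.shape[0]

    def require_valid(self) -> None:
        """Raise ``ValueError`` if the model violates any invariant."""
        report = validate_model(self)
        if report.violations:
            raise ValueError("invalid generative model:\n" + str(report))


@dataclass(frozen=True)
class PolicySet:
    """Allowable policies: K control-state sequences of length horizon - 1."""

    policies: np.ndarray     # (K, horizon - 1) integer control indices
    scheme: str

    def __post_init__(self):
        object.__setattr__(
            self, "policies", np.asarray(self.policies, dtype=np.intp)
        )

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    def control_at(self, t: int) -> np.ndarray:
        """Control prescribed by each policy at trial ``t`` (1-based, t < horizon)."""
        return self.policies[:, t - 1]


@dataclass
class ValidationReport:
    """Accumulated invariant violations, each with a human-readable location."""

    violations: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    def __bool__(self) -> bool:  # truthy iff the model is valid
        return not self.violations

    def __str__(self) -> str:
        return "\n".join(self.violations) if self.violations else "ok"


def _check_stochastic(report: ValidationReport, M: np.ndarray, name: str) -> None:
    if (M < 0).any():
        rows, cols = np.nonzero(M < 0)
        report.add(f"{name}: negative probability at entry ({rows[0]}, {cols[0]})")
    sums = M.sum(axis=0)
    bad = np.nonzero(np.abs(sums - 1.0) > _STOCHASTIC_TOL)[0]
    for j in bad:
        report.add(f"{name}: column {j} sums to {sums[j]:.12g}, expected 1")


def _check_simplex(report: ValidationReport, v: np.ndarray, name: str) -> None:
    if (v < 0).any():
        report.add(f"{name}: negative probability at entry {int(np.argmin(v))}")
    if abs(v.sum() - 1.0) > _STOCHASTIC_TOL:
        report.add(f"{name}: sums to {v.sum():.12g}, expected 1")


def validate_model(model: GenerativeModel) -> ValidationReport:
    """Check every structural invariant of a :class:`GenerativeModel`.

    Returns a report listing each violation with its location; the report is
    empty (truthy) iff the model is valid.  This is a reporting operation —
    it never raises.
    """
    report = ValidationReport()
    if model.A.ndim != 2:
        report.add(f"A: expected 2 dimensions, got {model.A.ndim}")
        return report
    J = model.A.shape[1]
    _check_stochastic(report, model.A, "A")
    if model.B.ndim != 3 or model.B.shape[1:] != (J, J):
        report.add(f"B: expected shape (n_controls, {J}, {J}), got {model.B.shape}")
    else:
        for u in range(model.B.shape[0]):
            _check_stochastic(report, model.B[u], f"B[{u}]")
    for vec, name in ((model.c, "c"), (model.d, "d")):
        if vec.shape != (J,):
            report.add(f"{name}: expected length {J}, got shape {vec.shape}")
        else:
            _check_simplex(report, vec, name)
    if not model.alpha > 0:
        report.add(f"alpha: must be positive, got {model.alpha}")
    if not model.beta > 0:
        report.add(f"beta: must be positive, got {model.beta}")
    if model.horizon < 1:
        report.add(f"horizon: must be >= 1, got {model.horizon}")
    if not np.isfinite(model.log_floor):
        report.add(f"log_floor: must be finite, got {model.log_floor}")
    else:
        positive = []
        for arr in (model.A, model.B, model.c, model.d):
            a = np.asarray(arr, dtype=float)
            if (a > 0).any():
                positive.append(a[a > 0].min())
        if positive and model.log_floor > np.log(min(positive)):
            report.add(
                f"log_floor: {model.log_floor} exceeds log of smallest "
                f"positive entry {np.log(min(positive)):.6g}"
            )
    return report


def make_policy_set(horizon: int, n_controls: int, scheme: str = "stay_then_shift") -> PolicySet:
    """Construct the allowable policy set for a given scheme.

    ``stay_then_shift`` (requires 2 controls, 0 = stay, 1 = shift) yields
    ``horizon`` policies: "shift exactly at step k" for k = 1..horizon-1,
    plus the all-stay policy.  This spans the behaviourally distinct options
    whenever the shift leads into an absorbing state, while keeping the
    number of policies linear in the horizon.

    ``exhaustive`` yields all ``n_controls**(horizon-1)`` sequences; only
    sensible for small horizons.
    """
    if horizon < 2:
        raise ValueError("horizon must be >= 2 to form nonempty policies")
    steps = horizon - 1
    if scheme == "stay_then_shift":
        if n_controls < 2:
            raise ValueError("stay_then_shift requires at least 2 control states")
        policies = np.zeros((horizon, steps), dtype=np.intp)
        for k in range(steps):
            policies[k, k] = 1
        # last row: all-stay
        return PolicySet(policies=policies, scheme=scheme)
    if scheme == "exhaustive":
        grids = np.meshgrid(*([np.arange(n_controls)] * steps), indexing="ij")
        policies = np.stack([g.ravel() for g in grids], axis=1)
        return PolicySet(policies=policies, scheme=scheme)
    raise ValueError(f"unknown policy scheme: {scheme!r}")


def write_model(model: GenerativeModel, path: str | Path, policy_scheme: str = "stay_then_shift") -> None:
    """Serialize a model to a YAML document (lists of rows for matrices)."""
    doc = {
        "schema_version": 1,
        "A": model.A.tolist(),
        "B": model.B.tolist(),
        "c": model.c.tolist(),
        "d": model.d.tolist(),
        "alpha": float(model.alpha),
        "beta": float(model.beta),
        "horizon": int(model.horizon),
        "policy_scheme": policy_scheme,
        "log_floor": float(model.log_floor),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path: str | Path) -> tuple[GenerativeModel, str]:
    """Load a model file, returning the model and its policy scheme label.

    Raises ``ValueError`` if the file fails :func:`validate_model`.
    """
    doc = yaml.safe_load(Path(path).read_text())
    required = {"A", "B", "c", "d", "horizon"}
    missing = required - set(doc)
    if missing:
        raise ValueError(f"model file missing keys: {sorted(missing)}")
    model = GenerativeModel(
        A=np.asarray(doc["A"], dtype=float),
        B=np.asarray(doc["B"], dtype=float),
        c=np.asarray(doc["c"], dtype=float),
        d=np.asarray(doc["d"], dtype=float),
        horizon=int(doc["horizon"]),
        alpha=float(doc.get("alpha", 8.0)),
        beta=float(doc.get("beta", 1.0)),
        log_floor=float(doc.get("log_floor", DEFAULT_LOG_FLOOR)),
    )
    model.require_valid()
    return model, str(doc.get("policy_scheme", "stay_then_shift"))
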