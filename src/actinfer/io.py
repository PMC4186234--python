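"""Configuration files, trace writers and seed management.

Run configurations are YAML documents with an explicit ``schema_version``.
Game traces are written as CSV with one row per variational iteration —
small, diff-friendly and trivially re-loadable — with numbers in their
shortest round-tripping decimal form so a read-back reconstructs the
precision sequence exactly.  Trial indices are 1-based in all files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .inference import DEFAULT_MAX_ITER, DEFAULT_TOL
from .neuromod import DEFAULT_TAU, DopamineTrace
from .simulate import GameTrace

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_game_trace",
    "read_game_trace",
    "write_dopamine_trace",
]

SCHEMA_VERSION = 1
_TASKS = ("limited_offer", "random", "file")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-identically."""

    task: str = "limited_offer"
    task_params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    tau: float = DEFAULT_TAU
    output_dir: str = "."
    verbosity: str = "info"

    def validate(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"task: must be one of {_TASKS}, got {self.task!r}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed: must be an integer, got {self.seed!r}")
        if not self.tol > 0:
            raise ValueError(f"tol: must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter: must be >= 1, got {self.max_iter}")
        if not self.tau > 0:
            raise ValueError(f"tau: must be positive, got {self.tau}")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a run configuration, filling documented defaults."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    doc.pop("schema_version", None)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **asdict(cfg)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def game_trace_frame(trace: GameTrace) -> pd.DataFrame:
    """Per-iteration DataFrame view of a game trace."""
    rows = []
    for rec in trace.records:
        n_iter = len(rec.gamma_iterations)
        belief_iters = rec.belief  # converged belief; per-iteration gammas recorded
        for i in range(n_iter):
            row: dict[str, Any] = {
                "trial": rec.trial,
                "iteration": i + 1,
                "gamma_hat": rec.gamma_iterations[i],
                "true_state": rec.true_state,
                "observation": rec.observation,
                "action": -1 if rec.action is None else rec.action,
            }
            for j, v in enumerate(belief_iters.s_hat[-1], start=1):
                row[f"s_hat_{j}"] = v
            for k, v in enumerate(belief_iters.pi_hat, start=1):
                row[f"pi_hat_{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def write_game_trace(trace: GameTrace, path: str | Path) -> None:
    """Write the per-iteration trace CSV.

    Numbers use the shortest round-tripping decimal representation, so a
    read-back reconstructs the gamma sequence exactly.
    """
    game_trace_frame(trace).to_csv(path, index=False)


def read_game_trace(path: str | Path) -> pd.DataFrame:
    # float_precision="round_trip" so the written shortest-repr decimals
    # parse back to bit-identical doubles
    return pd.read_csv(path, float_precision="round_trip")


def write_dopamine_trace(
    dopamine: DopamineTrace, reconstruction, path: str | Path
) -> None:
    """Write the deconvolved impulse series next to its reconstruction."""
    frame = pd.DataFrame(
        {
            "iteration": range(1, len(dopamine.impulses) + 1),
            "impulse": dopamine.impulses,
            "reconstruction": reconstruction,
        }
    )
    frame.to_csv(path, index=False)
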