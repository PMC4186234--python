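"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: Finite stand-in for log(0).  Far below any realistic log-probability at
#: the state-space sizes this package targets, but small enough that softmax
#: arguments never overflow.
DEFAULT_LOG_FLOOR = -32.0


def floored_log(x: np.ndarray, log_floor: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """Elementwise natural log with zeros mapped to a finite floor.

    Negative inputs are invalid probabilities and also map to the floor;
    callers are expected to have validated their inputs.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, log_floor, dtype=float)
    np.log(x, where=x > 0, out=out)
    return out


def softmax(v: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    v = np.asarray(v, dtype=float)
    v = v - v.max(axis=-1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=-1, keepdims=True)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    pos = p > 0
    return float(-(p[pos] * np.log(p[pos])).sum())
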