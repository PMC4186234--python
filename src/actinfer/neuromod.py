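"""Simulated dopamine responses from precision dynamics.

The per-iteration expected-precision sequence of a game (concatenated across
trials) is interpreted as a smoothed trace of underlying phasic events.
Deconvolving it against an exponentially decaying kernel — time constant
8 iterations by default, standing in for the decaying postsynaptic effect
of released dopamine — yields an impulse series whose causal reconvolution
reproduces the precision trace.  Because the convolution operator is lower
triangular with unit diagonal, the least-squares deconvolution is exact.

Impulses are not constrained to be non-negative; dips below zero are
interpretable as transient suppression below tonic firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

__all__ = ["DeconvKernel", "DopamineTrace", "exp_kernel", "deconvolve_precision", "reconvolve"]

DEFAULT_TAU = 8.0


@dataclass(frozen=True)
class DeconvKernel:
    """Exponentially decaying kernel h_i = exp(-i / tau), i = 0..length-1."""

    tau: float
    weights: np.ndarray

    @property
    def length(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class DopamineTrace:
    """Deconvolved impulse series and its reconstruction error."""

    impulses: np.ndarray
    residual_norm: float


def exp_kernel(tau: float = DEFAULT_TAU, length: int = 64) -> DeconvKernel:
    """Exponential kernel with decay time constant ``tau`` (in iterations)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    i = np.arange(length, dtype=float)
    return DeconvKernel(tau=float(tau), weights=np.exp(-i / tau))


def _first_column(kernel: DeconvKernel, n: int) -> np.ndarray:
    """Kernel truncated or zero-padded to the sequence length."""
    col = np.zeros(n)
    m = min(n, kernel.length)
    col[:m] = kernel.weights[:m]
    return col


def deconvolve_precision(gamma_seq: np.ndarray, kernel: DeconvKernel) -> DopamineTrace:
    """Least-squares deconvolution of a precision sequence.

    Solves the causal convolution system H x = g where H is the lower
    triangular Toeplitz matrix of kernel weights.  H has a unit diagonal, so
    the minimizer is the exact triangular solve and the residual is at float
    tolerance.
    """
    g = np.asarray(gamma_seq, dtype=float)
    if g.ndim != 1 or len(g) == 0:
        raise ValueError("gamma_seq must be a nonempty 1-d sequence")
    n = len(g)
    col = _first_column(kernel, n)
    row = np.zeros(n)
    row[0] = col[0]
    x = solve_toeplitz((col, row), g)
    residual = float(np.linalg.norm(reconvolve_array(x, kernel) - g))
    return DopamineTrace(impulses=x, residual_norm=residual)


def reconvolve_array(impulses: np.ndarray, kernel: DeconvKernel) -> np.ndarray:
    """Causal convolution of an impulse series with the kernel."""
    x = np.asarray(impulses, dtype=float)
    return np.convolve(x, _first_column(kernel, len(x)))[: len(x)]


def reconvolve(trace: DopamineTrace, kernel: DeconvKernel) -> np.ndarray:
    """Reconstruct the precision sequence from a dopamine trace (round-trip check)."""
    return reconvolve_array(trace.impulses, kernel)
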