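"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: divergences
are accumulated by explicit summation over final states, softmax functions
are evaluated term by term with math.exp, and transition compositions apply
one matrix-vector product at a time.
"""

import math

import numpy as np

LOG_FLOOR = -32.0


def _ln(x: float) -> float:
    return math.log(x) if x > 0 else LOG_FLOOR


def final_state_distribution(B, policy, t, horizon, start_state):
    """Propagate a point mass through B(u_t)..B(u_{T-1}) one step at a time."""
    p = [0.0] * B.shape[1]
    p[start_state] = 1.0
    for step in range(t, horizon):
        u = policy[step - 1]
        p = [sum(B[u][i][j] * p[j] for j in range(len(p))) for i in range(len(p))]
    return p


def neg_kl_direct(p, c):
    """-KL(p || c) by direct summation, with log-floored zero goal entries."""
    total = 0.0
    for pf, cf in zip(p, c):
        if pf > 0:
            total -= pf * (math.log(pf) - _ln(cf))
    return total


def softmax_direct(values):
    """Softmax evaluated term by term (max-shifted for stability)."""
    m = max(values)
    exps = [math.exp(v - m) for v in values]
    z = sum(exps)
    return [e / z for e in exps]


def state_update_direct(A, B, d, obs_index, prev_s, prev_action, Q, pi, gamma):
    """Direct evaluation of the perception update for one trial."""
    J = A.shape[1]
    log_lik = [_ln(A[obs_index][j]) for j in range(J)]
    if prev_s is None:
        log_prior = [_ln(d[j]) for j in range(J)]
    else:
        pred = [sum(B[prev_action][i][j] * prev_s[j] for j in range(J)) for i in range(J)]
        log_prior = [_ln(pred[i]) for i in range(J)]
    value = [gamma * sum(Q[k][j] * pi[k] for k in range(len(pi))) for j in range(J)]
    return softmax_direct([log_lik[j] + log_prior[j] + value[j] for j in range(J)])


def policy_update_direct(Q, s, gamma):
    """Direct evaluation of the action-selection update."""
    return softmax_direct([gamma * sum(Q[k][j] * s[j] for j in range(len(s))) for k in range(len(Q))])


def precision_update_direct(alpha, beta, Q, s, pi):
    """Direct evaluation of the confidence update."""
    ev = sum(pi[k] * Q[k][j] * s[j] for k in range(len(pi)) for j in range(len(s)))
    beta_hat = beta - ev
    return beta_hat, alpha / beta_hat


def entropy_direct(p):
    return -sum(pf * math.log(pf) for pf in p if pf > 0)


def convolve_direct(x, kernel_weights):
    """Causal convolution by explicit double loop."""
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        for j in range(0, i + 1):
            if i - j < len(kernel_weights):
                out[i] += kernel_weights[i - j] * x[j]
    return out
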