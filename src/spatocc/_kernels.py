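"""Numba-compiled likelihood kernels.

The hot path evaluates, for every site at once, the log of

    Pr(history_i) = psi_i * F_i + (1 - psi_i) * I[no detection observed]

where F_i is the probability of the observed segment outcomes given the site
is occupied.  In the correlated model F_i comes from a two-state forward
recursion over latent segment-level presence; in the standard model segments
are independent Bernoulli trials.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MISSING = -1


@njit(cache=True)
def loglik_correlated(y, psi, p, theta0, theta1, pi):  # pragma: no cover - numba
    n, K = y.shape
    out = np.empty(n)
    for i in range(n):
        f0 = 1.0 - pi
        f1 = pi
        logscale = 0.0
        nodet = True
        dead = False  # forward mass exactly zero
        for k in range(K):
            if k > 0:
                g0 = f0 * (1.0 - theta0) + f1 * (1.0 - theta1)
                g1 = f0 * theta0 + f1 * theta1
                f0 = g0
                f1 = g1
            yk = y[i, k]
            if yk == 1:
                nodet = False
                f0 = 0.0
                f1 = f1 * p[i, k]
            elif yk == 0:
                f1 = f1 * (1.0 - p[i, k])
            # missing segment: emission factor 1, chain still transitions
            s = f0 + f1
            if s <= 0.0:
                dead = True
                break
            if s < 1e-250:
                f0 /= s
                f1 /= s
                logscale += np.log(s)
        if dead:
            F = 0.0
            logF = -np.inf
        else:
            F = 0.0  # unused marker; likelihood assembled in log space below
            logF = np.log(f0 + f1) + logscale
        if nodet:
            # psi*F + (1-psi); F <= 1 so no overflow concern
            if logF == -np.inf:
                lik = 1.0 - psi[i]
            else:
                lik = psi[i] * np.exp(logF) + (1.0 - psi[i])
            out[i] = np.log(lik) if lik > 0.0 else -np.inf
        else:
            if logF == -np.inf or psi[i] <= 0.0:
                out[i] = -np.inf
            else:
                out[i] = np.log(psi[i]) + logF
    return out


@njit(cache=True)
def loglik_standard(y, psi, p):  # pragma: no cover - numba
    n, K = y.shape
    out = np.empty(n)
    for i in range(n):
        logF = 0.0
        nodet = True
        dead = False
        for k in range(K):
            yk = y[i, k]
            if yk == 1:
                nodet = False
                if p[i, k] <= 0.0:
                    dead = True
                    break
                logF += np.log(p[i, k])
            elif yk == 0:
                if p[i, k] >= 1.0:
                    dead = True
                    break
                logF += np.log(1.0 - p[i, k])
        if nodet:
            F = 0.0 if dead else np.exp(logF)
            lik = psi[i] * F + (1.0 - psi[i])
            out[i] = np.log(lik) if lik > 0.0 else -np.inf
        else:
            if dead or psi[i] <= 0.0:
                out[i] = -np.inf
            else:
                out[i] = np.log(psi[i]) + logF
    return out


@njit(cache=True)
def detection_count_probs(y, psi, p, theta0, theta1, pi):  # pragma: no cover - numba
    """Per-site distribution of the total number of detections.

    Dynamic program over (latent state, running count); missing segments
    transition the chain but cannot yield detections.  Returns (n, K+1)
    probabilities; column t is Pr(total detections = t).
    """
    n, K = y.shape
    out = np.zeros((n, K + 1))
    for i in range(n):
        f0 = np.zeros(K + 1)
        f1 = np.zeros(K + 1)
        f0[0] = 1.0 - pi
        f1[0] = pi
        for k in range(K):
            if k > 0:
                for t in range(K + 1):
                    g0 = f0[t] * (1.0 - theta0) + f1[t] * (1.0 - theta1)
                    g1 = f0[t] * theta0 + f1[t] * theta1
                    f0[t] = g0
                    f1[t] = g1
            if y[i, k] != MISSING:
                pk = p[i, k]
                for t in range(K, 0, -1):
                    f1[t] = f1[t] * (1.0 - pk) + f1[t - 1] * pk
                f1[0] = f1[0] * (1.0 - pk)
        for t in range(K + 1):
            out[i, t] = psi[i] * (f0[t] + f1[t])
        out[i, 0] += 1.0 - psi[i]
    return out


@njit(cache=True)
def detection_count_pair_probs(y, psi, p, theta0, theta1, pi, split):  # pragma: no cover
    """Joint distribution of detection counts in segments [0, split) and
    [split, K).  Returns (n, split+1, K-split+1) probabilities."""
    n, K = y.shape
    n1 = split + 1
    n2 = K - split + 1
    out = np.zeros((n, n1, n2))
    for i in range(n):
        f0 = np.zeros((n1, n2))
        f1 = np.zeros((n1, n2))
        f0[0, 0] = 1.0 - pi
        f1[0, 0] = pi
        for k in range(K):
            if k > 0:
                for a in range(n1):
                    for b in range(n2):
                        g0 = f0[a, b] * (1.0 - theta0) + f1[a, b] * (1.0 - theta1)
                        g1 = f0[a, b] * theta0 + f1[a, b] * theta1
                        f0[a, b] = g0
                        f1[a, b] = g1
            if y[i, k] != MISSING:
                pk = p[i, k]
                if k < split:
                    for a in range(n1 - 1, 0, -1):
                        for b in range(n2):
                            f1[a, b] = f1[a, b] * (1.0 - pk) + f1[a - 1, b] * pk
                    for b in range(n2):
                        f1[0, b] = f1[0, b] * (1.0 - pk)
                else:
                    for b in range(n2 - 1, 0, -1):
                        for a in range(n1):
                            f1[a, b] = f1[a, b] * (1.0 - pk) + f1[a, b - 1] * pk
                    for a in range(n1):
                        f1[a, 0] = f1[a, 0] * (1.0 - pk)
        for a in range(n1):
            for b in range(n2):
                out[i, a, b] = psi[i] * (f0[a, b] + f1[a, b])
        out[i, 0, 0] += 1.0 - psi[i]
    return out
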