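"""Compiled inner loops for the latent-layer scan.

One fused kernel computes, for every cluster: the log mixture entries of
G(y_it), the scaled forward pass, the backward state draw, and the member
state draws. Randomness enters through pre-drawn uniforms so the kernel is
deterministic given its inputs. The pure-numpy implementations in
:mod:`phmm.likelihood` / :mod:`phmm.sampler` remain the reference; this
kernel is cross-checked against them in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["latent_scan_kernel"]


@njit(cache=True)
def latent_scan_kernel(Lm, Qn, pi_n, P_n, u_last, u_back, u_mem, identity):
    """Fused latent scan.

    Parameters
    ----------
    Lm : (N, T, M, Cm) member-visit log emission likelihoods per state
    Qn : (N, M, C, Cm) perception matrices already indexed by cluster arm
    pi_n : (N, C) initial probabilities per cluster
    P_n : (N, C, C) transition matrices per cluster
    u_last, u_back, u_mem : pre-drawn uniforms, shapes (N,), (N, T-1),
        (N, T, M)
    identity : bool, member states copy cluster states

    Returns
    -------
    Z (N, T), Zm (N, T, M), log_c (N, T)
    """
    N, T, M, Cm = Lm.shape
    C = pi_n.shape[1]
    logG = np.empty((N, T, C))
    for n in range(N):
        for t in range(T):
            for h in range(C):
                logG[n, t, h] = 0.0
            for m in range(M):
                mx = Lm[n, t, m, 0]
                for k in range(1, Cm):
                    if Lm[n, t, m, k] > mx:
                        mx = Lm[n, t, m, k]
                for h in range(C):
                    acc = 0.0
                    for k in range(Cm):
                        acc += np.exp(Lm[n, t, m, k] - mx) * Qn[n, m, h, k]
                    if acc < 1e-300:
                        acc = 1e-300
                    logG[n, t, h] += np.log(acc) + mx

    alpha = np.empty((N, T, C))
    log_c = np.empty((N, T))
    pred = np.empty(C)
    for n in range(N):
        for h in range(C):
            pred[h] = pi_n[n, h]
        for t in range(T):
            mx = logG[n, t, 0]
            for h in range(1, C):
                if logG[n, t, h] > mx:
                    mx = logG[n, t, h]
            c = 0.0
            for h in range(C):
                alpha[n, t, h] = pred[h] * np.exp(logG[n, t, h] - mx)
                c += alpha[n, t, h]
            if c <= 0.0:
                raise FloatingPointError("zero forward likelihood")
            for h in range(C):
                alpha[n, t, h] /= c
            log_c[n, t] = np.log(c) + mx
            if t < T - 1:
                for h in range(C):
                    pred[h] = 0.0
                for k in range(C):
                    ak = alpha[n, t, k]
                    for h in range(C):
                        pred[h] += ak * P_n[n, k, h]

    Z = np.empty((N, T), dtype=np.int64)
    prob = np.empty(C)
    for n in range(N):
        u = u_last[n]
        acc = 0.0
        Z[n, T - 1] = C - 1
        for h in range(C):
            acc += alpha[n, T - 1, h]
            if u <= acc:
                Z[n, T - 1] = h
                break
        for t in range(T - 2, -1, -1):
            tot = 0.0
            for h in range(C):
                prob[h] = alpha[n, t, h] * P_n[n, h, Z[n, t + 1]]
                tot += prob[h]
            if tot <= 0.0:
                raise FloatingPointError("degenerate backward distribution")
            u = u_back[n, t] * tot
            acc = 0.0
            Z[n, t] = C - 1
            for h in range(C):
                acc += prob[h]
                if u <= acc:
                    Z[n, t] = h
                    break

    Zm = np.empty((N, T, M), dtype=np.int64)
    pmem = np.empty(Cm)
    if identity:
        for n in range(N):
            for t in range(T):
                for m in range(M):
                    Zm[n, t, m] = Z[n, t]
    else:
        for n in range(N):
            for t in range(T):
                h = Z[n, t]
                for m in range(M):
                    mx = Lm[n, t, m, 0]
                    for k in range(1, Cm):
                        if Lm[n, t, m, k] > mx:
                            mx = Lm[n, t, m, k]
                    tot = 0.0
                    for k in range(Cm):
                        q = Qn[n, m, h, k]
                        if q < 1e-300:
                            q = 1e-300
                        pmem[k] = np.exp(Lm[n, t, m, k] - mx) * q
                        tot += pmem[k]
                    u = u_mem[n, t, m] * tot
                    acc = 0.0
                    Zm[n, t, m] = Cm - 1
                    for k in range(Cm):
                        acc += pmem[k]
                        if u <= acc:
                            Zm[n, t, m] = k
                            break
    return Z, Zm, log_c
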