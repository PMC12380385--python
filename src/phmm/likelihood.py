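"""Emission densities, perception-marginalized mixtures, forward recursion.

The per-visit likelihood enters the cluster-level chain through a diagonal
matrix G(y_it) whose h-th entry mixes each member's emission likelihood over
that member's latent state:

    g_h = prod_m sum_k [ prod_j f(y_ijt^m | member state k) ] * Q_m[h, k]

i.e. one shared member state drives all of a member's outcomes at a visit,
so the sum over the member state sits OUTSIDE the product over that
member's outcomes (``mixture_form="member"``, the generative-model-
consistent default). The alternative ``"outcome"`` form mixes each outcome
independently (product over outcomes outside the sum) and is provided for
comparison only.

The forward recursion alpha_t = alpha_{t-1} P G(y_t) is run in scaled form:
alpha rows are normalized each visit and the log scaling constants
accumulated; each constant is the one-step-ahead predictive likelihood of
that visit's data, and their sum is the cluster log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .panel import PanelData
from .params import ModelSpec, ParameterSet

__all__ = [
    "ForwardResult",
    "emission_logpdf",
    "member_mixture_vector",
    "forward",
    "marginal_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ForwardResult:
    """Scaled forward pass for one cluster.

    alpha : (n, C) scaled forward probabilities (rows sum to 1).
    log_c : (n,) per-visit log scaling constants.
    loglik : float, total log-likelihood = sum(log_c).
    """

    alpha: np.ndarray
    log_c: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.log_c.sum())


def emission_logpdf(y, state: int, b_entry: float, X_row, tau, beta, gamma):
    """Gaussian log density of one outcome cell given a member state.

    ``state`` is 1-based. The mean is the state's cumulative mean increment
    plus covariate and random-effect contributions; the variance is the
    cumulative variance increment. A missing (NaN) cell contributes log 1 = 0.
    """
    tau = np.asarray(tau, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if not 1 <= state <= len(tau):
        raise ValueError("state out of range")
    var = gamma[:state].sum()
    if var <= 0:
        raise ValueError("cumulative state variance must be positive")
    X_row = np.asarray(X_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    mean = tau[:state].sum() + (X_row @ beta if X_row.size else 0.0) + b_entry
    y = np.asarray(y, dtype=float)
    out = -0.5 * (_LOG2PI + np.log(var) + (y - mean) ** 2 / var)
    return np.where(np.isnan(y), 0.0, out)


# ---------------------------------------------------------------------------
# vectorized internals shared with the sampler


def _state_logliks(y, X, b, params: ParameterSet):
    """Per-cell log emission density for every member state.

    Returns (N, T, M, J, Cm); missing cells are exactly zero.
    """
    N, T, M, J = y.shape
    means = np.cumsum(params.tau, axis=-1)        # (M, J, Cm)
    variances = np.cumsum(params.gamma, axis=-1)
    if np.any(variances <= 0):
        raise ValueError("non-positive cumulative state variance")
    xb = np.einsum("ntq,mjq->ntmj", X, params.beta)   # (N, T, M, J)
    bmat = b.reshape(N, M, J)
    mu = (means[None, None] + xb[..., None]
          + bmat[:, None, :, :, None])                # (N, T, M, J, Cm)
    resid2 = (np.nan_to_num(y)[..., None] - mu) ** 2
    ll = -0.5 * (_LOG2PI + np.log(variances)[None, None] + resid2 / variances)
    return np.where(np.isnan(y)[..., None], 0.0, ll)


def _member_logliks(y, X, b, params: ParameterSet):
    """(N, T, M, Cm): member-visit log-likelihood for each member state."""
    return _state_logliks(y, X, b, params).sum(axis=3)


def _mix_one(L, Q_m):
    # L: (..., Cm) log emission likelihoods; returns (..., C) log mixture
    mx = L.max(axis=-1, keepdims=True)
    A = np.exp(L - mx)
    mixed = A @ Q_m.T                       # (..., C)
    return np.log(np.maximum(mixed, 1e-300)) + mx


def _log_G(panel: PanelData, params: ParameterSet, b,
           mixture_form: str = "member", Lm=None):
    """Log diagonal entries of G(y_it) for every cluster-visit.

    Returns (N, T, C). Padded (beyond-follow-up) visits give zeros, so they
    pass through the recursion without affecting the likelihood. ``Lm``
    may carry precomputed member log-likelihoods for the member form.
    """
    y, X, arm = panel.y, panel.X, panel.arm
    N, T, M, J = y.shape

    per_arm_Q = params.Q.ndim == 4
    arms = np.unique(arm) if per_arm_Q else [None]
    if mixture_form == "member":
        if Lm is None:
            Lm = _member_logliks(y, X, b, params)    # (N, T, M, Cm)
        C = params.P.shape[-1]
        out = np.zeros((N, T, C))
        for s in arms:
            sel = slice(None) if s is None else (arm == s)
            Q = params.Q if s is None else params.Q[s]
            for m in range(M):
                out[sel] += _mix_one(Lm[sel][:, :, m], Q[m])
    elif mixture_form == "outcome":
        Lc = _state_logliks(y, X, b, params)     # (N, T, M, J, Cm)
        C = params.P.shape[-1]
        out = np.zeros((N, T, C))
        for s in arms:
            sel = slice(None) if s is None else (arm == s)
            Q = params.Q if s is None else params.Q[s]
            for m in range(M):
                for j in range(J):
                    out[sel] += _mix_one(Lc[sel][:, :, m, j], Q[m])
    else:
        raise ValueError("mixture_form must be 'member' or 'outcome'")
    return out


def _forward_all(panel: PanelData, params: ParameterSet, b,
                 mixture_form: str = "member", Lm=None):
    """Scaled forward pass for every cluster at once.

    Returns (alpha (N, T, C), log_c (N, T)).
    """
    logG = _log_G(panel, params, b, mixture_form, Lm=Lm)
    N, T, C = logG.shape
    Ps = params.P[panel.arm]          # (N, C, C)
    alpha = np.empty((N, T, C))
    log_c = np.empty((N, T))
    pred = params.pi[panel.arm]       # (N, C)
    for t in range(T):
        mx = logG[:, t].max(axis=1)
        w = np.exp(logG[:, t] - mx[:, None])
        a = pred * w
        c = a.sum(axis=1)
        if np.any(c <= 0):
            bad = int(np.nonzero(c <= 0)[0][0])
            raise FloatingPointError(
                f"zero forward likelihood at cluster {bad}, visit {t + 1}")
        alpha[:, t] = a / c[:, None]
        log_c[:, t] = np.log(c) + mx
        pred = np.einsum("nc,nch->nh", alpha[:, t], Ps)
    return alpha, log_c


def forward(y_i, b_i, arm: int, params: ParameterSet, X_i=None,
            mixture_form: str = "member") -> ForwardResult:
    """Forward pass for a single cluster.

    ``y_i`` is (n, M, J) with NaN for missing cells, ``b_i`` an r-vector,
    ``X_i`` (n, q) covariates (defaults to none).
    """
    y_i = np.asarray(y_i, dtype=float)
    n = y_i.shape[0]
    q = params.beta.shape[-1]
    X_i = np.zeros((n, q)) if X_i is None else np.asarray(X_i, dtype=float)
    panel = PanelData(y=y_i[None], arm=np.array([arm]), X=X_i[None],
                      n_visits=np.array([n]))
    alpha, log_c = _forward_all(panel, params, np.asarray(b_i, float)[None],
                                mixture_form)
    return ForwardResult(alpha=alpha[0], log_c=log_c[0])


def member_mixture_vector(y_itm, b_i, member: int, params: ParameterSet,
                          X_it=None, arm: int = 0) -> np.ndarray:
    """One member's contribution to the diagonal of G(y_it).

    Entry h = sum_k [prod_j f(y_j | member state k)] * Q_m[h, k]; an
    all-missing member-visit returns a vector of ones.
    """
    y_itm = np.asarray(y_itm, dtype=float)
    J = y_itm.shape[0]
    q = params.beta.shape[-1]
    X = (np.zeros(q) if X_it is None else np.asarray(X_it, float))[None, None]
    y = np.full((1, 1, params.tau.shape[0], J), np.nan)
    y[0, 0, member] = y_itm
    L = _member_logliks(y, X, np.asarray(b_i, float)[None], params)[0, 0, member]
    Q = params.Q_for_arm(arm)[member]
    mx = L.max()
    return (np.exp(L - mx) @ Q.T) * np.exp(mx)


def marginal_loglik(panel: PanelData, params: ParameterSet, b=None,
                    n_mc: int = 0, rng=None,
                    mixture_form: str = "member") -> np.ndarray:
    """Per-cluster log-likelihood.

    With ``b`` supplied, conditional on those random effects. With
    ``n_mc > 0``, the random effects are integrated out by Monte Carlo over
    b ~ N(0, Sigma) with ``n_mc`` draws per cluster.
    """
    if (b is None) == (n_mc == 0):
        raise ValueError("supply exactly one of b or n_mc")
    if b is not None:
        _, log_c = _forward_all(panel, params, np.asarray(b, float), mixture_form)
        return log_c.sum(axis=1)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    np.linalg.cholesky(params.Sigma)
    N = panel.n_clusters
    r = params.Sigma.shape[0]
    lls = np.empty((n_mc, N))
    for d in range(n_mc):
        bd = rng.multivariate_normal(np.zeros(r), params.Sigma, size=N,
                                     method="cholesky")
        _, log_c = _forward_all(panel, params, bd, mixture_form)
        lls[d] = log_c.sum(axis=1)
    return logsumexp(lls, axis=0) - np.log(n_mc)
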