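"""Conjugate Gibbs sampler: FFBS for cluster states, member-state draws,
and closed-form updates for every parameter block.

The sampler alternates between drawing the latent layer (cluster state
paths by forward-filtering backward-sampling, then member states from
their exact conditionals) and the parameter layer (Dirichlet rows for the
initial/transition/perception probabilities, a joint Gaussian draw for the
mean increments and covariate coefficients, inverse-Gamma state variances,
Gaussian cluster random effects, and an inverse-Wishart covariance).

Two variance parameterizations are available. ``direct`` (default) treats
each per-state variance as a free inverse-Gamma-conjugate parameter and
reports the corresponding (possibly negative) increments; ``increments``
places the inverse-Gamma prior on the positive variance increments
themselves, which breaks conjugacy and is handled by a
Metropolis-within-Gibbs step that preserves the implied nondecreasing
state-variance constraint.

Estimation runs in two phases: a short pilot chain whose post-burn-in
posterior mean re-initializes a longer production chain from which thinned
draws are retained. Each retained draw is put in a canonical labelling
(see :mod:`phmm.relabel`) before storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import invwishart

from .draws import PosteriorDraws
from .likelihood import _forward_all, _member_logliks
from .panel import PanelData
from .params import (ModelSpec, ParameterSet, PriorConfig,
                     identity_perception, validate)
from .relabel import relabel_draw

__all__ = [
    "SamplerConfig",
    "run_sampler",
    "ffbs_family_states",
    "sample_member_states",
    "update_chain_probs",
    "update_perception",
    "update_regression",
    "update_variances",
    "update_random_effects",
    "update_sigma",
    "initial_parameters",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Two-phase MCMC schedule and sampler options.

    Defaults follow a pilot run of 4,000 iterations (3,000 burn-in) whose
    posterior mean initializes a production run of 40,000 iterations
    (30,000 burn-in); ``thin`` applies to the production phase only.
    """

    phase1_iters: int = 4000
    phase1_burnin: int = 3000
    phase2_iters: int = 40000
    phase2_burnin: int = 30000
    thin: int = 10
    seed: int | None = None
    variance_param: str = "direct"
    relabel: bool = True
    store_latent: bool = True
    mixture_form: str = "member"
    mh_step: float = 0.4
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.phase1_iters < 0 or self.phase1_burnin < 0:
            raise ValueError("phase-1 counts must be non-negative")
        if self.phase1_iters > 0 and self.phase1_burnin >= self.phase1_iters:
            raise ValueError("phase-1 burn-in must be < iterations")
        if not (0 <= self.phase2_burnin < self.phase2_iters):
            raise ValueError("phase-2 burn-in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.variance_param not in ("direct", "increments"):
            raise ValueError("variance_param must be 'direct' or 'increments'")

    def reduced(self, **kw) -> "SamplerConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# latent-layer draws


def _categorical_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of an (n, K) probability matrix."""
    totals = p.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise FloatingPointError("degenerate categorical row (all-zero)")
    cum = np.cumsum(p / totals, axis=-1)
    u = rng.random(p.shape[:-1] + (1,))
    return (u > cum).sum(axis=-1)


def ffbs_family_states(panel: PanelData, b: np.ndarray, params: ParameterSet,
                       rng: np.random.Generator,
                       mixture_form: str = "member",
                       alpha: np.ndarray | None = None) -> np.ndarray:
    """Draw cluster-state paths from their exact full conditional.

    Forward-filter (scaled), then sample backward: the final state from the
    filtered distribution, earlier states proportional to
    ``alpha_t[k] * P[k, z_{t+1}]``. Returns (N, T) 0-based states; visits
    beyond a cluster's follow-up are draws from the prior-propagated chain
    and should be masked by callers. ``alpha`` may carry a precomputed
    filtered forward pass.
    """
    if alpha is None:
        alpha, _ = _forward_all(panel, params, b, mixture_form)
    N, T, C = alpha.shape
    Ps = params.P[panel.arm]
    Z = np.empty((N, T), dtype=np.int64)
    Z[:, T - 1] = _categorical_rows(alpha[:, T - 1], rng)
    for t in range(T - 2, -1, -1):
        back = Ps[np.arange(N), :, Z[:, t + 1]]      # (N, C)
        p = alpha[:, t] * back
        if np.any(p.sum(axis=1) <= 0):
            bad = int(np.nonzero(p.sum(axis=1) <= 0)[0][0])
            raise FloatingPointError(
                f"degenerate backward distribution at cluster {bad}, visit {t + 1}")
        Z[:, t] = _categorical_rows(p, rng)
    return Z


def sample_member_states(panel: PanelData, Z: np.ndarray, b: np.ndarray,
                         params: ParameterSet, rng: np.random.Generator,
                         identity: bool = False,
                         Lm: np.ndarray | None = None) -> np.ndarray:
    """Draw member states given cluster states.

    P(Zm = k) is proportional to Q_m[Z, k] times the member's emission
    likelihood at state k; independent across members and visits given Z.
    """
    if identity:
        return np.repeat(Z[:, :, None], params.tau.shape[0], axis=2)
    if Lm is None:
        Lm = _member_logliks(panel.y, panel.X, b, params)  # (N, T, M, Cm)
    N, T, M, Cm = Lm.shape
    Zm = np.empty((N, T, M), dtype=np.int64)
    per_arm = params.Q.ndim == 4
    for m in range(M):
        if per_arm:
            Qrows = params.Q[panel.arm[:, None], m, Z]    # (N, T, Cm)
        else:
            Qrows = params.Q[m, Z]
        logp = Lm[:, :, m, :] + np.log(np.maximum(Qrows, 1e-300))
        logp -= logp.max(axis=-1, keepdims=True)
        Zm[:, :, m] = _categorical_rows(np.exp(logp), rng)
    return Zm


# ---------------------------------------------------------------------------
# conjugate parameter updates


def _dirichlet_rows(conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    g = rng.gamma(conc)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def update_chain_probs(Z: np.ndarray, arms: np.ndarray, n_visits: np.ndarray,
                       spec: ModelSpec, prior: PriorConfig,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet draws of the initial and transition probabilities.

    Each row's posterior is Dirichlet(prior + counts); empty rows fall
    back to the prior. The initial distribution pools arms when the spec
    ties it across arms.
    """
    S, C = spec.S, spec.C
    init_counts = np.zeros((S, C))
    np.add.at(init_counts, (arms, Z[:, 0]), 1.0)
    if spec.share_initial:
        pooled = _dirichlet_rows(prior.dirichlet + init_counts.sum(0), rng)
        pi = np.broadcast_to(pooled, (S, C)).copy()
    else:
        pi = _dirichlet_rows(prior.dirichlet + init_counts, rng)

    trans = np.zeros((S, C, C))
    T = Z.shape[1]
    for t in range(T - 1):
        sel = (t + 1) < n_visits
        if sel.any():
            np.add.at(trans, (arms[sel], Z[sel, t], Z[sel, t + 1]), 1.0)
    P = _dirichlet_rows(prior.dirichlet + trans, rng)
    return pi, P


def update_perception(Z: np.ndarray, Zm: np.ndarray, arms: np.ndarray,
                      visit_mask: np.ndarray, spec: ModelSpec,
                      prior: PriorConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    """Dirichlet draws of perception rows from cluster/member state cross-counts.

    Identity mode returns the identity without sampling; shared mode pools
    arms; arm-specific mode keeps separate counts per arm.
    """
    if spec.perception_mode == "identity":
        return identity_perception(spec)
    counts = np.zeros((spec.S, spec.M, spec.C, spec.Cm))
    n, t = np.nonzero(visit_mask)
    for m in range(spec.M):
        np.add.at(counts, (arms[n], m, Z[n, t], Zm[n, t, m]), 1.0)
    if spec.perception_mode == "shared":
        return _dirichlet_rows(prior.dirichlet + counts.sum(axis=0), rng)
    return _dirichlet_rows(prior.dirichlet + counts, rng)


def _cumulative_design(Zm_cells: np.ndarray, Cm: int) -> np.ndarray:
    """Design columns of the cumulative state encoding: col l = 1[state >= l]."""
    return (Zm_cells[:, None] >= np.arange(Cm)[None, :]).astype(float)


def update_regression(panel: PanelData, Zm: np.ndarray, b: np.ndarray,
                      state_variances: np.ndarray, rng: np.random.Generator,
                      jitter_log: list | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Joint Gaussian draw of (tau, beta) from the flat-prior WLS conditional.

    For each member-outcome series the design stacks the cumulative state
    encoding with the covariates, weighted by the reciprocal state
    variance; the response subtracts the random-effect contribution.
    Rank-deficient designs (a state never visited) fall back to a small
    ridge, recorded in ``jitter_log``.
    """
    M, J, Cm = state_variances.shape
    q = panel.n_covariates
    tau = np.zeros((M, J, Cm))
    beta = np.zeros((M, J, q))
    for m in range(M):
        for j in range(J):
            obs = np.isfinite(panel.y[:, :, m, j])
            n_idx, t_idx = np.nonzero(obs)
            k = Zm[n_idx, t_idx, m]
            W = np.hstack([_cumulative_design(k, Cm), panel.X[n_idx, t_idx]])
            w = 1.0 / state_variances[m, j, k]
            resp = panel.y[n_idx, t_idx, m, j] - b[n_idx, m * J + j]
            A = (W * w[:, None]).T @ W
            rhs = (W * w[:, None]).T @ resp
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                eps = 1e-6 * (np.trace(A) / A.shape[0] + 1.0)
                if jitter_log is not None:
                    jitter_log.append((m, j, eps))
                L = np.linalg.cholesky(A + eps * np.eye(A.shape[0]))
            mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            drawv = mean + np.linalg.solve(L.T, rng.standard_normal(A.shape[0]))
            tau[m, j] = drawv[:Cm]
            beta[m, j] = drawv[Cm:]
    return tau, beta


def _invgamma(shape, scale, rng: np.random.Generator):
    # guard against underflow of gamma draws at tiny shapes (empty states
    # draw from the near-improper prior); keep variances in a sane range
    g = max(rng.gamma(shape), 1e-290)
    return float(np.clip(scale / g, 1e-10, 1e8))


def update_variances(panel: PanelData, Zm: np.ndarray, tau: np.ndarray,
                     beta: np.ndarray, b: np.ndarray, gamma_cur: np.ndarray,
                     prior: PriorConfig, rng: np.random.Generator,
                     parameterization: str = "direct",
                     reject_log: list | None = None) -> np.ndarray:
    """Draw the variance parameters; returns increment form ``gamma``.

    direct: each per-state variance ~ IG(a + n_k/2, b + SS_k/2)
    independently, then differenced into increments (which may be
    negative). increments: Metropolis-within-Gibbs log-random-walk on the
    positive increments under the IG(a, b) prior, preserving nondecreasing
    state variances; rejections are counted in ``reject_log``.
    """
    M, J, Cm = tau.shape
    means = np.cumsum(tau, axis=-1)
    a0, b0 = prior.ig_shape, prior.ig_scale
    resid = {}
    for m in range(M):
        for j in range(J):
            obs = np.isfinite(panel.y[:, :, m, j])
            n_idx, t_idx = np.nonzero(obs)
            k = Zm[n_idx, t_idx, m]
            e = (panel.y[n_idx, t_idx, m, j]
                 - means[m, j, k]
                 - panel.X[n_idx, t_idx] @ beta[m, j]
                 - b[n_idx, m * J + j])
            resid[m, j] = (k, e)

    gamma = np.empty((M, J, Cm))
    if parameterization == "direct":
        for m in range(M):
            for j in range(J):
                k, e = resid[m, j]
                var = np.empty(Cm)
                for s in range(Cm):
                    sel = k == s
                    n_s = int(sel.sum())
                    ss = float((e[sel] ** 2).sum())
                    var[s] = _invgamma(a0 + n_s / 2.0, b0 + ss / 2.0, rng)
                gamma[m, j] = np.diff(var, prepend=0.0)
        return gamma

    # increments mode: one MH sweep per increment with a log-normal RW
    step = 0.4
    for m in range(M):
        for j in range(J):
            k, e = resid[m, j]
            g = gamma_cur[m, j].copy()
            if np.any(g <= 0):   # re-entry from direct mode: project to positive
                g = np.maximum(g, 1e-4)
            for s in range(Cm):
                prop = g.copy()
                prop[s] = g[s] * np.exp(step * rng.standard_normal())
                if np.any(np.cumsum(prop) <= 0):
                    if reject_log is not None:
                        reject_log.append((m, j, s))
                    continue
                cur_v = np.cumsum(g)[k]
                new_v = np.cumsum(prop)[k]
                ll_cur = -0.5 * (np.log(cur_v) + e ** 2 / cur_v).sum()
                ll_new = -0.5 * (np.log(new_v) + e ** 2 / new_v).sum()
                # IG(a, b) log prior on the increment + log proposal Jacobian
                lp_cur = -(a0 + 1) * np.log(g[s]) - b0 / g[s] + np.log(g[s])
                lp_new = -(a0 + 1) * np.log(prop[s]) - b0 / prop[s] + np.log(prop[s])
                if np.log(rng.random()) < (ll_new + lp_new) - (ll_cur + lp_cur):
                    g = prop
                elif reject_log is not None:
                    reject_log.append((m, j, s))
            gamma[m, j] = g
    return gamma


def update_random_effects(panel: PanelData, Zm: np.ndarray,
                          params: ParameterSet, rng: np.random.Generator
                          ) -> np.ndarray:
    """Exact Gaussian full-conditional draw of every cluster's random effects.

    Combines the N(0, Sigma) prior with the Gaussian cell likelihoods;
    clusters with no observed cells draw from the prior.
    """
    N = panel.n_clusters
    M, J, Cm = params.tau.shape
    r = M * J
    means = np.cumsum(params.tau, axis=-1)
    variances = np.cumsum(params.gamma, axis=-1)
    prec_diag = np.zeros((N, r))
    lin = np.zeros((N, r))
    for m in range(M):
        for j in range(J):
            e = m * J + j
            obs = np.isfinite(panel.y[:, :, m, j])
            k = Zm[:, :, m]
            v = variances[m, j, k]
            w = np.where(obs, 1.0 / v, 0.0)
            resid = np.where(
                obs,
                np.nan_to_num(panel.y[:, :, m, j])
                - means[m, j, k] - panel.X @ params.beta[m, j], 0.0)
            prec_diag[:, e] = w.sum(axis=1)
            lin[:, e] = (w * resid).sum(axis=1)
    Sinv = np.linalg.inv(params.Sigma)
    A = Sinv[None] + prec_diag[:, :, None] * np.eye(r)[None]
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, lin[:, :, None])[:, :, 0]
    z = rng.standard_normal((N, r, 1))
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
    return mean + noise


def update_sigma(b: np.ndarray, prior: PriorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw of the random-effect covariance."""
    N, r = b.shape
    df = prior.iw_df_for(r) + N
    scale = prior.iw_scale_for(r) + b.T @ b
    return invwishart.rvs(df=df, scale=scale, random_state=rng)


# ---------------------------------------------------------------------------
# initialization


def initial_parameters(panel: PanelData, spec: ModelSpec,
                       prior: PriorConfig, rng: np.random.Generator
                       ) -> tuple[ParameterSet, np.ndarray, np.ndarray]:
    """Crude data-driven starting point.

    Cluster states are initialized by k-means on the standardized
    cluster-visit outcome vectors (missing cells imputed at zero after
    standardization), falling back to quantile bins of the composite score
    if clustering degenerates; member states start equal to the cluster
    state, random effects at zero, Sigma at the identity.
    """
    from scipy.cluster.vq import kmeans2

    y, mask = panel.y, panel.observed
    N, T, M, J = y.shape
    flat = y.reshape(N, T, M * J)
    mu = np.nanmean(np.where(mask.reshape(N, T, -1), flat, np.nan), axis=(0, 1))
    sd = np.nanstd(np.where(mask.reshape(N, T, -1), flat, np.nan), axis=(0, 1))
    sd = np.where(sd > 0, sd, 1.0)
    zscore = np.where(mask.reshape(N, T, -1), (flat - mu) / sd, 0.0)
    score = zscore.mean(axis=2)

    def bin_states(values, n_bins):
        edges = np.quantile(values[panel.visit_mask],
                            np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.clip(np.searchsorted(edges, values), 0, n_bins - 1)

    def kmeans_states(n_bins):
        rows = zscore[panel.visit_mask]
        _, labels = kmeans2(rows, n_bins, minit="++", seed=rng, iter=20)
        if len(np.unique(labels)) < n_bins:
            return None
        out = np.zeros((N, T), dtype=int)
        out[panel.visit_mask] = labels
        return out

    Z0 = kmeans_states(spec.C)
    if Z0 is None:
        Z0 = bin_states(score, spec.C)
    if spec.Cm == spec.C:
        Zm0 = np.repeat(Z0[:, :, None], M, axis=2)
    else:
        Zcm = kmeans_states(spec.Cm)
        if Zcm is None:
            Zcm = bin_states(score, spec.Cm)
        Zm0 = np.repeat(Zcm[:, :, None], M, axis=2)

    tau = np.zeros((M, J, spec.Cm))
    gamma = np.zeros((M, J, spec.Cm))
    for m in range(M):
        for j in range(J):
            cells = y[:, :, m, j]
            obs = np.isfinite(cells)
            overall_mean = float(cells[obs].mean()) if obs.any() else 0.0
            overall_var = float(cells[obs].var()) if obs.any() else 1.0
            overall_var = max(overall_var, 1e-6)
            smeans = np.empty(spec.Cm)
            svars = np.empty(spec.Cm)
            for k in range(spec.Cm):
                sel = obs & (Zm0[:, :, m] == k) & panel.visit_mask
                if sel.sum() >= 2:
                    smeans[k] = cells[sel].mean()
                    svars[k] = max(cells[sel].var(), 0.05 * overall_var)
                else:
                    smeans[k], svars[k] = overall_mean, overall_var
            tau[m, j] = np.diff(smeans, prepend=0.0)
            gamma[m, j] = np.diff(svars, prepend=0.0)

    b0 = np.zeros((N, spec.r))
    pi, P = update_chain_probs(Z0, panel.arm, panel.n_visits, spec, prior, rng)
    Q = update_perception(Z0, Zm0, panel.arm, panel.visit_mask, spec, prior, rng)
    params = ParameterSet(pi=pi, P=P, Q=Q, tau=tau,
                          beta=np.zeros((M, J, spec.q)), gamma=gamma,
                          Sigma=np.eye(spec.r))
    return params, b0, Zm0


# ---------------------------------------------------------------------------
# driver


def _latent_scan(panel, spec, config, params, b, rng):
    """Draw (Z, Zm) given the current parameters, sharing the emission
    likelihood cube and forward pass; returns (Z, Zm, log_c)."""
    if config.mixture_form == "member":
        from ._kernels import latent_scan_kernel

        Lm = _member_logliks(panel.y, panel.X, b, params)
        N, T = Lm.shape[:2]
        Qn = (params.Q[panel.arm] if params.Q.ndim == 4
              else np.broadcast_to(params.Q, (N,) + params.Q.shape))
        Z, Zm, log_c = latent_scan_kernel(
            np.ascontiguousarray(Lm), np.ascontiguousarray(Qn),
            np.ascontiguousarray(params.pi[panel.arm]),
            np.ascontiguousarray(params.P[panel.arm]),
            rng.random(N), rng.random((N, max(T - 1, 0))),
            rng.random((N, T, spec.M)),
            spec.perception_mode == "identity")
        return Z, Zm, log_c
    alpha, log_c = _forward_all(panel, params, b, config.mixture_form)
    Z = ffbs_family_states(panel, b, params, rng, config.mixture_form,
                           alpha=alpha)
    Zm = sample_member_states(panel, Z, b, params, rng,
                              identity=spec.perception_mode == "identity")
    return Z, Zm, log_c


def _one_scan(panel, spec, config, params, b, rng, frozen, logs):
    """One full Gibbs scan; returns (params, b)."""
    Z, Zm, _ = _latent_scan(panel, spec, config, params, b, rng)
    return _finish_scan(panel, spec, config, params, b, Z, Zm, rng, frozen,
                        logs)


def run_sampler(panel: PanelData, spec: ModelSpec,
                config: SamplerConfig | None = None,
                init_params: ParameterSet | None = None,
                init_b: np.ndarray | None = None,
                frozen: frozenset = frozenset(),
                rng: np.random.Generator | None = None) -> PosteriorDraws:
    """Run the full two-phase sampler and return retained draws.

    ``frozen`` names parameter blocks held fixed at their initial values
    (any of ``chain``, ``perception``, ``regression``, ``variance``, ``b``,
    ``sigma``) — used by the constrained perception approximation and by
    validation tests.
    """
    config = config or SamplerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    logs = {"jitter": [], "reject": [], "relabels": 0}

    params0, b0, _ = initial_parameters(panel, spec, config.prior, rng)
    params = init_params.copy() if init_params is not None else params0
    b = init_b.copy() if init_b is not None else b0

    problems = validate(params, spec)
    if problems:
        raise ValueError(f"initial parameters invalid: {problems}")

    # phase 1: pilot run, re-initialize at the post-burn-in mean
    if config.phase1_iters > 0:
        kept = []
        for it in range(config.phase1_iters):
            params, b = _one_scan(panel, spec, config, params, b, rng,
                                  frozen, logs)
            if it >= config.phase1_burnin:
                rl = (relabel_draw(params, spec)[0] if config.relabel
                      else params.copy())
                kept.append(rl)
        mean = {}
        for f in ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma"):
            mean[f] = np.mean([getattr(k, f) for k in kept], axis=0)
        for f in ("pi", "P", "Q"):
            mean[f] = mean[f] / mean[f].sum(axis=-1, keepdims=True)
        # guard: mean of direct-mode draws can have non-monotone variances
        cv = np.cumsum(mean["gamma"], axis=-1)
        if np.any(cv <= 0):
            mean["gamma"] = np.diff(np.maximum.accumulate(
                np.maximum(cv, 1e-6), axis=-1), axis=-1, prepend=0.0)
        params = ParameterSet(**mean)

    # phase 2: production run with storage
    n_keep = (config.phase2_iters - config.phase2_burnin) // config.thin
    N, T = panel.n_clusters, panel.n_visits_max
    store = {f: np.empty((n_keep,) + _expected_shape(spec, f))
             for f in ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma")}
    pointwise = np.empty((n_keep, N, T))
    b_store = np.empty((n_keep, N, spec.r))
    Z_store = (np.empty((n_keep, N, T), dtype=np.int8)
               if config.store_latent else None)
    Zm_store = (np.empty((n_keep, N, T, spec.M), dtype=np.int8)
                if config.store_latent else None)

    d = 0
    for it in range(config.phase2_iters):
        # store before updating: (Z, Zm | params) plus the params themselves
        # form one coherent joint draw, and the forward constants computed
        # for FFBS are exactly this draw's pointwise log-likelihoods
        keep = (it >= config.phase2_burnin
                and (it - config.phase2_burnin) % config.thin == 0
                and d < n_keep)
        if keep:
            Z, Zm, log_c = _latent_scan(panel, spec, config, params, b, rng)
            if config.relabel:
                rl, fam_map, mem_maps, moved = relabel_draw(params, spec)
                logs["relabels"] += int(moved)
                Zs, Zms = fam_map[Z], np.empty_like(Zm)
                for m in range(spec.M):
                    Zms[:, :, m] = mem_maps[m][Zm[:, :, m]]
            else:
                rl, Zs, Zms = params.copy(), Z, Zm
            for f in store:
                store[f][d] = getattr(rl, f)
            pointwise[d] = log_c
            b_store[d] = b
            if config.store_latent:
                Z_store[d] = Zs
                Zm_store[d] = Zms
            d += 1
            # continue the chain from the (unrelabelled) sampled latents
            params, b = _finish_scan(panel, spec, config, params, b, Z, Zm,
                                     rng, frozen, logs)
        else:
            params, b = _one_scan(panel, spec, config, params, b, rng,
                                  frozen, logs)

    ll = pointwise.sum(axis=(1, 2))
    meta = {
        "seed": config.seed,
        "schedule": [config.phase1_iters, config.phase1_burnin,
                     config.phase2_iters, config.phase2_burnin, config.thin],
        "variance_param": config.variance_param,
        "mixture_form": config.mixture_form,
        "frozen": sorted(frozen),
        "n_visits": panel.n_visits.tolist(),
        "arms": panel.arm.tolist(),
        "arm_names": list(panel.arm_names),
        "member_names": list(panel.member_names),
        "outcome_names": list(panel.outcome_names),
        "relabel_count": logs["relabels"],
        "ridge_jitter_events": len(logs["jitter"]),
        "mh_rejections": len(logs["reject"]),
        "mean_loglik": float(ll.mean()),
    }
    return PosteriorDraws(spec=spec, pointwise=pointwise, b=b_store,
                          Z=Z_store, Zm=Zm_store, meta=meta, **store)


def _finish_scan(panel, spec, config, params, b, Z, Zm, rng, frozen, logs):
    """Parameter half of a scan when the latents were already drawn."""
    pi, P, Q = params.pi, params.P, params.Q
    tau, beta, gamma, Sigma = params.tau, params.beta, params.gamma, params.Sigma
    if "chain" not in frozen:
        pi, P = update_chain_probs(Z, panel.arm, panel.n_visits, spec,
                                   config.prior, rng)
    if "perception" not in frozen:
        Q = update_perception(Z, Zm, panel.arm, panel.visit_mask, spec,
                              config.prior, rng)
    state_var = np.cumsum(gamma, axis=-1)
    if "regression" not in frozen:
        tau, beta = update_regression(panel, Zm, b, state_var, rng,
                                      logs["jitter"])
    if "variance" not in frozen:
        gamma = update_variances(panel, Zm, tau, beta, b, gamma, config.prior,
                                 rng, config.variance_param, logs["reject"])
    new = ParameterSet(pi=pi, P=P, Q=Q, tau=tau, beta=beta, gamma=gamma,
                       Sigma=Sigma)
    if "b" not in frozen:
        b = update_random_effects(panel, Zm, new, rng)
    if "sigma" not in frozen:
        new.Sigma = update_sigma(b, config.prior, rng)
    return new, b


def _expected_shape(spec: ModelSpec, f: str):
    shapes = {
        "pi": (spec.S, spec.C),
        "P": (spec.S, spec.C, spec.C),
        "Q": ((spec.S, spec.M, spec.C, spec.Cm)
              if spec.perception_mode == "arm_specific"
              else (spec.M, spec.C, spec.Cm)),
        "tau": (spec.M, spec.J, spec.Cm),
        "beta": (spec.M, spec.J, spec.q),
        "gamma": (spec.M, spec.J, spec.Cm),
        "Sigma": (spec.r, spec.r),
    }
    return shapes[f]
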