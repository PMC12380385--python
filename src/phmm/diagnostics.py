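"""Model selection and goodness-of-fit: WAIC, posterior predictive checks,
forecast pseudo-residuals, and convergence summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr, ndtri

from .draws import PosteriorDraws
from .likelihood import _forward_all, marginal_loglik
from .panel import PanelData
from .simulate import simulate_family_chain, simulate_member_states, simulate_outcomes

__all__ = ["WaicReport", "PpcReport", "waic", "posterior_predictive_check",
           "pseudo_residuals", "convergence_summary"]


@dataclass
class WaicReport:
    """Widely applicable information criterion: waic = -2 (lppd - p_waic)."""

    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray
    flavor: str

    def __str__(self) -> str:
        return (f"WAIC ({self.flavor}): {self.waic:.1f}  "
                f"[lppd {self.lppd:.1f}, p_waic {self.p_waic:.1f}]")


def waic(draws: PosteriorDraws, flavor: str = "conditional",
         panel: PanelData | None = None, n_mc: int = 200,
         rng=None) -> WaicReport:
    """WAIC from stored pointwise log-likelihoods.

    ``conditional`` (default) uses the stored cluster-visit one-step-ahead
    log-likelihoods, conditional on each draw's random effects.
    ``marginal`` integrates the random effects out by Monte Carlo
    (pointwise unit: cluster) and requires the panel.
    """
    if draws.n_draws < 2:
        raise ValueError("WAIC needs at least 2 draws (p_waic undefined)")
    if flavor == "conditional":
        mask = draws._visit_mask()
        ll = draws.pointwise[:, mask]                       # (D, points)
    elif flavor == "marginal":
        if panel is None:
            raise ValueError("marginal WAIC requires the panel")
        rng = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        ll = np.stack([marginal_loglik(panel, p, n_mc=n_mc, rng=rng,
                                       mixture_form=draws.meta.get(
                                           "mixture_form", "member"))
                       for p in draws.iter_draws()])
    else:
        raise ValueError("flavor must be 'conditional' or 'marginal'")
    D = ll.shape[0]
    lppd_pt = logsumexp(ll, axis=0) - np.log(D)
    p_pt = ll.var(axis=0, ddof=1)
    lppd = float(lppd_pt.sum())
    p_waic = float(p_pt.sum())
    return WaicReport(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
                      pointwise_lppd=lppd_pt, pointwise_p=p_pt, flavor=flavor)


@dataclass
class PpcReport:
    """Posterior-predictive placement of observed summary statistics."""

    table: pd.DataFrame     # statistic, quantiles, observed, placement, extreme

    @property
    def extreme(self) -> pd.DataFrame:
        return self.table[self.table["extreme"]]


def _simulate_replicate(params, spec, panel: PanelData,
                        rng: np.random.Generator) -> np.ndarray:
    """One predictive panel with the observed design (arms, X, missingness)."""
    N, T = panel.n_clusters, panel.n_visits_max
    Z = np.empty((N, T), dtype=int)
    for i in range(N):
        Z[i] = simulate_family_chain(params.pi[panel.arm[i]],
                                     params.P[panel.arm[i]], T, rng)
    Zm = np.empty((N, T, spec.M), dtype=int)
    for s in range(spec.S):
        sel = panel.arm == s
        if sel.any():
            Zm[sel] = simulate_member_states(Z[sel], params.Q_for_arm(s), rng)
    b = rng.multivariate_normal(np.zeros(spec.r), params.Sigma, size=N,
                                method="cholesky")
    y = simulate_outcomes(Zm, b, panel.X, params, rng)
    return np.where(panel.observed, y, np.nan)


def posterior_predictive_check(draws: PosteriorDraws, panel: PanelData,
                               n_rep: int = 1000, rng=None,
                               extreme_band=(0.01, 0.99)) -> PpcReport:
    """Compare observed means/variances of each outcome series with their
    posterior-predictive distributions.

    Each replicate simulates a full panel (fresh latent states and random
    effects) from a randomly chosen retained draw, preserving the observed
    design and missingness pattern. Statistics: mean and variance of each
    member-outcome series. Placements outside ``extreme_band`` are flagged.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = draws.spec
    M, J = spec.M, spec.J
    members = draws.meta.get("member_names", [f"m{i+1}" for i in range(M)])
    outcomes = draws.meta.get("outcome_names", [f"y{j+1}" for j in range(J)])

    def stats_of(y):
        out = np.empty(2 * M * J)
        for m in range(M):
            for j in range(J):
                cells = y[:, :, m, j]
                obs = np.isfinite(cells)
                out[m * J + j] = cells[obs].mean()
                out[M * J + m * J + j] = cells[obs].var(ddof=1)
        return out

    observed = stats_of(panel.y)
    sims = np.empty((n_rep, 2 * M * J))
    which = rng.integers(0, draws.n_draws, size=n_rep)
    for rep in range(n_rep):
        y_rep = _simulate_replicate(draws.draw(which[rep]), spec, panel, rng)
        sims[rep] = stats_of(y_rep)

    qs = np.quantile(sims, [0.025, 0.25, 0.50, 0.75, 0.975], axis=0)
    placement = (sims < observed[None]).mean(axis=0)
    names = ([f"mean[{members[m]}:{outcomes[j]}]" for m in range(M)
              for j in range(J)] +
             [f"var[{members[m]}:{outcomes[j]}]" for m in range(M)
              for j in range(J)])
    table = pd.DataFrame({
        "statistic": names,
        "q2.5": qs[0], "q25": qs[1], "q50": qs[2], "q75": qs[3],
        "q97.5": qs[4],
        "observed": observed,
        "placement": placement,
    })
    table["extreme"] = ((placement < extreme_band[0])
                        | (placement > extreme_band[1]))
    return PpcReport(table=table)


def pseudo_residuals(draws: PosteriorDraws, panel: PanelData,
                     eps: float = 1e-10) -> np.ndarray:
    """Forecast (one-step-ahead) normal pseudo-residuals per outcome cell.

    For each draw, the predictive CDF of y_ijt^m given the cluster's data
    up to visit t-1 is a mixture over the predicted cluster state (the
    propagated filtered distribution; the initial distribution at t=1) and
    the member's perception row. CDF values are averaged over draws and
    mapped through the standard normal quantile function; a well-calibrated
    model yields approximately N(0, 1) residuals. Values are clipped to
    (eps, 1-eps).
    """
    spec = draws.spec
    N, T, M, J = panel.y.shape
    mixture_form = draws.meta.get("mixture_form", "member")
    u_acc = np.zeros((N, T, M, J))
    for d in range(draws.n_draws):
        p = draws.draw(d)
        b = draws.b[d]
        alpha, _ = _forward_all(panel, p, b, mixture_form)
        Ps = p.P[panel.arm]
        pred = np.empty((N, T, spec.C))
        pred[:, 0] = p.pi[panel.arm]
        for t in range(1, T):
            pred[:, t] = np.einsum("nc,nch->nh", alpha[:, t - 1], Ps)
        means = np.cumsum(p.tau, axis=-1)
        sds = np.sqrt(np.cumsum(p.gamma, axis=-1))
        for m in range(M):
            if p.Q.ndim == 4:
                w = np.einsum("ntc,nck->ntk", pred, p.Q[panel.arm, m])
            else:
                w = pred @ p.Q[m]                     # (N, T, Cm)
            for j in range(J):
                mu = (means[m, j][None, None]
                      + (panel.X @ p.beta[m, j])[..., None]
                      + b[:, None, m * J + j, None])
                zed = (panel.y[:, :, m, j, None] - mu) / sds[m, j][None, None]
                cdf = (w * ndtr(np.nan_to_num(zed))).sum(axis=-1)
                u_acc[:, :, m, j] += cdf
    u = u_acc / draws.n_draws
    u = np.clip(u, eps, 1.0 - eps)
    res = ndtri(u)
    return np.where(panel.observed, res, np.nan)


def convergence_summary(draws: PosteriorDraws, n_chains: int = 2,
                        ess_warn: float = 50.0, rhat_warn: float = 1.05
                        ) -> pd.DataFrame:
    """Rank-based split-chain diagnostics per scalar parameter.

    The single stored chain is split into ``n_chains`` segments; bulk
    effective sample size and split-Rhat are tabulated per parameter
    entry, with warnings for low ESS, high Rhat, or degenerate (constant)
    parameters.
    """
    import arviz as az

    if draws.n_draws < 4:
        raise ValueError("need at least 4 draws for split diagnostics")
    idata = draws.to_inference_data(n_chains=n_chains)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
        rhat = az.rhat(idata)
    for name in ess.data_vars:
        e = np.asarray(ess[name]).ravel()
        r = np.asarray(rhat[name]).ravel()
        arr = getattr(draws, name).reshape(draws.n_draws, -1)
        const = arr.std(axis=0) < 1e-12
        for idx in range(e.size):
            flag = ""
            if const[idx]:
                flag = "degenerate"
            elif e[idx] < ess_warn:
                flag = "low-ess"
            elif np.isfinite(r[idx]) and r[idx] > rhat_warn:
                flag = "high-rhat"
            rows.append({"param": name, "index": idx,
                         "ess": float(e[idx]),
                         "rhat": float(r[idx]) if np.isfinite(r[idx]) else np.nan,
                         "flag": flag})
    return pd.DataFrame(rows)
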