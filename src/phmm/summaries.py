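"""Posterior decoding and headline contrasts: arm differences in transition
and stationary probabilities, parent-vs-child perception differences, and
the ad hoc perception approximation available under the identity-perception
(mixed HMM) fit."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .draws import PosteriorDraws
from .panel import PanelData
from .params import ModelSpec, ParameterSet

__all__ = ["stationary_distribution", "arm_contrasts",
           "perception_contrasts", "decode_states",
           "mhmm_perception_approx", "align_draws_to_truth"]


def stationary_distribution(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of a row-stochastic transition matrix.

    The left eigenvector at eigenvalue 1, normalized to sum 1. For a
    reducible or periodic chain (non-unique unit eigenvalue) the limiting
    Cesaro average from a uniform start is returned with a warning.
    """
    P = np.asarray(P, dtype=float)
    C = P.shape[0]
    if P.shape != (C, C) or np.any(P < -tol) \
            or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be a square row-stochastic matrix")
    vals, vecs = np.linalg.eig(P.T)
    close = np.abs(vals - 1.0) < 1e-8
    if close.sum() == 1:
        v = np.real(vecs[:, np.nonzero(close)[0][0]])
        v = np.abs(v)
        return v / v.sum()
    warnings.warn("chain is reducible or periodic; returning limiting "
                  "average from a uniform start", RuntimeWarning)
    w = np.full(C, 1.0 / C)
    acc = np.zeros(C)
    K = 5000
    for _ in range(K):
        acc += w / K
        w = w @ P
    return acc / acc.sum()


def _interval_frame(samples: np.ndarray, names: list[str],
                    level: float = 0.95) -> pd.DataFrame:
    """Per-draw contrast samples (D, k) -> mean / CI / excludes-zero table."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [a, 1.0 - a], axis=0)
    mean = samples.mean(axis=0)
    return pd.DataFrame({
        "contrast": names, "mean": mean, "lower": lo, "upper": hi,
        "excludes_zero": (lo > 0) | (hi < 0),
    })


def arm_contrasts(draws: PosteriorDraws, level: float = 0.95,
                  arm_pair: tuple[int, int] | None = None) -> pd.DataFrame:
    """Second-minus-first-arm differences of transition and stationary
    probabilities, per posterior draw, summarized by mean and central CI.

    Draws with a reducible transition matrix are excluded from the
    stationary contrasts (count reported via the ``n_excluded`` attribute
    on the returned frame).
    """
    S = draws.spec.S
    if arm_pair is None:
        if S != 2:
            raise ValueError("specify arm_pair explicitly when S != 2")
        arm_pair = (0, 1)
    a0, a1 = arm_pair
    C = draws.spec.C
    arm_names = draws.meta.get("arm_names", [f"arm{s+1}" for s in range(S)])

    trans = draws.P[:, a1] - draws.P[:, a0]          # (D, C, C)
    trans_samples = trans.reshape(draws.n_draws, -1)
    trans_names = [f"P[{k+1}->{j+1}] {arm_names[a1]}-{arm_names[a0]}"
                   for k in range(C) for j in range(C)]

    stat_rows = []
    n_excluded = 0
    with warnings.catch_warnings():
        warnings.simplefilter("error", RuntimeWarning)
        for d in range(draws.n_draws):
            try:
                s1 = stationary_distribution(draws.P[d, a1])
                s0 = stationary_distribution(draws.P[d, a0])
                stat_rows.append(s1 - s0)
            except RuntimeWarning:
                n_excluded += 1
    if not stat_rows:
        raise RuntimeError("all draws had degenerate transition matrices")
    stat_samples = np.asarray(stat_rows)
    stat_names = [f"stationary[{j+1}] {arm_names[a1]}-{arm_names[a0]}"
                  for j in range(C)]

    out = pd.concat([_interval_frame(trans_samples, trans_names, level),
                     _interval_frame(stat_samples, stat_names, level)],
                    ignore_index=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def perception_contrasts(draws: PosteriorDraws, level: float = 0.95,
                         members: tuple[int, int] | None = None
                         ) -> pd.DataFrame:
    """Parent-minus-child (last-minus-first member by default) differences
    of perception probabilities, per posterior draw."""
    spec = draws.spec
    if spec.M < 2:
        raise ValueError("perception contrasts need at least two members")
    names = draws.meta.get("member_names", [f"m{i+1}" for i in range(spec.M)])
    if members is None:
        lowered = [n.lower() for n in names]
        if "parent" in lowered and "child" in lowered:
            members = (lowered.index("child"), lowered.index("parent"))
        else:
            members = (0, spec.M - 1)
    m0, m1 = members
    # arm-specific draws are (D, S, M, C, Cm): average over arms per draw
    Q = draws.Q.mean(axis=1) if draws.Q.ndim == 5 else draws.Q
    diff = (Q[:, m1] - Q[:, m0]).reshape(draws.n_draws, -1)
    labels = [f"Q[{k+1}->{j+1}] {names[m1]}-{names[m0]}"
              for k in range(spec.C) for j in range(spec.Cm)]
    out = _interval_frame(diff, labels, level)
    if spec.perception_mode == "identity":
        out.attrs["note"] = ("identity perception: all contrasts are "
                             "structurally zero")
    return out


def decode_states(draws: PosteriorDraws
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Modal (most frequently sampled) states per cluster-visit, 1-based.

    Ties break to the lowest state label. Returns (Z_hat (N, T),
    Zm_hat (N, T, M) or None if member paths were not stored).
    """
    if draws.Z is None:
        raise ValueError("latent paths were not stored")

    def modal(paths, K):
        D = paths.shape[0]
        flat = paths.reshape(D, -1)
        counts = np.zeros((K,) + flat.shape[1:])
        for k in range(K):
            counts[k] = (flat == k).sum(axis=0)
        return counts.argmax(axis=0).reshape(paths.shape[1:])

    Z_hat = modal(draws.Z, draws.spec.C) + 1
    Zm_hat = (modal(draws.Zm, draws.spec.Cm) + 1
              if draws.Zm is not None else None)
    return Z_hat, Zm_hat


# ---------------------------------------------------------------------------
# simulation-study alignment of fitted to generating states


def align_draws_to_truth(draws: PosteriorDraws,
                         true_params: ParameterSet) -> PosteriorDraws:
    """Relabel stored draws so fitted states correspond to generating states.

    Latent labels are arbitrary; for recovery studies fitted member states
    are matched to the generating states by Hungarian assignment on the
    posterior-mean emission state-mean vectors (each member's J outcomes),
    and cluster states are then matched through the perception matrices
    (identity mode reuses the member assignment). One permutation, computed
    from the posterior means, is applied to every draw.
    """
    spec = draws.spec
    M, J, C, Cm = spec.M, spec.J, spec.C, spec.Cm
    mean_tau = draws.tau.mean(axis=0)
    if spec.perception_mode == "identity":
        # one shared state space: match on the stacked outcome mean
        # vectors of all members
        fit_means = np.cumsum(mean_tau, axis=-1).reshape(M * J, Cm).T
        true_means = np.cumsum(true_params.tau, axis=-1).reshape(M * J, Cm).T
        mapping = _align_to_reference(true_means, fit_means)
        shared = np.empty(Cm, dtype=int)
        shared[mapping] = np.arange(Cm)
        member_perms = [shared] * M
    else:
        member_perms = []
        for m in range(M):
            fit_means = np.cumsum(mean_tau[m], axis=-1).T       # (Cm, J)
            true_means = np.cumsum(true_params.tau[m], axis=-1).T
            mapping = _align_to_reference(true_means, fit_means)
            perm = np.empty(Cm, dtype=int)       # perm[new] = old
            perm[mapping] = np.arange(Cm)
            member_perms.append(perm)

    if spec.perception_mode == "identity":
        fam_perm = member_perms[0]
    else:
        Qm = draws.Q.mean(axis=0)
        if Qm.ndim == 4:                      # arm-specific: pool arms
            Qm = Qm.mean(axis=0)
        score = np.zeros((C, C))              # score[old_row, new_label]
        for m in range(M):
            score += Qm[m][:, member_perms[m]]
        rows, cols = linear_sum_assignment(-score)
        fam_perm = np.empty(C, dtype=int)
        fam_perm[cols] = rows                 # fam_perm[new] = old

    out = {}
    out["pi"] = draws.pi[:, :, fam_perm]
    out["P"] = draws.P[:, :, fam_perm][:, :, :, fam_perm]
    Q = draws.Q
    if Q.ndim == 5:
        Q = Q[:, :, :, fam_perm]
        Qn = np.empty_like(Q)
        for m in range(M):
            Qn[:, :, m] = Q[:, :, m][:, :, :, member_perms[m]]
    else:
        Q = Q[:, :, fam_perm]
        Qn = np.empty_like(Q)
        for m in range(M):
            Qn[:, m] = Q[:, m][:, :, member_perms[m]]
    out["Q"] = Qn
    tau = np.empty_like(draws.tau)
    gamma = np.empty_like(draws.gamma)
    for m in range(M):
        means = np.cumsum(draws.tau[:, m], axis=-1)[:, :, member_perms[m]]
        variances = np.cumsum(draws.gamma[:, m], axis=-1)[:, :, member_perms[m]]
        tau[:, m] = np.diff(means, axis=-1, prepend=0.0)
        gamma[:, m] = np.diff(variances, axis=-1, prepend=0.0)
    out["tau"], out["gamma"] = tau, gamma

    fam_map = np.empty(C, dtype=int)
    fam_map[fam_perm] = np.arange(C)
    Z = fam_map[draws.Z] if draws.Z is not None else None
    Zm = None
    if draws.Zm is not None:
        Zm = np.empty_like(draws.Zm)
        for m in range(M):
            mem_map = np.empty(Cm, dtype=int)
            mem_map[member_perms[m]] = np.arange(Cm)
            Zm[..., m] = mem_map[draws.Zm[..., m]]
    return PosteriorDraws(spec=spec, beta=draws.beta, Sigma=draws.Sigma,
                          pointwise=draws.pointwise, b=draws.b, Z=Z, Zm=Zm,
                          meta=dict(draws.meta, truth_aligned=True), **out)


# ---------------------------------------------------------------------------
# perception approximation from identity-perception (mixed HMM) fits


def _align_to_reference(ref_means: np.ndarray, fit_means: np.ndarray
                        ) -> np.ndarray:
    """map[fit_state] = reference_state minimizing total mean distance."""
    C = ref_means.shape[0]
    cost = ((fit_means[:, None, :] - ref_means[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(C, dtype=int)
    mapping[rows] = cols
    return mapping


def mhmm_perception_approx(panel: PanelData, n_states: int,
                           config, mode: str = "unconstrained",
                           seed: int | None = None) -> dict:
    """Approximate perception matrices from identity-perception fits.

    Fits a mixed HMM (identity perception) to the full panel and to each
    member's outcomes alone, decodes modal states from each fit, aligns
    the member-fit state labels to the full-panel fit by matching state
    mean vectors on the member's own outcomes, and row-normalizes the
    cross-tabulation of full-panel versus member decoded states.

    ``constrained`` freezes the member-fit emission parameters (state
    means, covariate effects, state variances) at the full-panel fit's
    posterior means; ``unconstrained`` estimates everything per fit.

    Returns ``{"Q": (M, C, C) array, "family_results": ..., "member_results":
    [...], "alignment": [...]}``.
    """
    from .model import PerceptionHMM

    if mode not in ("unconstrained", "constrained"):
        raise ValueError("mode must be 'unconstrained' or 'constrained'")
    rng = np.random.default_rng(seed)
    M, J = panel.n_members, panel.n_outcomes
    C = n_states

    fam_model = PerceptionHMM(panel, n_states=C, perception="identity")
    fam_res = fam_model.fit(config=config,
                            seed=int(rng.integers(2 ** 31 - 1)))
    fam_mean = fam_res.posterior_mean()
    Z_fam, _ = fam_res.decode_states()

    Q = np.zeros((M, C, C))
    member_results = []
    alignments = []
    vm = panel.visit_mask
    for m in range(M):
        sub = panel.member_subset([m])
        model_m = PerceptionHMM(sub, n_states=C, perception="identity")
        init = None
        frozen = frozenset()
        if mode == "constrained":
            init = ParameterSet(
                pi=fam_mean.pi.copy(), P=fam_mean.P.copy(),
                Q=np.broadcast_to(np.eye(C), (1, C, C)).copy(),
                tau=fam_mean.tau[m:m + 1].copy(),
                beta=fam_mean.beta[m:m + 1].copy(),
                gamma=fam_mean.gamma[m:m + 1].copy(),
                Sigma=fam_mean.Sigma[m * J:(m + 1) * J,
                                     m * J:(m + 1) * J].copy())
            frozen = frozenset({"regression", "variance"})
        res_m = model_m.fit(config=config,
                            seed=int(rng.integers(2 ** 31 - 1)),
                            init_params=init, frozen=frozen)
        Z_m, _ = res_m.decode_states()

        mean_m = res_m.posterior_mean()
        fit_means = np.cumsum(mean_m.tau[0], axis=-1).T       # (C, J)
        ref_means = np.cumsum(fam_mean.tau[m], axis=-1).T
        mapping = _align_to_reference(ref_means, fit_means)
        Z_m_aligned = mapping[Z_m - 1] + 1

        tab = np.zeros((C, C))
        np.add.at(tab, (Z_fam[vm] - 1, Z_m_aligned[vm] - 1), 1.0)
        row_sums = tab.sum(axis=1, keepdims=True)
        Q[m] = np.where(row_sums > 0, tab / np.maximum(row_sums, 1.0),
                        1.0 / C)
        member_results.append(res_m)
        alignments.append(mapping)

    return {"Q": Q, "family_results": fam_res,
            "member_results": member_results, "alignment": alignments,
            "mode": mode}
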