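"""Model and Results classes tying the pipeline together.

``PerceptionHMM`` is constructed from a panel (or a long-format
DataFrame), configured with the number of latent states and the perception
mode, and fitted by the two-phase Gibbs sampler; ``fit`` returns a
``PerceptionHMMResults`` carrying the posterior draws and exposing
estimates, credible intervals, model selection, goodness-of-fit
diagnostics, contrasts, and decoding.

Example
-------
>>> from phmm import PerceptionHMM, scenario_preset, simulate_dataset
>>> panel, truth = simulate_dataset(scenario_preset(2), seed=1)
>>> model = PerceptionHMM(panel, n_states=3, perception="shared")
>>> res = model.fit(phase1_iters=200, phase1_burnin=100,
...                 phase2_iters=800, phase2_burnin=400, thin=1, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diagnostics as _diag
from . import summaries as _summ
from .draws import PosteriorDraws, read_draws, write_draws
from .likelihood import marginal_loglik
from .panel import PanelData, panel_from_dataframe
from .params import ModelSpec, ParameterSet, PriorConfig
from .sampler import SamplerConfig, run_sampler

__all__ = ["PerceptionHMM", "PerceptionHMMResults"]

_MODE_ALIASES = {"mhmm": "identity", "phmm": "shared", "phmme": "arm_specific",
                 "identity": "identity", "shared": "shared",
                 "arm_specific": "arm_specific"}


class PerceptionHMM:
    """Perception-augmented hidden Markov model for multi-member panels.

    Parameters
    ----------
    panel : PanelData
        Long-format panel (see :func:`phmm.read_panel`).
    n_states : int
        Number of cluster-level latent states.
    perception : str
        ``"identity"``/``"mhmm"`` (member states equal cluster states),
        ``"shared"``/``"phmm"`` (member-specific perception), or
        ``"arm_specific"``/``"phmme"``.
    n_member_states : int, optional
        Member-level state count; defaults to ``n_states``.
    share_initial : bool
        Tie the initial distribution across arms (default True).
    prior : PriorConfig, optional
    """

    def __init__(self, panel: PanelData, n_states: int = 3,
                 perception: str = "shared",
                 n_member_states: int | None = None,
                 share_initial: bool = True,
                 prior: PriorConfig | None = None):
        try:
            mode = _MODE_ALIASES[perception.lower()]
        except KeyError:
            raise ValueError(f"unknown perception mode {perception!r}") from None
        self.panel = panel
        self.prior = prior or PriorConfig()
        self.spec = ModelSpec(
            n_states=n_states, n_members=panel.n_members,
            n_outcomes=panel.n_outcomes, n_arms=panel.n_arms,
            n_covariates=panel.n_covariates, perception_mode=mode,
            n_member_states=n_member_states, share_initial=share_initial)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates=None,
                       log_outcomes=None, **kwargs) -> "PerceptionHMM":
        """Build the model from a long-format DataFrame with columns
        cluster_id, visit, arm, member, outcome, value (+ covariates)."""
        panel = panel_from_dataframe(df, covariates=covariates,
                                     log_outcomes=log_outcomes)
        return cls(panel, **kwargs)

    def fit(self, config: SamplerConfig | None = None,
            seed: int | None = None, init_params: ParameterSet | None = None,
            init_b=None, frozen: frozenset = frozenset(),
            **schedule) -> "PerceptionHMMResults":
        """Run the two-phase Gibbs sampler.

        ``schedule`` keywords (phase1_iters, phase2_burnin, thin, ...)
        override fields of ``config``; ``seed`` overrides the config seed.
        """
        config = config or SamplerConfig(prior=self.prior)
        if schedule or seed is not None:
            over = dict(schedule)
            if seed is not None:
                over["seed"] = seed
            config = config.reduced(**over)
        draws = run_sampler(self.panel, self.spec, config,
                            init_params=init_params, init_b=init_b,
                            frozen=frozen)
        return PerceptionHMMResults(self, draws)

    def loglike(self, params: ParameterSet, b=None, n_mc: int = 0,
                rng=None) -> float:
        """Total log-likelihood at ``params`` (conditional on ``b``, or
        integrating random effects by MC with ``n_mc`` draws)."""
        return float(marginal_loglik(self.panel, params, b=b, n_mc=n_mc,
                                     rng=rng).sum())


class PerceptionHMMResults:
    """Posterior summary object returned by :meth:`PerceptionHMM.fit`."""

    def __init__(self, model: PerceptionHMM, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def spec(self) -> ModelSpec:
        return self.draws.spec

    @property
    def panel(self) -> PanelData:
        return self.model.panel

    # -- estimates --------------------------------------------------------
    def posterior_mean(self) -> ParameterSet:
        return self.draws.posterior_mean()

    def credible_interval(self, name: str, level: float = 0.95):
        return self.draws.credible_interval(name, level)

    # -- diagnostics ------------------------------------------------------
    def waic(self, flavor: str = "conditional", **kw) -> _diag.WaicReport:
        if flavor == "marginal":
            kw.setdefault("panel", self.panel)
        return _diag.waic(self.draws, flavor=flavor, **kw)

    def posterior_predictive_check(self, n_rep: int = 1000,
                                   rng=None) -> _diag.PpcReport:
        return _diag.posterior_predictive_check(self.draws, self.panel,
                                                n_rep=n_rep, rng=rng)

    def pseudo_residuals(self) -> np.ndarray:
        return _diag.pseudo_residuals(self.draws, self.panel)

    def convergence_summary(self, **kw) -> pd.DataFrame:
        return _diag.convergence_summary(self.draws, **kw)

    # -- contrasts and decoding ------------------------------------------
    def arm_contrasts(self, level: float = 0.95, **kw) -> pd.DataFrame:
        return _summ.arm_contrasts(self.draws, level=level, **kw)

    def perception_contrasts(self, level: float = 0.95, **kw) -> pd.DataFrame:
        return _summ.perception_contrasts(self.draws, level=level, **kw)

    def decode_states(self):
        return _summ.decode_states(self.draws)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        write_draws(self.draws, path)

    @classmethod
    def from_saved(cls, path, panel: PanelData) -> "PerceptionHMMResults":
        draws = read_draws(path)
        model = PerceptionHMM(
            panel, n_states=draws.spec.C,
            perception=draws.spec.perception_mode,
            n_member_states=draws.spec.Cm,
            share_initial=draws.spec.share_initial)
        return cls(model, draws)

    # -- reporting --------------------------------------------------------
    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean and central CI for the interpretable parameters."""
        spec = self.spec
        meta = self.draws.meta
        arms = meta.get("arm_names", [f"arm{s+1}" for s in range(spec.S)])
        members = meta.get("member_names", [f"m{i+1}" for i in range(spec.M)])
        outcomes = meta.get("outcome_names", [f"y{j+1}" for j in range(spec.J)])
        a = (1 - level) / 2
        rows = []

        def add(name, samples):
            lo, hi = np.quantile(samples, [a, 1 - a])
            rows.append({"parameter": name, "mean": samples.mean(),
                         "lower": lo, "upper": hi})

        for j in range(spec.C):
            add(f"pi[{j+1}]", self.draws.pi[:, 0, j])
        for s in range(spec.S):
            for k in range(spec.C):
                for j in range(spec.C):
                    add(f"P[{k+1}->{j+1}|{arms[s]}]", self.draws.P[:, s, k, j])
        if spec.perception_mode != "identity":
            Q = (self.draws.Q.mean(axis=1) if self.draws.Q.ndim == 5
                 else self.draws.Q)
            for m in range(spec.M):
                for k in range(spec.C):
                    for j in range(spec.Cm):
                        add(f"Q[{k+1}->{j+1}|{members[m]}]", Q[:, m, k, j])
        means = np.cumsum(self.draws.tau, axis=-1)
        for m in range(spec.M):
            for j in range(spec.J):
                for k in range(spec.Cm):
                    add(f"mean[{members[m]}:{outcomes[j]}|state {k+1}]",
                        means[:, m, j, k])
        return pd.DataFrame(rows)

    def summary(self, level: float = 0.95) -> str:
        spec = self.spec
        lines = [
            "Perception-augmented HMM results",
            "=" * 64,
            f"perception mode: {spec.perception_mode}"
            f"   cluster states: {spec.C}   member states: {spec.Cm}",
            f"clusters: {self.panel.n_clusters}   max visits: "
            f"{self.panel.n_visits_max}   members: {spec.M}   "
            f"outcomes/member: {spec.J}",
            f"retained draws: {self.draws.n_draws}   "
            f"mean cond. log-lik: {self.draws.meta.get('mean_loglik', np.nan):.1f}",
            f"relabelled draws: {self.draws.meta.get('relabel_count', 0)}",
            "-" * 64,
        ]
        frame = self.summary_frame(level)
        lines.append(frame.to_string(
            index=False, float_format=lambda v: f"{v:8.3f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<PerceptionHMMResults: {self.spec.perception_mode}, "
                f"C={self.spec.C}, draws={self.draws.n_draws}>")
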