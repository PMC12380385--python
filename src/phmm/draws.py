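"""Posterior draw storage, persistence, and arviz conversion."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .params import ModelSpec, ParameterSet, validate

__all__ = ["PosteriorDraws", "write_draws", "read_draws"]

_FORMAT_VERSION = 1

_PARAM_FIELDS = ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma")


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws with chain metadata.

    Parameter arrays carry a leading draw axis. ``pointwise`` holds the
    per-draw, per-cluster-visit one-step-ahead log-likelihood contributions
    (conditional on that draw's random effects) used by WAIC. ``Z``/``Zm``
    are stored 0-based with padding visits present; consult
    ``meta['n_visits']`` for real follow-up lengths.
    """

    spec: ModelSpec
    pi: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    Sigma: np.ndarray
    pointwise: np.ndarray                  # (D, N, T)
    b: np.ndarray | None = None            # (D, N, r)
    Z: np.ndarray | None = None            # (D, N, T) int
    Zm: np.ndarray | None = None           # (D, N, T, M) int
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    def draw(self, d: int) -> ParameterSet:
        return ParameterSet(*(getattr(self, f)[d] for f in _PARAM_FIELDS))

    def iter_draws(self):
        for d in range(self.n_draws):
            yield self.draw(d)

    def posterior_mean(self) -> ParameterSet:
        """Posterior-mean parameter set (simplex rows renormalized)."""
        out = {f: getattr(self, f).mean(axis=0) for f in _PARAM_FIELDS}
        for f in ("pi", "P", "Q"):
            out[f] = out[f] / out[f].sum(axis=-1, keepdims=True)
        return ParameterSet(**out)

    def credible_interval(self, name: str, level: float = 0.95):
        """Central credible interval for one parameter block."""
        arr = getattr(self, name)
        a = (1.0 - level) / 2.0
        return np.quantile(arr, [a, 1.0 - a], axis=0)

    def validate_all(self) -> list[str]:
        problems = []
        for d in range(self.n_draws):
            v = validate(self.draw(d), self.spec)
            if v:
                problems.append(f"draw {d}: {v}")
        return problems

    def loglik_per_draw(self) -> np.ndarray:
        """(D,) total conditional log-likelihood of each draw."""
        T_mask = self._visit_mask()
        return (self.pointwise * T_mask[None]).sum(axis=(1, 2))

    def _visit_mask(self) -> np.ndarray:
        N, T = self.pointwise.shape[1:]
        n_visits = np.asarray(self.meta.get("n_visits", [T] * N))
        return np.arange(T)[None, :] < n_visits[:, None]

    def to_inference_data(self, n_chains: int = 2):
        """arviz InferenceData; the single chain is split into segments."""
        import arviz as az

        D = self.n_draws
        per = D // n_chains
        if per < 2:
            raise ValueError("too few draws to split into chains")
        data = {}
        for f in _PARAM_FIELDS:
            arr = getattr(self, f)[: per * n_chains]
            data[f] = arr.reshape((n_chains, per) + arr.shape[1:])
        return az.from_dict(posterior=data)


def write_draws(draws: PosteriorDraws, path) -> None:
    """Persist draws to a single .npz archive with embedded JSON metadata."""
    if draws.n_draws == 0:
        raise ValueError("refusing to write empty draws")
    spec = draws.spec
    header = {
        "format_version": _FORMAT_VERSION,
        "spec": {
            "n_states": spec.n_states, "n_members": spec.n_members,
            "n_outcomes": spec.n_outcomes, "n_arms": spec.n_arms,
            "n_covariates": spec.n_covariates,
            "perception_mode": spec.perception_mode,
            "n_member_states": spec.n_member_states,
            "share_initial": spec.share_initial,
        },
        "meta": draws.meta,
    }
    arrays = {f: getattr(draws, f) for f in _PARAM_FIELDS}
    arrays["pointwise"] = draws.pointwise
    for opt in ("b", "Z", "Zm"):
        val = getattr(draws, opt)
        if val is not None:
            arrays[opt] = val
    arrays["_header"] = np.frombuffer(
        json.dumps(header, default=_json_default).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_draws(path) -> PosteriorDraws:
    with np.load(path) as z:
        if "_header" not in z:
            raise ValueError("not a draws archive (missing header)")
        header = json.loads(bytes(z["_header"]).decode())
        if header.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"draws format version {header.get('format_version')} "
                f"not supported (expected {_FORMAT_VERSION})")
        spec = ModelSpec(**header["spec"])
        kw = {f: z[f] for f in _PARAM_FIELDS}
        kw["pointwise"] = z["pointwise"]
        for opt in ("b", "Z", "Zm"):
            if opt in z.files:
                kw[opt] = z[opt]
        return PosteriorDraws(spec=spec, meta=header["meta"], **kw)
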