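"""Model specification and parameter containers.

The model has three layers: a cluster-level Markov chain with ``C`` states
(arm-specific transition matrices), a member-level perception layer in which
each of ``M`` cluster members maps the cluster state to its own latent state
through a row-stochastic perception matrix ``Q``, and Gaussian emissions for
each member's outcomes given the member state, covariates, and a
cluster-level random effect.

State means and variances use a cumulative-increment parameterization: with
``u_k`` the vector whose first ``k`` entries are one, the state-``k`` mean of
outcome ``j`` of member ``m`` is ``u_k' tau[m, j]`` (the prefix sum of the
first ``k`` increments) and the state-``k`` variance is ``u_k' gamma[m, j]``.
Mean increments may be negative (state means need not be monotone); every
cumulative variance must stay strictly positive.

States are labelled 1..C in all public data (CSV files, decoded paths);
array axes inside this package are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "PriorConfig",
    "validate",
    "state_moments",
    "to_increments",
]

_SIMPLEX_TOL = 1e-10

PERCEPTION_MODES = ("identity", "shared", "arm_specific")


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and structural options of a perception-augmented HMM.

    Parameters
    ----------
    n_states : int
        Number of cluster-level latent states ``C``.
    n_members : int
        Members per cluster ``M`` (2 for a parent-child dyad).
    n_outcomes : int
        Outcomes per member ``J`` (common across members).
    n_arms : int
        Number of treatment arms ``S``.
    n_covariates : int
        Number of emission covariates ``q``.
    perception_mode : {"identity", "shared", "arm_specific"}
        ``identity`` is the mixed HMM (member states equal cluster states),
        ``shared`` uses one perception matrix per member, ``arm_specific``
        one per member and arm.
    n_member_states : int, optional
        Member-level state count ``C_m`` (common across members); defaults
        to ``n_states`` and must equal it in identity mode.
    share_initial : bool
        Tie the initial-state distribution across arms (default). The
        stored ``pi`` keeps its ``S x C`` shape with identical rows.
    """

    n_states: int
    n_members: int = 2
    n_outcomes: int = 2
    n_arms: int = 2
    n_covariates: int = 0
    perception_mode: str = "shared"
    n_member_states: int | None = None
    share_initial: bool = True

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_members < 1 or self.n_outcomes < 1 or self.n_arms < 1:
            raise ValueError("n_members, n_outcomes, n_arms must be >= 1")
        if self.perception_mode not in PERCEPTION_MODES:
            raise ValueError(f"perception_mode must be one of {PERCEPTION_MODES}")
        if self.n_member_states is None:
            object.__setattr__(self, "n_member_states", self.n_states)
        if self.perception_mode == "identity" and self.n_member_states != self.n_states:
            raise ValueError("identity perception requires n_member_states == n_states")

    @property
    def C(self) -> int:
        return self.n_states

    @property
    def Cm(self) -> int:
        return int(self.n_member_states)

    @property
    def M(self) -> int:
        return self.n_members

    @property
    def J(self) -> int:
        return self.n_outcomes

    @property
    def S(self) -> int:
        return self.n_arms

    @property
    def q(self) -> int:
        return self.n_covariates

    @property
    def r(self) -> int:
        """Total outcome count (random-effect dimension)."""
        return self.n_members * self.n_outcomes

    def outcome_index(self, member: int, outcome: int) -> int:
        """Flat index of outcome ``outcome`` of member ``member`` (0-based)."""
        return member * self.n_outcomes + outcome


@dataclass
class ParameterSet:
    """One full parameter vector Theta.

    Attributes
    ----------
    pi : (S, C) array
        Initial-state probabilities per arm (rows identical when the
        initial distribution is shared across arms).
    P : (S, C, C) array
        Arm-specific transition matrices, rows are simplexes.
    Q : (M, C, Cm) or (S, M, C, Cm) array
        Perception matrices; the 4-d form is used in arm-specific mode.
    tau : (M, J, Cm) array
        Mean increments; prefix sums give state means.
    beta : (M, J, q) array
        Covariate coefficients.
    gamma : (M, J, Cm) array
        Variance increments; prefix sums give state variances.
    Sigma : (r, r) array
        Random-effect covariance.
    """

    pi: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def copy(self) -> "ParameterSet":
        return ParameterSet(*(getattr(self, f).copy() for f in
                              ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma")))

    def Q_for_arm(self, arm: int) -> np.ndarray:
        """Perception matrices (M, C, Cm) applying in arm ``arm`` (0-based)."""
        return self.Q[arm] if self.Q.ndim == 4 else self.Q

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {f: getattr(self, f).tolist() for f in
                ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma")}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**{f: np.asarray(d[f], dtype=float) for f in
                      ("pi", "P", "Q", "tau", "beta", "gamma", "Sigma")})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PriorConfig:
    """Conjugate prior settings.

    Dirichlet(concentration) rows for pi, P and Q; inverse-Gamma(shape,
    scale) on variance increments; flat prior on (tau, beta);
    inverse-Wishart(df, scale) on Sigma with df defaulting to r + 1 and
    scale to the identity.
    """

    dirichlet: float = 1.0
    ig_shape: float = 0.001
    ig_scale: float = 0.0002
    iw_df: float | None = None
    iw_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dirichlet <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")

    def iw_df_for(self, r: int) -> float:
        df = self.iw_df if self.iw_df is not None else r + 1
        if df < r:
            raise ValueError("inverse-Wishart df must be >= r")
        return float(df)

    def iw_scale_for(self, r: int) -> np.ndarray:
        if self.iw_scale is None:
            return np.eye(r)
        S = np.asarray(self.iw_scale, dtype=float)
        _check_spd(S)
        return S


def _check_spd(S: np.ndarray) -> None:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    np.linalg.cholesky(S)


def _expected_shapes(spec: ModelSpec) -> dict:
    qshape = ((spec.S, spec.M, spec.C, spec.Cm)
              if spec.perception_mode == "arm_specific"
              else (spec.M, spec.C, spec.Cm))
    return {
        "pi": (spec.S, spec.C),
        "P": (spec.S, spec.C, spec.C),
        "Q": qshape,
        "tau": (spec.M, spec.J, spec.Cm),
        "beta": (spec.M, spec.J, spec.q),
        "gamma": (spec.M, spec.J, spec.Cm),
        "Sigma": (spec.r, spec.r),
    }


def validate(params: ParameterSet, spec: ModelSpec) -> list[str]:
    """Check a parameter set against its model specification.

    Returns an empty list when valid; otherwise a list of human-readable
    violation messages, each naming the offending component. Shape
    mismatches raise ``ValueError`` (a structural error, not an invariant
    violation).
    """
    for name, shape in _expected_shapes(spec).items():
        got = getattr(params, name).shape
        if got != shape:
            raise ValueError(f"{name}: expected shape {shape}, got {got}")

    violations: list[str] = []

    def check_rows(arr: np.ndarray, label: str) -> None:
        rows = arr.reshape(-1, arr.shape[-1])
        for idx, row in enumerate(rows):
            if np.any(row < -_SIMPLEX_TOL):
                violations.append(f"{label} row {idx}: negative entry {row.min():.3g}")
            s = row.sum()
            if abs(s - 1.0) > _SIMPLEX_TOL:
                violations.append(f"{label} row {idx}: row sum {s:.6g}")

    check_rows(params.pi, "pi")
    check_rows(params.P, "P")
    check_rows(params.Q, "Q")

    if spec.perception_mode == "identity":
        eye = np.eye(spec.C)
        Qs = params.Q if params.Q.ndim == 4 else params.Q[None]
        for m in range(spec.M):
            if not np.allclose(Qs[..., m, :, :], eye, atol=_SIMPLEX_TOL):
                violations.append(f"Q member {m}: not identity under identity mode")

    if spec.share_initial and not np.allclose(
            params.pi, params.pi[:1], atol=_SIMPLEX_TOL):
        violations.append("pi: arm rows differ under shared initial distribution")

    cumvar = np.cumsum(params.gamma, axis=-1)
    for m in range(spec.M):
        for j in range(spec.J):
            bad = np.nonzero(cumvar[m, j] <= 0)[0]
            for k in bad:
                violations.append(
                    f"gamma member {m} outcome {j}: state-{k + 1} variance "
                    f"{cumvar[m, j, k]:.3g} <= 0")

    try:
        _check_spd(params.Sigma)
    except (ValueError, np.linalg.LinAlgError) as exc:
        violations.append(f"Sigma: not symmetric positive definite ({exc})")

    return violations


def state_moments(params: ParameterSet, member: int, outcome: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-state means and variances of one outcome series.

    The state-``k`` mean is the prefix sum of the first ``k`` mean
    increments, and likewise for variances; covariate and random-effect
    contributions are excluded. ``member`` and ``outcome`` are 0-based.
    """
    means = np.cumsum(params.tau[member, outcome])
    variances = np.cumsum(params.gamma[member, outcome])
    return means, variances


def to_increments(means: np.ndarray, variances: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`state_moments`: first differences of the moments.

    Non-increasing variance sequences are allowed and produce negative
    variance increments (legal under the direct-variance sampler, rejected
    under the increments prior); all variances must be strictly positive.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape or means.ndim != 1:
        raise ValueError("means and variances must be 1-d with equal length")
    if np.any(variances <= 0):
        raise ValueError("state variances must be strictly positive")
    tau = np.diff(means, prepend=0.0)
    gamma = np.diff(variances, prepend=0.0)
    return tau, gamma


def identity_perception(spec: ModelSpec) -> np.ndarray:
    """Identity perception matrices with the shape the spec dictates."""
    eye = np.broadcast_to(np.eye(spec.C), (spec.M, spec.C, spec.C)).copy()
    if spec.perception_mode == "arm_specific":
        return np.broadcast_to(eye, (spec.S, spec.M, spec.C, spec.C)).copy()
    return eye


def replace_spec(spec: ModelSpec, **kw) -> ModelSpec:
    return replace(spec, **kw)
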