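"""Canonical state labelling to guard against label switching.

Latent-state labels are arbitrary; the likelihood is invariant under a
simultaneous permutation of (pi, P rows/columns, Q rows) and, separately
per member, of (Q columns, state moments). Each retained draw is mapped to
a canonical labelling:

1. the reference member's states (the last member, the parent in a dyad)
   are ordered by decreasing state mean of its first outcome — the
   task-involvement ordering Discordant > Harmonious > Indifferent, which
   is strictly monotone for the parent;
2. cluster states are aligned to the reference member's states through the
   dominant diagonal of that member's perception matrix (Hungarian
   assignment);
3. every other member's states are aligned to the cluster states through
   the dominant diagonal of its own perception matrix.

Under identity perception the single ordering from step 1 applies to all
state-indexed blocks directly.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .params import ModelSpec, ParameterSet

__all__ = ["relabel_draw"]


def _permute_moments(tau_mj, gamma_mj, perm):
    means = np.cumsum(tau_mj)[perm]
    variances = np.cumsum(gamma_mj)[perm]
    return (np.diff(means, prepend=0.0), np.diff(variances, prepend=0.0))


def _apply_member_perm(p: ParameterSet, m: int, perm: np.ndarray) -> None:
    for j in range(p.tau.shape[1]):
        p.tau[m, j], p.gamma[m, j] = _permute_moments(p.tau[m, j],
                                                      p.gamma[m, j], perm)
    if p.Q.ndim == 4:
        p.Q[:, m] = p.Q[:, m][:, :, perm]
    else:
        p.Q[m] = p.Q[m][:, perm]


def _apply_family_perm(p: ParameterSet, perm: np.ndarray) -> None:
    p.pi[:] = p.pi[:, perm]
    p.P[:] = p.P[:, perm][:, :, perm]
    if p.Q.ndim == 4:
        p.Q[:] = p.Q[:, :, perm]
    else:
        p.Q[:] = p.Q[:, perm]


def _diag_assignment(Q_m: np.ndarray) -> np.ndarray:
    """Permutation aligning columns to rows by maximizing the diagonal mass."""
    C, Cm = Q_m.shape
    k = min(C, Cm)
    rows, cols = linear_sum_assignment(-Q_m[:k, :k])
    perm = np.arange(Cm)
    perm[rows] = cols
    # make it a proper permutation of all Cm columns
    used = set(perm[:k])
    rest = [c for c in range(Cm) if c not in used]
    perm[k:] = rest
    return perm


def relabel_draw(params: ParameterSet, spec: ModelSpec,
                 ref_member: int | None = None, ref_outcome: int = 0):
    """Return a canonically labelled copy of one draw.

    Returns ``(relabelled, family_map, member_maps, moved)`` where
    ``family_map[old_state] = new_state`` remaps stored cluster-state
    draws, ``member_maps[m]`` does the same per member, and ``moved``
    says whether any permutation was non-trivial.
    """
    p = params.copy()
    M, C, Cm = spec.M, spec.C, spec.Cm
    ref = M - 1 if ref_member is None else ref_member

    if spec.perception_mode == "identity":
        order = np.argsort(-np.cumsum(p.tau[ref, ref_outcome]))
        for m in range(M):
            for j in range(p.tau.shape[1]):
                p.tau[m, j], p.gamma[m, j] = _permute_moments(
                    p.tau[m, j], p.gamma[m, j], order)
        _apply_family_perm_identity(p, order)
        fam_map = _inverse(order)
        member_maps = [fam_map] * M
        moved = not np.array_equal(order, np.arange(C))
        return p, fam_map, member_maps, moved

    member_orders = [np.arange(Cm) for _ in range(M)]

    # 1. reference member by decreasing first-outcome state mean
    order_ref = np.argsort(-np.cumsum(p.tau[ref, ref_outcome]))
    _apply_member_perm(p, ref, order_ref)
    member_orders[ref] = order_ref

    # 2. cluster states via the reference member's perception diagonal
    Q_ref = (p.Q[:, ref].mean(axis=0) if p.Q.ndim == 4 else p.Q[ref])
    fam_order = _family_order_from(Q_ref)
    _apply_family_perm(p, fam_order)

    # 3. remaining members via their own perception diagonals
    for m in range(M):
        if m == ref:
            continue
        Q_m = (p.Q[:, m].mean(axis=0) if p.Q.ndim == 4 else p.Q[m])
        order_m = _diag_assignment(Q_m)
        _apply_member_perm(p, m, order_m)
        member_orders[m] = member_orders[m][order_m]

    fam_map = _inverse(fam_order)
    member_maps = [_inverse(o) for o in member_orders]
    moved = (not np.array_equal(fam_order, np.arange(C))
             or any(not np.array_equal(o, np.arange(Cm))
                    for o in member_orders))
    return p, fam_map, member_maps, moved


def _family_order_from(Q_ref: np.ndarray) -> np.ndarray:
    """Order of old cluster-state rows so the perception diagonal dominates."""
    C, Cm = Q_ref.shape
    k = min(C, Cm)
    rows, cols = linear_sum_assignment(-Q_ref[:, :k].T)  # member state -> row
    order = np.empty(C, dtype=int)
    order[: len(cols)] = cols
    used = set(cols)
    order[len(cols):] = [x for x in range(C) if x not in used]
    return order


def _apply_family_perm_identity(p: ParameterSet, perm: np.ndarray) -> None:
    p.pi[:] = p.pi[:, perm]
    p.P[:] = p.P[:, perm][:, :, perm]
    # Q stays the identity


def _inverse(perm: np.ndarray) -> np.ndarray:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv
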