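"""Long-format panel data container and CSV readers/writers.

A panel is one row per cluster x visit x member x outcome with a numeric
value, plus cluster-level arm labels and cluster-visit covariates.  Missing
outcome cells are permitted and simply contribute no emission factor to the
likelihood (cells are conditionally independent given the latent states, so
cell-wise omission is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelData", "read_panel", "write_panel", "read_panel_wide"]

REQUIRED_COLUMNS = ("cluster_id", "visit", "arm", "member", "outcome", "value")


@dataclass
class PanelData:
    """Observed outcomes with arms and covariates, in dense masked arrays.

    Attributes
    ----------
    y : (N, T, M, J) float array
        Outcome values, NaN where missing; visits beyond a cluster's
        follow-up are all-NaN padding.
    arm : (N,) int array
        0-based arm index per cluster.
    X : (N, T, q) float array
        Cluster-visit covariates.
    n_visits : (N,) int array
        Number of follow-ups per cluster (T = max).
    """

    y: np.ndarray
    arm: np.ndarray
    X: np.ndarray
    n_visits: np.ndarray
    cluster_ids: list = field(default_factory=list)
    arm_names: list = field(default_factory=list)
    member_names: list = field(default_factory=list)
    outcome_names: list = field(default_factory=list)   # per member, length J
    covariate_names: list = field(default_factory=list)
    log_outcomes: list = field(default_factory=list)    # outcome names stored on log scale

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.arm = np.asarray(self.arm, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.n_visits = np.asarray(self.n_visits, dtype=int)
        N, T, M, J = self.y.shape
        if self.arm.shape != (N,):
            raise ValueError("arm must have one entry per cluster")
        if self.X.shape[:2] != (N, T):
            raise ValueError("X must align with y on clusters and visits")
        if not self.cluster_ids:
            self.cluster_ids = list(range(1, N + 1))
        if not self.member_names:
            self.member_names = [f"m{m + 1}" for m in range(M)]
        if not self.outcome_names:
            self.outcome_names = [f"y{j + 1}" for j in range(J)]
        if not self.arm_names:
            self.arm_names = [f"arm{s + 1}" for s in range(int(self.arm.max()) + 1)]
        if not self.covariate_names:
            self.covariate_names = [f"x{k + 1}" for k in range(self.X.shape[2])]
        bad = ~(np.isnan(self.y) | np.isfinite(self.y))
        if bad.any():
            raise ValueError("panel contains non-finite, non-missing outcome values")

    @property
    def n_clusters(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits_max(self) -> int:
        return self.y.shape[1]

    @property
    def n_members(self) -> int:
        return self.y.shape[2]

    @property
    def n_outcomes(self) -> int:
        return self.y.shape[3]

    @property
    def n_arms(self) -> int:
        return len(self.arm_names)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @property
    def observed(self) -> np.ndarray:
        """(N, T, M, J) boolean mask of present cells."""
        return np.isfinite(self.y)

    @property
    def visit_mask(self) -> np.ndarray:
        """(N, T) boolean mask of real (non-padding) visits."""
        return np.arange(self.n_visits_max)[None, :] < self.n_visits[:, None]

    def member_subset(self, members: list[int]) -> "PanelData":
        """Panel restricted to the given members (0-based indices)."""
        return PanelData(
            y=self.y[:, :, members, :].copy(),
            arm=self.arm.copy(), X=self.X.copy(), n_visits=self.n_visits.copy(),
            cluster_ids=list(self.cluster_ids), arm_names=list(self.arm_names),
            member_names=[self.member_names[m] for m in members],
            outcome_names=list(self.outcome_names),
            covariate_names=list(self.covariate_names),
            log_outcomes=list(self.log_outcomes))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (observed cells only), visits 1-based."""
        rows = []
        for i in range(self.n_clusters):
            for t in range(self.n_visits[i]):
                for m in range(self.n_members):
                    for j in range(self.n_outcomes):
                        v = self.y[i, t, m, j]
                        if not np.isfinite(v):
                            continue
                        rec = {
                            "cluster_id": self.cluster_ids[i],
                            "visit": t + 1,
                            "arm": self.arm_names[self.arm[i]],
                            "member": self.member_names[m],
                            "outcome": self.outcome_names[j],
                            "value": v,
                        }
                        for k, name in enumerate(self.covariate_names):
                            rec[name] = self.X[i, t, k]
                        rows.append(rec)
        return pd.DataFrame(rows)


def _build_panel(df: pd.DataFrame, covariates: list[str] | None,
                 log_outcomes: list[str] | None) -> PanelData:
    covariates = list(covariates or [])
    log_outcomes = list(log_outcomes or [])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}'")
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"declared covariate column '{col}' not found")

    dup = df.duplicated(subset=["cluster_id", "visit", "member", "outcome"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate panel key (cluster_id=%r, visit=%r, member=%r, outcome=%r)"
            % (row["cluster_id"], row["visit"], row["member"], row["outcome"]))
    if not np.issubdtype(df["visit"].dtype, np.integer):
        if not np.allclose(df["visit"], df["visit"].astype(int)):
            raise ValueError("visit indices must be positive integers")
    if (df["visit"] < 1).any():
        raise ValueError("visit indices must be positive integers")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        raise ValueError(f"non-numeric value at row {int(np.nonzero(bad.values)[0][0])}")

    # first-appearance order for every label map (logged for reproducibility)
    cluster_ids = list(pd.unique(df["cluster_id"]))
    arm_names = list(pd.unique(df["arm"]))
    member_names = list(pd.unique(df["member"]))
    outcome_names = list(pd.unique(df["outcome"]))

    arm_by_cluster = df.groupby("cluster_id", sort=False)["arm"].agg(pd.unique)
    for cid, arms in arm_by_cluster.items():
        if len(arms) > 1:
            raise ValueError(f"cluster {cid!r}: arm label not constant")

    N = len(cluster_ids)
    T = int(df["visit"].max())
    M, J, q = len(member_names), len(outcome_names), len(covariates)
    y = np.full((N, T, M, J), np.nan)
    X = np.zeros((N, T, q))
    n_visits = np.zeros(N, dtype=int)
    arm = np.zeros(N, dtype=int)

    ci = {c: i for i, c in enumerate(cluster_ids)}
    mi = {m: i for i, m in enumerate(member_names)}
    oi = {o: i for i, o in enumerate(outcome_names)}
    si = {s: i for i, s in enumerate(arm_names)}

    vals = values.to_numpy()
    for row_idx, row in enumerate(df.itertuples(index=False)):
        i = ci[row.cluster_id]
        t = int(row.visit) - 1
        v = vals[row_idx]
        if row.outcome in log_outcomes and np.isfinite(v):
            if v <= 0:
                raise ValueError(
                    f"outcome {row.outcome!r} declared log-scale but value {v} <= 0")
            v = np.log(v)
        y[i, t, mi[row.member], oi[row.outcome]] = v
        arm[i] = si[row.arm]
        n_visits[i] = max(n_visits[i], t + 1)
        for k, c in enumerate(covariates):
            X[i, t, k] = getattr(row, c)

    return PanelData(y=y, arm=arm, X=X, n_visits=n_visits,
                     cluster_ids=cluster_ids, arm_names=arm_names,
                     member_names=member_names, outcome_names=outcome_names,
                     covariate_names=covariates, log_outcomes=log_outcomes)


def read_panel(path, covariates: list[str] | None = None,
               log_outcomes: list[str] | None = None) -> PanelData:
    """Read a long-format panel CSV.

    Required columns: cluster_id, visit, arm, member, outcome, value.
    ``covariates`` names additional cluster-visit covariate columns;
    ``log_outcomes`` names outcomes to be log-transformed at read time
    (values are reported back on the original scale by ``write_panel``).
    """
    return _build_panel(pd.read_csv(path), covariates, log_outcomes)


def panel_from_dataframe(df: pd.DataFrame, covariates=None,
                         log_outcomes=None) -> PanelData:
    return _build_panel(df.copy(), covariates, log_outcomes)


def write_panel(panel: PanelData, path) -> None:
    """Write a panel to long CSV, inverting any read-time log transform."""
    df = panel.to_dataframe()
    if panel.log_outcomes:
        sel = df["outcome"].isin(panel.log_outcomes)
        df.loc[sel, "value"] = np.exp(df.loc[sel, "value"])
    df.to_csv(path, index=False)


def read_panel_wide(path, member_outcome_columns: dict[str, tuple[str, str]],
                    arm_column: str = "arm", cluster_column: str = "cluster_id",
                    visit_column: str = "visit", covariates=None,
                    log_outcomes=None) -> PanelData:
    """Import a wide table with one column per member-outcome series.

    ``member_outcome_columns`` maps a column name to a (member, outcome)
    label pair, e.g. ``{"CDFR": ("child", "DFR"), "PDFR": ("parent", "DFR")}``.
    """
    wide = pd.read_csv(path)
    records = []
    for col, (member, outcome) in member_outcome_columns.items():
        if col not in wide.columns:
            raise ValueError(f"wide column '{col}' not found")
        sub = wide[[cluster_column, visit_column, arm_column] +
                   list(covariates or [])].copy()
        sub.columns = ["cluster_id", "visit", "arm"] + list(covariates or [])
        sub["member"] = member
        sub["outcome"] = outcome
        sub["value"] = wide[col]
        records.append(sub)
    df = pd.concat(records, ignore_index=True)
    df = df[df["value"].notna()].reset_index(drop=True)
    return _build_panel(df, covariates, log_outcomes)
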