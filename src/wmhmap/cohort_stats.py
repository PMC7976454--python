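"""Subject-level statistics for the lacunar-stroke cohort.

Linear regression / ANCOVA of WMH volume and 1-year change on lesion
measures, rank-based group tests (Kruskal-Wallis, nonparametric Levene), and
the dual location-coding path (primary cluster only vs multi-cluster
recoding, so every model can be run twice).

Model fitting is ordinary least squares (delegated to statsmodels) on a
design with an intercept, continuous terms as-is, and categorical terms
expanded to indicator contrasts against a declared reference level.  Rows
with missing values are dropped listwise and the count reported.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .locations import format_codes


@dataclasses.dataclass
class ModelSpec:
    """Specification of one regression model.

    ``categorical`` maps a predictor name to its reference level; such
    predictors expand to indicator columns for every other observed level.
    """

    response: str
    predictors: list[str]
    categorical: dict = dataclasses.field(default_factory=dict)
    recode_multicluster: bool = False

    def __post_init__(self) -> None:
        if self.response in self.predictors:
            raise ValueError("response must not be among predictors")


@dataclasses.dataclass
class FitResult:
    """Per-term estimates of a fitted linear model."""

    terms: pd.DataFrame          # columns: term, B, SE, P
    n_used: int
    n_dropped: int
    r_squared: float
    df_resid: int

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in model")
        r = row.iloc[0]
        return float(r["B"]), float(r["SE"]), float(r["P"])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        b, se, _ = self.coef(term)
        t = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        return b - t * se, b + t * se


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, int]:
    """Assemble (response, design-with-intercept, n_dropped) from a data frame."""
    cols = [spec.response] + list(spec.predictors)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    data = df[cols].copy()
    for col in spec.predictors:
        if col not in spec.categorical and data[col].dtype == bool:
            data[col] = data[col].astype(float)
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)

    pieces = []
    for col in spec.predictors:
        if col in spec.categorical:
            ref = spec.categorical[col]
            levels = pd.unique(data[col].astype(str))
            others = [l for l in sorted(levels) if l != str(ref)]
            for level in others:
                pieces.append(pd.Series(
                    (data[col].astype(str) == level).astype(float),
                    name=f"{col}[{level}]",
                ))
        else:
            pieces.append(pd.to_numeric(data[col]).rename(col))
    X = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=data.index)
    X.insert(0, "Intercept", 1.0)
    y = pd.to_numeric(data[spec.response])
    return y, X, n_dropped


def fit_linear(df: pd.DataFrame, spec: ModelSpec, cov_type: str = "HC3") -> FitResult:
    """Ordinary least squares fit of ``spec`` on the cohort-derived frame.

    Standard errors are heteroscedasticity-consistent (HC3) by default —
    lesion-volume and count data have variance that grows with the mean, so
    classical OLS errors understate the sampling variability; pass
    ``cov_type="nonrobust"`` for the classical ones.  Two-sided t-based
    p-values per coefficient.  Raises on rank-deficient designs (naming the
    aliased terms) and on non-positive residual degrees of freedom.
    """
    y, X, n_dropped = build_design(df, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_used ({n}) must exceed number of parameters ({p})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify aliased columns by pivoted QR-free greedy scan
        aliased = []
        kept = []
        for col in X.columns:
            trial = X[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                aliased.append(col)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    model = sm.OLS(y.to_numpy(), X.to_numpy())
    if cov_type == "nonrobust":
        res = model.fit()
    else:
        res = model.fit(cov_type=cov_type, use_t=True)
    terms = pd.DataFrame({
        "term": list(X.columns),
        "B": res.params,
        "SE": res.bse,
        "P": res.pvalues,
    })
    return FitResult(
        terms=terms.reset_index(drop=True),
        n_used=n,
        n_dropped=n_dropped,
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
    )


def fit_ancova(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """ANCOVA realized as a linear model with categorical + continuous terms.

    Identical machinery to :func:`fit_linear`; the separate name mirrors its
    role (change response adjusted for age, lacune count, risk factors,
    old-lesion volume and location).
    """
    return fit_linear(df, spec)


def _kw_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    n_total = len(values)
    ranks = stats.rankdata(values)
    groups = pd.unique(labels)
    h = 0.0
    for g in groups:
        r = ranks[labels == g]
        h += len(r) * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_groups(
    values, group_labels, method: str = "auto"
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    ``method``: ``"asymptotic"`` uses the chi-square reference with k-1 df;
    ``"exact"`` enumerates all distinct assignments of the observed values to
    the group sizes; ``"auto"`` switches to exact when total n <= 12.
    Identical values across all observations give (H=0, P=1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal length")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("kruskal_groups needs at least 2 groups")
    if (counts < 1).any():
        raise ValueError("every group needs at least 1 observation")
    if np.unique(values).size == 1:
        return 0.0, 1.0
    h = _kw_statistic(values, labels)
    n = len(values)
    if method not in ("auto", "asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= 12)
    if not exact:
        p = float(stats.chi2.sf(h, len(groups) - 1))
        return float(h), p
    # exact permutation null: enumerate distinct splits of indices into groups
    idx = np.arange(n)
    sizes = [int(np.sum(labels == g)) for g in groups]
    count_ge = 0
    total = 0
    perm_labels = np.empty(n, dtype=int)

    def assign(remaining: np.ndarray, gi: int) -> None:
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            perm_labels[remaining] = gi
            h_perm = _kw_statistic(values, perm_labels)
            total += 1
            if h_perm >= h - 1e-12:
                count_ge += 1
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[gi]):
            sel = remaining[list(combo)]
            perm_labels[sel] = gi
            rest = np.delete(remaining, list(combo))
            assign(rest, gi + 1)

    assign(idx, 0)
    return float(h), count_ge / total


def levene_ranked(values, group_labels) -> tuple[float, float]:
    """Nonparametric (rank-based) Levene test of homogeneity of variance.

    The pooled values are rank-transformed, then a Brown-Forsythe style
    one-way F test is run on absolute deviations of the ranks from their
    group medians.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("levene_ranked needs at least 2 groups")
    if (counts < 2).any():
        small = [g for g, c in zip(groups, counts) if c < 2]
        raise ValueError(f"every group needs n >= 2; too small: {small}")
    ranks = stats.rankdata(values)
    samples = [ranks[labels == g] for g in groups]
    stat, p = stats.levene(*samples, center="median")
    return float(stat), float(p)


def recode_locations(cohort: pd.DataFrame, mode: str = "primary_only") -> pd.Series:
    """RSSI location coding for models, in one of the two analysis paths.

    ``primary_only`` keeps the largest cluster's code; ``multi_cluster``
    emits a composite code (``"a|b"``, sorted) for subjects with more than
    one cluster.  No-RSSI subjects get ``"none"``.  Location-code lists are
    stored primary-first (largest cluster first) by the generator and the
    cohort reader, which this relies on.
    """
    if mode not in ("primary_only", "multi_cluster"):
        raise ValueError(f"unknown recode mode: {mode!r}")
    out = []
    for sid, vol, codes in zip(
        cohort["subject_id"], cohort["rssi_volume_ml"], cohort["rssi_location_codes"]
    ):
        if vol > 0 and len(codes) == 0:
            raise ValueError(f"subject {sid!r} has RSSI volume > 0 but no location code")
        if len(codes) == 0:
            out.append("none")
        elif mode == "primary_only" or len(codes) == 1:
            out.append(format_codes([codes[0]]))
        else:
            out.append("|".join(sorted(format_codes([c]) for c in codes)))
    return pd.Series(out, index=cohort.index, name=f"rssi_location_{mode}")


def derive_model_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Augment a cohort table with the derived columns the models use.

    Adds %ICV-normalized volumes, the 1-year WMH change (ml and %ICV; NaN
    without follow-up), the smoker indicator used by default (current or
    recent vs ex or never), and both RSSI location codings.
    """
    df = cohort.copy()
    icv = df["icv_ml"].to_numpy(dtype=float)
    df["wmh_pct_icv_baseline"] = 100.0 * df["wmh_total_ml_baseline"] / icv
    df["rssi_pct_icv"] = 100.0 * df["rssi_volume_ml"] / icv
    df["old_pct_icv"] = 100.0 * df["old_lesion_volume_ml"] / icv
    df["wmh_change_ml"] = df["wmh_total_ml_year1"] - df["wmh_total_ml_baseline"]
    df["wmh_change_pct_icv"] = 100.0 * df["wmh_change_ml"] / icv
    df["smoker"] = df["smoking"].isin(("current", "recent"))
    df["rssi_location_primary"] = recode_locations(df, "primary_only")
    df["rssi_location_multi"] = recode_locations(df, "multi_cluster")
    return df
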