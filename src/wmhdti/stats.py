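"""Cohort statistics: group tests, matching, and nested regression.

Implements the analysis battery applied to the per-tract DTI summaries:

* Mann-Whitney U tests for demographics (exact enumeration at small n,
  tie-corrected normal approximation otherwise);
* pooled-variance Student's t-tests with Cohen's d for the matched
  lower- vs higher-WMH-load subgroup contrast;
* covariate matching that builds those subgroups (greedy nearest-neighbor
  on standardized age / MMSE / ventricle load within sex and CVD strata);
* standardized ordinary least squares (all variables z-scored) and the
  nested-model F-change test on ΔR², used to compare the disease contrast
  unadjusted (model 1: group + ventricle load) and adjusted (model 2:
  + WMH load) for lesion burden.

No multiple-comparison correction is applied by default; Holm correction
is available as an option on the table-level drivers.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .metrics import classify_wmh_load

__all__ = [
    "GroupComparison",
    "RegressionFit",
    "NestedComparison",
    "MatchedPairs",
    "mann_whitney_u",
    "ttest_cohens_d",
    "cohens_d_from_summary",
    "match_subgroups",
    "standardized_ols",
    "nested_model_test",
    "run_table2",
    "run_table3",
]

ALPHA = 0.05


@dataclasses.dataclass
class GroupComparison:
    tract: str
    metric: str                      # "md" | "fa"
    mean_sd_low: Tuple[float, float]
    mean_sd_high: Tuple[float, float]
    t_stat: float
    p_two_sided: float
    cohens_d: float
    n_low: int = 0
    n_high: int = 0


@dataclasses.dataclass
class RegressionFit:
    outcome: str
    predictors: List[str]
    standardized_betas: Dict[str, float]
    beta_p_values: Dict[str, float]
    r_squared: float
    n: int


@dataclasses.dataclass
class NestedComparison:
    fit_model1: RegressionFit
    fit_model2: RegressionFit
    delta_r2: float
    f_change: float
    p_change: float

    @property
    def outcome(self) -> str:
        return self.fit_model2.outcome


@dataclasses.dataclass
class MatchedPairs:
    pairs: List[Tuple[str, str]]            # (lower-load id, higher-load id)
    balance_report: Dict[str, Tuple[float, float]]   # covariate -> (stat, p)

    @property
    def lower_ids(self) -> List[str]:
        return [p[0] for p in self.pairs]

    @property
    def higher_ids(self) -> List[str]:
        return [p[1] for p in self.pairs]


# ---------------------------------------------------------------------------
# rank / location tests


def _u_from_ranks(ranks_a: np.ndarray, n1: int) -> float:
    return ranks_a.sum() - n1 * (n1 + 1) / 2.0


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   exact_max_n: int = 8) -> Tuple[float, float]:
    """Mann-Whitney U (statistic of ``a``) and two-sided p.

    When both samples have at most ``exact_max_n`` observations the null
    distribution of U is enumerated exhaustively over all label
    assignments (midranks make this exact under ties).  Otherwise the
    tie-corrected normal approximation with continuity correction is used.
    All-tied data yield p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)               # midranks
    u_obs = _u_from_ranks(ranks[:n1], n1)
    if np.ptp(combined) == 0:
        warnings.warn("all observations tied; Mann-Whitney p set to 1",
                      stacklevel=2)
        return u_obs, 1.0
    mu = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev = abs(u_obs - mu)
        hits = total = 0
        for subset in itertools.combinations(range(n1 + n2), n1):
            u = _u_from_ranks(ranks[list(subset)], n1)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    # normal approximation, tie-corrected variance, continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u_obs, min(p, 1.0)


def cohens_d_from_summary(mean_low: float, sd_low: float, n_low: int,
                          mean_high: float, sd_high: float,
                          n_high: int) -> float:
    """Cohen's d from group summaries using the pooled standard deviation."""
    s_pooled = np.sqrt(
        ((n_low - 1) * sd_low ** 2 + (n_high - 1) * sd_high ** 2)
        / (n_low + n_high - 2)
    )
    if s_pooled == 0:
        raise ValueError("zero pooled variance")
    return (mean_high - mean_low) / s_pooled


def ttest_cohens_d(low: Sequence[float], high: Sequence[float],
                   tract: str = "", metric: str = "") -> GroupComparison:
    """Pooled-variance two-sided t-test plus Cohen's d (high minus low)."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.size < 2 or high.size < 2:
        raise ValueError("each group needs at least 2 observations")
    m_lo, m_hi = low.mean(), high.mean()
    s_lo, s_hi = low.std(ddof=1), high.std(ddof=1)
    d = cohens_d_from_summary(m_lo, s_lo, low.size, m_hi, s_hi, high.size)
    t, p = sps.ttest_ind(high, low, equal_var=True)
    if low.size == high.size and np.allclose(np.sort(low), np.sort(high)):
        # identical multisets: force the exact null answer
        t, p, d = 0.0, 1.0, 0.0
    return GroupComparison(
        tract=tract, metric=metric,
        mean_sd_low=(m_lo, s_lo), mean_sd_high=(m_hi, s_hi),
        t_stat=float(t), p_two_sided=float(p), cohens_d=float(d),
        n_low=int(low.size), n_high=int(high.size),
    )


# ---------------------------------------------------------------------------
# matching


def match_subgroups(
    cohort: pd.DataFrame,
    target_n: int = 21,
    continuous: Sequence[str] = ("age", "mmse", "vv_pct"),
    strata: Sequence[str] = ("sex", "cvd"),
    group: Optional[str] = "control",
    id_column: str = "subject_id",
) -> MatchedPairs:
    """Greedy 1:1 matching of lower- vs higher-WMH-load subjects.

    Subjects (by default only those in the ``control`` group) are split by
    their WMH load class; pairs are formed by repeatedly taking the
    globally closest unmatched lower/higher pair in standardized Euclidean
    distance over the continuous covariates, first requiring exact
    agreement on all strata, then relaxing strata one by one if a class is
    exhausted before ``target_n`` pairs exist.
    """
    df = cohort if group is None else cohort[cohort["group"] == group]
    load_class = df["wmh_pct"].map(classify_wmh_load)
    lower = df[load_class == "lower"]
    higher = df[load_class == "higher"]
    if len(lower) < target_n or len(higher) < target_n:
        raise ValueError(
            f"not enough subjects to match: {len(lower)} lower-load and "
            f"{len(higher)} higher-load available, {target_n} pairs requested"
        )

    both = pd.concat([lower, higher])
    z = {}
    for c in continuous:
        mu, sd = both[c].mean(), both[c].std(ddof=1)
        z[c] = ((lower[c] - mu) / (sd if sd > 0 else 1.0),
                (higher[c] - mu) / (sd if sd > 0 else 1.0))
    zl = np.stack([z[c][0].to_numpy() for c in continuous], axis=1)
    zh = np.stack([z[c][1].to_numpy() for c in continuous], axis=1)
    dist = np.linalg.norm(zl[:, None, :] - zh[None, :, :], axis=2)

    pairs: List[Tuple[str, str]] = []
    used_l = np.zeros(len(lower), dtype=bool)
    used_h = np.zeros(len(higher), dtype=bool)
    # relaxation ladder: all strata, then drop them from the right
    for k in range(len(strata), -1, -1):
        if len(pairs) >= target_n:
            break
        active = list(strata[:k])
        if active:
            same = np.ones_like(dist, dtype=bool)
            for s in active:
                same &= (lower[s].to_numpy()[:, None]
                         == higher[s].to_numpy()[None, :])
        else:
            same = np.ones_like(dist, dtype=bool)
        d = np.where(same & ~used_l[:, None] & ~used_h[None, :],
                     dist, np.inf)
        while len(pairs) < target_n and np.isfinite(d).any():
            i, j = np.unravel_index(np.argmin(d), d.shape)
            pairs.append((str(lower.iloc[i][id_column]),
                          str(higher.iloc[j][id_column])))
            used_l[i] = used_h[j] = True
            d[i, :] = np.inf
            d[:, j] = np.inf

    ml = lower[used_l]
    mh = higher[used_h]
    report: Dict[str, Tuple[float, float]] = {}
    for c in continuous:
        report[c] = mann_whitney_u(ml[c].to_numpy(), mh[c].to_numpy())
    for s in strata:
        report[s] = _two_proportion_test(ml[s], mh[s])
    return MatchedPairs(pairs=pairs, balance_report=report)


def _two_proportion_test(a: pd.Series, b: pd.Series) -> Tuple[float, float]:
    """Two-sided two-proportion z-test on a binary/categorical covariate."""
    ref = sorted(pd.concat([a, b]).unique())[-1]
    x1, x2 = int((a == ref).sum()), int((b == ref).sum())
    n1, n2 = len(a), len(b)
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    zstat = (x1 / n1 - x2 / n2) / se
    return float(zstat), float(2.0 * sps.norm.sf(abs(zstat)))


# ---------------------------------------------------------------------------
# regression


def standardized_ols(y: Sequence[float], X: pd.DataFrame | Dict[str, Sequence[float]],
                     outcome: str = "y") -> RegressionFit:
    """OLS with every variable z-scored; β on the standardized scale.

    Binary 0/1 predictors are z-scored like any other column.  R² equals
    1 - SSE/SST of the standardized fit (identical to the raw-scale R²).
    Collinear predictors raise, naming the offending columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValueError("y and X must have the same number of rows")
    if n <= p + 1:
        raise ValueError("need more observations than predictors + 1")
    sds = X.std(ddof=1)
    const = sds[sds == 0].index.tolist()
    if const:
        raise ValueError(f"constant predictor column(s): {const}")
    if y.std(ddof=1) == 0:
        raise ValueError("outcome is constant")
    Z = (X - X.mean()) / sds
    if np.linalg.matrix_rank(Z.to_numpy()) < p:
        bad = [
            c for c in Z.columns
            if np.linalg.matrix_rank(Z.drop(columns=[c]).to_numpy())
            == np.linalg.matrix_rank(Z.to_numpy())
        ]
        raise ValueError(f"collinear predictor column(s): {bad}")
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(Z.to_numpy()))
    res = model.fit()
    betas = dict(zip(X.columns, res.params[1:]))
    pvals = dict(zip(X.columns, res.pvalues[1:]))
    return RegressionFit(
        outcome=outcome,
        predictors=list(X.columns),
        standardized_betas={k: float(v) for k, v in betas.items()},
        beta_p_values={k: float(v) for k, v in pvals.items()},
        r_squared=float(res.rsquared),
        n=n,
    )


def nested_model_test(fit1: RegressionFit, fit2: RegressionFit) -> NestedComparison:
    """ΔR² and the F-change test between two nested fits.

    F = (ΔR²/q) / ((1 - R²₂) / (n - p₂ - 1)) with q added predictors;
    identical models give F = 0, p = 1.
    """
    if fit1.n != fit2.n:
        raise ValueError("nested fits must use the same observations")
    s1, s2 = set(fit1.predictors), set(fit2.predictors)
    if not s1 <= s2:
        raise ValueError(
            f"models are not nested: {sorted(s1 - s2)} only in model 1"
        )
    q = len(s2 - s1)
    delta = fit2.r_squared - fit1.r_squared
    if q == 0:
        return NestedComparison(fit1, fit2, max(delta, 0.0), 0.0, 1.0)
    delta = max(delta, 0.0)            # clamp float negatives at exact nesting
    n, p2 = fit2.n, len(fit2.predictors)
    dof = n - p2 - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    denom = (1.0 - fit2.r_squared) / dof
    f = (delta / q) / denom if denom > 0 else np.inf
    p = float(sps.f.sf(f, q, dof))
    return NestedComparison(fit1, fit2, float(delta), float(f), p)


# ---------------------------------------------------------------------------
# table-level drivers


def _holm(pvals: List[float]) -> List[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def run_table2(
    cohort: pd.DataFrame,
    pairs: MatchedPairs,
    tracts: Optional[Sequence[str]] = None,
    metrics: Sequence[str] = ("md", "fa"),
    holm: bool = False,
    id_column: str = "subject_id",
) -> List[GroupComparison]:
    """Matched-subgroup t-tests and effect sizes, one row per tract x metric."""
    df = cohort.set_index(id_column)
    low = df.loc[pairs.lower_ids]
    high = df.loc[pairs.higher_ids]
    if tracts is None:
        tracts = sorted({
            c.rsplit("_", 1)[0] for c in cohort.columns if c.endswith("_md")
        })
    rows: List[GroupComparison] = []
    for t in tracts:
        for m in metrics:
            col = f"{t}_{m}"
            if col not in df.columns:
                warnings.warn(f"missing tract metric column {col!r}; skipped",
                              stacklevel=2)
                continue
            rows.append(ttest_cohens_d(low[col], high[col], tract=t, metric=m))
    if holm and rows:
        for r, padj in zip(rows, _holm([r.p_two_sided for r in rows])):
            r.p_two_sided = padj
    return rows


def run_table3(
    cohort: pd.DataFrame,
    tracts: Optional[Sequence[str]] = None,
    metrics: Sequence[str] = ("md", "fa"),
    extra_covariates: Sequence[str] = (),
) -> List[NestedComparison]:
    """Unadjusted vs WMH-adjusted nested regressions per tract x metric.

    Model 1 regresses the tract metric on group membership (prodromal AD
    vs control) and ventricle load; model 2 adds WMH load.  Additional
    covariate columns may be supplied but are off by default: MMSE and the
    amyloid ratio co-define the diagnosis, so adjusting for them would
    absorb the group effect itself.
    """
    if tracts is None:
        tracts = sorted({
            c.rsplit("_", 1)[0] for c in cohort.columns if c.endswith("_md")
        })
    base = ["ad", "vv_pct", *extra_covariates]
    out: List[NestedComparison] = []
    for t in tracts:
        for m in metrics:
            col = f"{t}_{m}"
            if col not in cohort.columns:
                warnings.warn(f"missing tract metric column {col!r}; skipped",
                              stacklevel=2)
                continue
            y = cohort[col].to_numpy()
            fit1 = standardized_ols(y, cohort[base], outcome=col)
            fit2 = standardized_ols(y, cohort[base + ["wmh_pct"]], outcome=col)
            out.append(nested_model_test(fit1, fit2))
    return out


def table2_frame(rows: List[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "tract": r.tract, "metric": r.metric,
            "mean_low": r.mean_sd_low[0], "sd_low": r.mean_sd_low[1],
            "mean_high": r.mean_sd_high[0], "sd_high": r.mean_sd_high[1],
            "t": r.t_stat, "p": r.p_two_sided, "cohens_d": r.cohens_d,
            "n_low": r.n_low, "n_high": r.n_high,
        }
        for r in rows
    ])


def table3_frame(rows: List[NestedComparison]) -> pd.DataFrame:
    recs = []
    for r in rows:
        f1, f2 = r.fit_model1, r.fit_model2
        recs.append({
            "outcome": f2.outcome,
            "beta_group_m1": f1.standardized_betas["ad"],
            "p_group_m1": f1.beta_p_values["ad"],
            "r2_m1": f1.r_squared,
            "beta_group_m2": f2.standardized_betas["ad"],
            "p_group_m2": f2.beta_p_values["ad"],
            "beta_wmh_m2": f2.standardized_betas["wmh_pct"],
            "p_wmh_m2": f2.beta_p_values["wmh_pct"],
            "r2_m2": f2.r_squared,
            "delta_r2": r.delta_r2,
            "f_change": r.f_change,
            "p_change": r.p_change,
        })
    return pd.DataFrame(recs)
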