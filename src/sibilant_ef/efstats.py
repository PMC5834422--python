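"""Statistics linking articulation to executive-function ratings.

The battery mirrors a small-cohort developmental design: Pearson
correlations between the per-child [s]-[ʃ] differentiation score and each
BRIEF scale (the Global Executive Composite plus five subscales shared by
the school-age and preschool forms), multiplicity control by the
Benjamini–Hochberg step-up rule at a 5% false discovery rate, and ordinary
least-squares regressions — differentiation on GEC (and age in days), GEC
on differentiation (and age) — reporting unstandardised B with classical
standard errors, standardised β, t, model F, R² and adjusted R².  A
moderation model adds the product of the mean-centred predictors.

BRIEF t-scores are norm-referenced (mean 50, SD 10); lower is better EF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: BRIEF scales analysed: the global composite plus the five subscales
#: shared between the BRIEF and BRIEF-P forms.
BRIEF_SCALES = (
    "gec",
    "inhibit",
    "shift",
    "emotional_control",
    "working_memory",
    "plan_organize",
)

T_SCORE_RANGE = (20.0, 120.0)


@dataclass(frozen=True)
class CorrelationResult:
    """One row of the correlation table, with its BH bookkeeping."""

    variable: str
    r: float
    p: float
    n: int
    rank_i: int
    m: int
    bh_critical: float
    passes_fdr: bool
    adjusted_p: float


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    b: float        # unstandardised slope, outcome units per predictor unit
    se: float       # classical (homoskedastic) standard error
    beta: float     # standardised slope, SD units
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[RegressionTerm, ...]
    intercept: float
    f: float
    df1: int
    df2: int
    n: int
    r_squared: float
    adj_r_squared: float
    p_model: float

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def read_ef_csv(path) -> pd.DataFrame:
    """Read the per-child EF table.

    Columns: child_id, version (BRIEF or BRIEF-P), age_days, then the six
    t-score scales.  t-scores outside [20, 120] are rejected; missing
    subscales are allowed and stay NaN.
    """
    df = pd.read_csv(path, dtype={"child_id": str})
    required = {"child_id", "age_days", *BRIEF_SCALES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EF CSV missing columns: {sorted(missing)}")
    for scale in BRIEF_SCALES:
        vals = df[scale].dropna()
        bad = vals[(vals < T_SCORE_RANGE[0]) | (vals > T_SCORE_RANGE[1])]
        if len(bad):
            raise ValueError(
                f"{scale}: t-scores outside {T_SCORE_RANGE}: {bad.tolist()}"
            )
    return df


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with a two-tailed p-value, after pairwise deletion.

    p comes from t = r*sqrt(n-2)/sqrt(1-r²) on n-2 degrees of freedom.
    Returns (r, p, n) where n is the number of complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        which = "x" if np.ptp(x) == 0 else "y"
        raise ValueError(f"variable {which} is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def bh_critical_values(
    p_values, q: float = 0.05
) -> list[tuple[int, float, bool]]:
    """Benjamini–Hochberg critical values and step-up decisions.

    P-values are ranked ascending; the critical value for rank i of m is
    (i/m)·q.  A hypothesis is significant iff its rank is at most the
    largest i with p_(i) <= (i/m)·q (step-up rule — a p-value above its own
    threshold can still pass on the strength of a larger-ranked one).
    Returns [(rank_i, critical, passes), ...] in the input order of
    ``p_values``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    critical = ranks / m * q
    passing_ranks = [i for i in range(1, m + 1) if p[order[i - 1]] <= (i / m) * q]
    cutoff = max(passing_ranks) if passing_ranks else 0
    passes = ranks <= cutoff
    return [(int(ranks[j]), float(critical[j]), bool(passes[j])) for j in range(m)]


def bh_adjusted(p_values) -> np.ndarray:
    """Step-up adjusted p-values: adj_(i) = min_{j>=i} (m·p_(j)/j), capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted


def correlation_table(
    profiles_df: pd.DataFrame,
    ef_df: pd.DataFrame,
    q: float = 0.05,
    scales: tuple[str, ...] = BRIEF_SCALES,
) -> list[CorrelationResult]:
    """Differentiation vs every BRIEF scale, BH-controlled as one family.

    The family size m is the number of scales tested (six by default), and
    missing ratings are handled by pairwise deletion, so each row may use a
    different n.
    """
    merged = profiles_df.merge(ef_df, on="child_id", suffixes=("", "_ef"))
    diff = merged["differentiation_hz"].to_numpy()
    rows = []
    for scale in scales:
        r, p, n = pearson(diff, merged[scale].to_numpy())
        rows.append((scale, r, p, n))
    pvals = [row[2] for row in rows]
    bh = bh_critical_values(pvals, q=q)
    adj = bh_adjusted(pvals)
    return [
        CorrelationResult(
            variable=scale,
            r=r,
            p=p,
            n=n,
            rank_i=rank,
            m=len(rows),
            bh_critical=crit,
            passes_fdr=passes,
            adjusted_p=float(a),
        )
        for (scale, r, p, n), (rank, crit, passes), a in zip(rows, bh, adj)
    ]


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    sd_y = float(np.std(y, ddof=1))
    terms = []
    for name in X.columns:
        b = float(model.params[name])
        sd_x = float(np.std(X[name], ddof=1))
        terms.append(
            RegressionTerm(
                name=name,
                b=b,
                se=float(model.bse[name]),
                beta=b * sd_x / sd_y,
                t=float(model.tvalues[name]),
                p=float(model.pvalues[name]),
            )
        )
    return RegressionResult(
        terms=tuple(terms),
        intercept=float(model.params["const"]),
        f=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        n=int(model.nobs),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        p_model=float(model.f_pvalue),
    )


def ols(y, X: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> RegressionResult:
    """OLS with intercept; B, SE, standardised β, t per term; F, R², adj R².

    Rows with any missing value are dropped (listwise within the model).
    """
    if not isinstance(X, pd.DataFrame):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and names is None:
            X = X.T
        X = pd.DataFrame(X, columns=names or [f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep].reset_index(drop=True)
    k = X.shape[1]
    if y.size <= k + 1:
        raise ValueError(f"need n > {k + 1} observations, got {y.size}")
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X.to_numpy()])) < k + 1:
        raise ValueError("rank-deficient design matrix")
    return _fit_ols(y, X)


def moderation(y, x, z, names: tuple[str, str] = ("x", "z")) -> RegressionResult:
    """Moderation model y ~ x + z + x·z with mean-centred main effects.

    The interaction term is the product of the centred predictors; its
    t-test p-value is the moderation p.  Centring leaves the interaction
    test invariant but makes the main-effect slopes interpretable at the
    sample means.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(z))
    x, z, y = x[keep], z[keep], y[keep]
    xc, zc = x - x.mean(), z - z.mean()
    X = pd.DataFrame(
        {names[0]: xc, names[1]: zc, f"{names[0]}:{names[1]}": xc * zc}
    )
    return ols(y, X)


def version_comparison(ef_df: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-test of each shared scale between BRIEF and BRIEF-P.

    A plain Welch-free (pooled-variance) independent-samples t-test per
    scale; requires both questionnaire versions in the input.  No norms
    logic — this only asks whether the two forms' t-scores differ in this
    sample, which justifies pooling them when they do not.
    """
    if "version" not in ef_df.columns:
        raise ValueError("EF table has no 'version' column")
    groups = ef_df.groupby("version")
    if len(groups) != 2:
        raise ValueError(
            f"need exactly two questionnaire versions, got {sorted(ef_df['version'].unique())}"
        )
    (va, a), (vb, b) = list(groups)
    rows = []
    for scale in BRIEF_SCALES:
        t, p = stats.ttest_ind(a[scale].dropna(), b[scale].dropna(), equal_var=True)
        rows.append({"scale": scale, "group_a": va, "group_b": vb,
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def ef_group_summary(ef_df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of every BRIEF scale by whole-year age group."""
    df = ef_df.copy()
    df["age_years"] = (df["age_days"] // 365.25).astype(int)
    rows = []
    for age, grp in df.groupby("age_years"):
        row = {"age_years": int(age), "n": len(grp)}
        for scale in BRIEF_SCALES:
            row[f"{scale}_mean"] = round(float(grp[scale].mean()), 1)
            row[f"{scale}_sd"] = (
                round(float(grp[scale].std(ddof=1)), 1) if len(grp) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("age_years").reset_index(drop=True)
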