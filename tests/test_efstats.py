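"""Correlation, FDR and regression machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sibilant_ef.efstats import (
    BRIEF_SCALES,
    bh_adjusted,
    bh_critical_values,
    correlation_table,
    ef_group_summary,
    moderation,
    ols,
    pearson,
    read_ef_csv,
)
from sibilant_ef.synthetic_data import CohortSpec, synth_cohort

# a reference family of six raw correlation p-values (one per BRIEF scale)
SIX_PVALUES = [0.001, 0.002, 0.018, 0.007, 0.009, 0.012]


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_perfect_linear():
    r, p, n = pearson([1, 2, 3], [2, 4, 6])
    assert r == pytest.approx(1.0)
    r, _, _ = pearson([1, 2, 3], [6, 4, 2])
    assert r == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula(rng):
    x = rng.standard_normal(31)
    y = 0.5 * x + rng.standard_normal(31)
    r, p, n = pearson(x, y)
    # direct formula oracle
    rx = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert r == pytest.approx(rx, abs=1e-12)
    t = rx * np.sqrt(n - 2) / np.sqrt(1 - rx**2)
    assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), abs=1e-12)


def test_pearson_pairwise_deletion_and_guards(rng):
    x = np.array([1.0, 2, 3, np.nan, 5])
    y = np.array([2.0, 4, np.nan, 8, 11])
    r, p, n = pearson(x, y)
    assert n == 3
    with pytest.raises(ValueError, match="constant"):
        pearson([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError, match="pairs"):
        pearson([1.0, 2.0], [1.0, 2.0])


def test_pearson_affine_invariance(rng):
    x = rng.standard_normal(40)
    y = rng.standard_normal(40)
    r0, _, _ = pearson(x, y)
    r1, _, _ = pearson(3.0 * x + 7.0, 0.5 * y - 2.0)
    assert r1 == pytest.approx(r0, abs=1e-12)
    r2, _, _ = pearson(-x, y)
    assert r2 == pytest.approx(-r0, abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_critical_values_reference_family():
    res = bh_critical_values(SIX_PVALUES, q=0.05)
    by_rank = {rank: crit for rank, crit, _ in res}
    assert round(by_rank[1], 3) == 0.008
    assert round(by_rank[4], 3) == 0.033
    assert round(by_rank[6], 3) == 0.050
    assert all(passes for _, _, passes in res)  # whole family significant


def test_bh_single_pvalue_critical_is_q():
    [(rank, crit, passes)] = bh_critical_values([0.03], q=0.05)
    assert (rank, crit, passes) == (1, 0.05, True)


def test_bh_rank_m_critical_equals_q_and_order_invariance(rng):
    p = list(rng.uniform(0.001, 0.9, 10))
    res = bh_critical_values(p, q=0.05)
    assert max(crit for _, crit, _ in res) == pytest.approx(0.05)
    perm = rng.permutation(10)
    res_perm = bh_critical_values([p[i] for i in perm], q=0.05)
    for j, i in enumerate(perm):
        assert res_perm[j] == res[i]


def _bh_bruteforce(p, q):
    """Exhaustive-scan oracle over all candidate ranks."""
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    m = len(p)
    cutoff = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            cutoff = i
    rejected = np.zeros(m, bool)
    rejected[order[:cutoff]] = True
    return rejected


def test_bh_stepup_matches_exhaustive_scan():
    rng = np.random.default_rng(99)
    for _ in range(100):
        m = int(rng.integers(1, 25))
        p = rng.uniform(1e-6, 1.0, m)
        ours = np.array([passes for _, _, passes in bh_critical_values(p, 0.05)])
        assert np.array_equal(ours, _bh_bruteforce(p, 0.05))


def test_bh_adjusted_identity_ties_and_monotonicity():
    assert bh_adjusted([0.01])[0] == pytest.approx(0.01)
    assert np.allclose(bh_adjusted([0.2, 0.2, 0.2]), 0.2)
    adj = bh_adjusted(SIX_PVALUES)
    # hand-computed step-up: sorted m*p/i = .006,.006,.014,.0135,.0144,.018
    # cumulative min from the right -> .006,.006,.0135,.0135,.0144,.018
    order = np.argsort(SIX_PVALUES)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    assert adj.min() == pytest.approx(0.006)
    assert np.all(adj >= np.asarray(SIX_PVALUES) - 1e-15)


def test_bh_adjusted_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.uniform(1e-5, 1, int(rng.integers(2, 30)))
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjusted(p), adj_sm, atol=1e-12)


def test_bh_input_validation():
    with pytest.raises(ValueError):
        bh_critical_values([])
    with pytest.raises(ValueError):
        bh_critical_values([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_adjusted([1.2])


# ---------------------------------------------------------------------------
# correlation table
# ---------------------------------------------------------------------------

def _latent_profiles(cohort):
    return pd.DataFrame(
        {"child_id": cohort.truth.child_id, "differentiation_hz": cohort.truth.true_diff_hz}
    )


def test_family_size_is_number_of_scales(small_cohort):
    rows = correlation_table(_latent_profiles(small_cohort), small_cohort.ef_ratings)
    assert len(rows) == 6
    assert all(row.m == 6 for row in rows)
    assert {row.variable for row in rows} == set(BRIEF_SCALES)


def test_true_negative_dependence_detected_at_large_n():
    cohort = synth_cohort(CohortSpec(n_children=400, rho_ef=-0.56, seed=21))
    rows = correlation_table(_latent_profiles(cohort), cohort.ef_ratings)
    assert all(row.r < 0 for row in rows)
    gec = next(r for r in rows if r.variable == "gec")
    assert gec.passes_fdr


def test_null_family_false_positive_rate():
    """Under independence the chance of any FDR discovery is about q."""
    any_hits = 0
    n_sims = 400
    for seed in range(n_sims):
        cohort = synth_cohort(CohortSpec(n_children=31, rho_ef=0.0, seed=10_000 + seed))
        rows = correlation_table(_latent_profiles(cohort), cohort.ef_ratings)
        any_hits += any(r.passes_fdr for r in rows)
    rate = any_hits / n_sims
    # the six scale tests are highly correlated (subscales share the GEC),
    # so the family behaves like few effective tests; P(any) stays near q
    assert rate < 0.12


# ---------------------------------------------------------------------------
# OLS and moderation
# ---------------------------------------------------------------------------

def test_ols_exact_fit():
    x = np.arange(10.0)
    res = ols(x.copy(), pd.DataFrame({"x": x}))
    assert res.term("x").b == pytest.approx(1.0, abs=1e-10)
    assert res.term("x").beta == pytest.approx(1.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_single_predictor_f_equals_t_squared(rng):
    x = rng.standard_normal(31)
    y = -0.5 * x + rng.standard_normal(31)
    res = ols(y, pd.DataFrame({"x": x}))
    assert res.f == pytest.approx(res.term("x").t ** 2, abs=1e-10)
    r, _, _ = pearson(x, y)
    assert res.r_squared == pytest.approx(r**2, abs=1e-12)
    assert abs(res.term("x").beta) <= 1.0
    assert np.sign(res.term("x").b) == np.sign(r)
    # adjusted R² identity
    adj = 1 - (1 - res.r_squared) * (res.n - 1) / (res.n - res.df1 - 1)
    assert res.adj_r_squared == pytest.approx(adj, abs=1e-12)
    assert res.adj_r_squared <= res.r_squared


def test_ols_matches_normal_equations_oracle(rng):
    X = rng.standard_normal((31, 2))
    y = X @ np.array([1.5, -2.0]) + rng.standard_normal(31)
    res = ols(y, pd.DataFrame(X, columns=["a", "b"]))
    design = np.column_stack([np.ones(31), X])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    assert res.intercept == pytest.approx(coef[0], abs=1e-10)
    assert res.term("a").b == pytest.approx(coef[1], abs=1e-10)
    assert res.term("b").b == pytest.approx(coef[2], abs=1e-10)
    resid = y - design @ coef
    sigma2 = resid @ resid / (31 - 3)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
    assert res.term("a").se == pytest.approx(se[1], abs=1e-10)


def test_ols_guards(rng):
    x = rng.standard_normal(10)
    with pytest.raises(ValueError, match="rank"):
        ols(x, pd.DataFrame({"a": x, "b": 2 * x}))
    with pytest.raises(ValueError, match="observations"):
        ols([1.0, 2.0], pd.DataFrame({"a": [1.0, 2.0]}))


def test_moderation_detects_pure_interaction(rng):
    x = rng.standard_normal(200)
    z = rng.standard_normal(200)
    y = x * z
    res = moderation(y, x, z)
    t_by_term = {t.name: abs(t.t) for t in res.terms}
    assert t_by_term["x:z"] == max(t_by_term.values())
    assert res.term("x:z").p < 1e-10


def test_moderation_centering_invariance(rng):
    x = rng.standard_normal(60) + 5.0
    z = rng.standard_normal(60) - 3.0
    y = x + z + rng.standard_normal(60)
    p_raw = moderation(y, x, z).term("x:z").p
    p_centered = moderation(y, x - x.mean(), z - z.mean()).term("x:z").p
    assert p_raw == pytest.approx(p_centered, abs=1e-12)


def test_moderation_null_p_uniform(rng):
    """With no true interaction the moderation p-value is uniform."""
    pvals = []
    for _ in range(200):
        x = rng.standard_normal(80)
        z = rng.standard_normal(80)
        y = x + z + rng.standard_normal(80)
        pvals.append(moderation(y, x, z).term("x:z").p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# EF input and summaries
# ---------------------------------------------------------------------------

def test_read_ef_csv_validates_t_scores(tmp_path, small_cohort):
    path = tmp_path / "ef.csv"
    small_cohort.ef_ratings.to_csv(path, index=False)
    df = read_ef_csv(path)
    assert len(df) == 6

    bad = small_cohort.ef_ratings.copy()
    bad.loc[0, "gec"] = 150.0
    bad.to_csv(path, index=False)
    with pytest.raises(ValueError, match="gec"):
        read_ef_csv(path)


def test_version_comparison_is_plain_t_test():
    from sibilant_ef.efstats import version_comparison

    rng = np.random.default_rng(2)
    rows = []
    for i in range(24):
        rows.append({"child_id": f"c{i}", "version": "BRIEF" if i % 2 else "BRIEF-P",
                     "age_days": 1900,
                     **{s: 50 + 8 * rng.standard_normal() for s in BRIEF_SCALES}})
    df = pd.DataFrame(rows)
    table = version_comparison(df)
    assert len(table) == 6
    a = df[df.version == "BRIEF"]["gec"]
    b = df[df.version == "BRIEF-P"]["gec"]
    _, p = stats.ttest_ind(a, b)  # two-tailed p is order-symmetric
    row = table[table.scale == "gec"].iloc[0]
    assert row["p"] == pytest.approx(p, abs=1e-12)
    with pytest.raises(ValueError, match="two questionnaire versions"):
        version_comparison(df[df.version == "BRIEF"])


def test_ef_group_summary_shape(small_cohort):
    table = ef_group_summary(small_cohort.ef_ratings)
    assert {"gec_mean", "gec_sd", "inhibit_mean"} <= set(table.columns)
    assert table["n"].sum() == 6
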