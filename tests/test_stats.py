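"""Statistical operations against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wmhdti.cohort import CohortSpec, simulate_cohort
from wmhdti.stats import (
    cohens_d_from_summary,
    mann_whitney_u,
    match_subgroups,
    nested_model_test,
    run_table2,
    run_table3,
    standardized_ols,
    table3_frame,
    ttest_cohens_d,
)


def _mw_exact_oracle(a, b):
    """Exhaustive-permutation Mann-Whitney oracle via direct pair counting."""
    a, b = list(a), list(b)
    combined = a + b
    n1 = len(a)

    def u_stat(x, y):
        return sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0
            for xi in x for yi in y
        )

    u_obs = u_stat(a, b)
    mu = n1 * len(b) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        x = [combined[i] for i in idx]
        y = [combined[i] for i in range(len(combined)) if i not in idx]
        total += 1
        if abs(u_stat(x, y) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_small_sample_worked_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=4).astype(float)   # ties likely
        b = rng.integers(0, 10, size=4).astype(float)
        u, p = mann_whitney_u(a, b)
        u_o, p_o = _mw_exact_oracle(a, b)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = mann_whitney_u([2.0] * 5, [2.0] * 5)
        assert p == 1.0

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1, 1, 60)
        _, p = mann_whitney_u(a, b)
        from scipy.stats import mannwhitneyu
        p_ref = mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCohensD:
    def test_pooled_formula_worked_example(self):
        """Printed subgroup summaries 0.73±0.03 vs 0.79±0.06 at n=21+21
        give d = 1.2649 by the pooled-SD formula."""
        d = cohens_d_from_summary(0.73, 0.03, 21, 0.79, 0.06, 21)
        assert d == pytest.approx(1.2649, abs=1e-4)

    def test_matches_formula_oracle_on_samples(self):
        rng = np.random.default_rng(2)
        low = rng.normal(0.73, 0.03, 21)
        high = rng.normal(0.79, 0.06, 21)
        r = ttest_cohens_d(low, high)
        sp = np.sqrt(((21 - 1) * low.std(ddof=1) ** 2
                      + (21 - 1) * high.std(ddof=1) ** 2) / 40)
        assert r.cohens_d == pytest.approx(
            (high.mean() - low.mean()) / sp, abs=1e-12
        )
        assert np.sign(r.cohens_d) == np.sign(
            r.mean_sd_high[0] - r.mean_sd_low[0]
        )

    def test_identical_groups_null(self):
        x = [0.7, 0.71, 0.72, 0.73]
        r = ttest_cohens_d(x, x)
        assert r.t_stat == 0.0 and r.cohens_d == 0.0 and r.p_two_sided == 1.0

    def test_swapping_groups_flips_signs(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        r1 = ttest_cohens_d(a, b)
        r2 = ttest_cohens_d(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d_from_summary(0.5, 0.0, 10, 0.7, 0.0, 10)


def _normal_equations_oracle(y, X):
    """Standardized OLS via explicit normal equations."""
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    A = np.column_stack([np.ones(len(yz)), Xz])
    beta = np.linalg.solve(A.T @ A, A.T @ yz)
    resid = yz - A @ beta
    r2 = 1.0 - resid @ resid / (yz @ yz)
    return beta[1:], r2, resid @ resid


class TestStandardizedOls:
    def test_perfect_fit(self):
        x = np.linspace(0, 1, 30)
        fit = standardized_ols(2.0 * x + 1.0, {"x": x})
        assert fit.standardized_betas["x"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = X @ [0.5, -0.2, 0.1] + rng.normal(0, 0.5, 200)
        fit = standardized_ols(y, pd.DataFrame(X, columns=list("abc")))
        betas_o, r2_o, _ = _normal_equations_oracle(y, X)
        got = np.array([fit.standardized_betas[c] for c in "abc"])
        assert np.abs(got - betas_o).max() < 1e-10
        assert fit.r_squared == pytest.approx(r2_o, abs=1e-10)

    def test_recovers_known_generative_betas(self):
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=(2, 10_000))
        y = 0.5 * z1 + 0.3 * z2 + rng.normal(
            0, np.sqrt(1 - 0.25 - 0.09), 10_000
        )
        fit = standardized_ols(y, {"z1": z1, "z2": z2})
        assert fit.standardized_betas["z1"] == pytest.approx(0.5, abs=0.02)
        assert fit.standardized_betas["z2"] == pytest.approx(0.3, abs=0.02)

    def test_scale_invariance_of_standardized_betas(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        y = rng.normal(size=100)
        f1 = standardized_ols(y, X)
        X2 = X.copy()
        X2["a"] = X2["a"] * 1000.0
        f2 = standardized_ols(y, X2)
        for c in ("a", "b"):
            assert abs(f1.standardized_betas[c]
                       - f2.standardized_betas[c]) < 1e-10

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardized_ols(np.arange(10.0),
                             {"c": np.ones(10), "x": np.arange(10.0)})

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            standardized_ols(rng.normal(size=50),
                             {"x": x, "x2": 2.0 * x})


def _sse_f_change_oracle(y, X1, X2):
    """F-change from raw sums of squared errors of the two nested fits."""
    def sse(X):
        A = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ beta
        return r @ r

    sse1, sse2 = sse(X1), sse(X2)
    q = X2.shape[1] - X1.shape[1]
    dof = len(y) - X2.shape[1] - 1
    f = ((sse1 - sse2) / q) / (sse2 / dof)
    from scipy.stats import f as fdist
    return f, fdist.sf(f, q, dof)


class TestNestedModels:
    def test_identical_models_give_null_comparison(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = rng.normal(size=50)
        fit = standardized_ols(y, X)
        cmp_ = nested_model_test(fit, fit)
        assert cmp_.delta_r2 == 0.0
        assert cmp_.f_change == 0.0
        assert cmp_.p_change == 1.0

    def test_matches_sse_decomposition_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 3))
        y = X @ [0.4, 0.0, 0.3] + rng.normal(0, 1, 120)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        f1 = standardized_ols(y, df[["a"]])
        f2 = standardized_ols(y, df)
        cmp_ = nested_model_test(f1, f2)
        f_o, p_o = _sse_f_change_oracle(y, X[:, :1], X)
        assert cmp_.f_change == pytest.approx(f_o, abs=1e-10)
        assert cmp_.p_change == pytest.approx(p_o, abs=1e-10)
        assert cmp_.delta_r2 == pytest.approx(
            f2.r_squared - f1.r_squared, abs=1e-14
        )

    def test_delta_r2_nonnegative_for_noise_predictor(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            x = rng.normal(size=40)
            noise = rng.normal(size=40)
            y = x + rng.normal(0, 1, 40)
            df = pd.DataFrame({"x": x, "noise": noise})
            f1 = standardized_ols(y, df[["x"]])
            f2 = standardized_ols(y, df)
            assert nested_model_test(f1, f2).delta_r2 >= 0.0

    def test_null_predictor_p_uniform(self):
        """Adding pure noise gives a uniform F-change p under the null."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(400):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            df = pd.DataFrame({"x": x, "n": rng.normal(size=50)})
            f1 = standardized_ols(y, df[["x"]])
            f2 = standardized_ols(y, df)
            pvals.append(nested_model_test(f1, f2).p_change)
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = rng.normal(size=40)
        f1 = standardized_ols(y, df[["a"]])
        f2 = standardized_ols(y, df[["b"]])
        with pytest.raises(ValueError, match="nested"):
            nested_model_test(f1, f2)


class TestMatching:
    def _toy_cohort(self, n=30, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        lo = pd.DataFrame({
            "subject_id": [f"L{i}" for i in range(n)],
            "group": "control",
            "wmh_pct": 0.3,
            "age": rng.normal(72, 4, n),
            "mmse": rng.normal(29, 1, n),
            "vv_pct": rng.normal(2.2, 0.9, n),
            "sex": rng.choice(["M", "F"], n),
            "cvd": rng.integers(0, 2, n),
        })
        hi = lo.copy()
        hi["subject_id"] = [f"H{i}" for i in range(n)]
        hi["wmh_pct"] = 1.5
        if not identical:
            hi["age"] = rng.normal(72, 4, n)
            hi["mmse"] = rng.normal(29, 1, n)
            hi["vv_pct"] = rng.normal(2.2, 0.9, n)
            hi["sex"] = rng.choice(["M", "F"], n)
            hi["cvd"] = rng.integers(0, 2, n)
        return pd.concat([lo, hi], ignore_index=True)

    def test_identical_classes_match_perfectly(self):
        df = self._toy_cohort(n=21, identical=True)
        pairs = match_subgroups(df, target_n=21)
        assert len(pairs.pairs) == 21
        ids = [p[0].replace("L", "") for p in pairs.pairs]
        assert sorted(ids) == sorted(p[1].replace("H", "")
                                     for p in pairs.pairs)

    def test_each_subject_used_at_most_once(self):
        df = self._toy_cohort(n=40, seed=1)
        pairs = match_subgroups(df, target_n=21)
        flat = [i for p in pairs.pairs for i in p]
        assert len(flat) == len(set(flat)) == 42

    def test_insufficient_class_reports_counts(self):
        df = self._toy_cohort(n=10)
        with pytest.raises(ValueError, match="10"):
            match_subgroups(df, target_n=21)

    def test_default_cohorts_balanced_after_matching(self):
        """Post-match covariate tests should be non-significant in almost
        every simulated cohort."""
        ok = 0
        n_runs = 25
        for s in range(n_runs):
            df = simulate_cohort(CohortSpec(seed=100 + s))
            pairs = match_subgroups(df)
            ok += all(p > 0.05 for _, p in pairs.balance_report.values())
        assert ok / n_runs >= 0.9


class TestTableDrivers:
    def test_table2_cardinality_and_direction(self):
        df = simulate_cohort(CohortSpec(seed=42))
        pairs = match_subgroups(df)
        rows = run_table2(df, pairs)
        assert len(rows) == 16           # 8 tracts x 2 metrics
        slf_md = [r for r in rows if r.tract == "slf_left"
                  and r.metric == "md"][0]
        slf_fa = [r for r in rows if r.tract == "slf_left"
                  and r.metric == "fa"][0]
        assert slf_md.cohens_d > 0       # lesions elevate MD
        assert slf_fa.cohens_d < 0       # and depress FA

    def test_table2_effect_ordering_follows_susceptibility(self):
        """|d| for MD must rank SLF above DC above the spared tracts in
        most simulated cohorts."""
        wins = 0
        n_runs = 0
        for s in range(30):
            df = simulate_cohort(CohortSpec(seed=500 + s))
            try:
                pairs = match_subgroups(df)
            except ValueError:
                # occasionally fewer than 21 higher-load controls are drawn
                continue
            n_runs += 1
            rows = run_table2(df, pairs, metrics=("md",))
            d = {r.tract: abs(r.cohens_d) for r in rows}
            slf = (d["slf_left"] + d["slf_right"]) / 2
            dc = (d["dc_left"] + d["dc_right"]) / 2
            spared = np.mean([d["vc_left"], d["vc_right"],
                              d["cst_left"], d["cst_right"]])
            wins += slf > dc > spared
        assert wins / n_runs >= 0.9

    def test_table3_structure(self):
        df = simulate_cohort(CohortSpec(seed=7))
        rows = run_table3(df)
        assert len(rows) == 16
        for r in rows:
            assert set(r.fit_model1.predictors) == {"ad", "vv_pct"}
            assert set(r.fit_model2.predictors) == {"ad", "vv_pct",
                                                    "wmh_pct"}
            assert r.delta_r2 >= 0.0

    def test_table3_frame_roundtrip(self):
        df = simulate_cohort(CohortSpec(seed=8))
        frame = table3_frame(run_table3(df, metrics=("md",)))
        assert len(frame) == 8
        assert {"beta_group_m1", "beta_wmh_m2", "delta_r2"} <= set(
            frame.columns
        )

    def test_missing_metric_column_skipped_with_warning(self):
        df = simulate_cohort(CohortSpec(seed=9))
        df = df.drop(columns=["slf_left_fa"])
        with pytest.warns(UserWarning, match="slf_left_fa"):
            rows = run_table3(df)
        assert len(rows) == 15
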