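import itertools
import subprocess
import sys
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ragdel import stats as rs
from ragdel.simulate import simulate_mixed_logit_outcomes

counts = st.integers(0, 30)


class TestChiSquare:
    def test_reproduces_published_offtarget_rag_contrast(self):
        t = rs.ContingencyTable.from_printed(220, 40.5, 91, 20.9)
        assert (t.a, t.c) == (89, 19)
        _, p = rs.chi_square_test(t)
        assert round(p, 3) == 0.001

    def test_equal_proportions_give_zero_statistic(self):
        stat, p = rs.chi_square_test(rs.ContingencyTable(10, 30, 5, 15))
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            rs.chi_square_test(rs.ContingencyTable(0, 0, 5, 15))

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_statistic_equals_algebraic_identity(self, a, b, c, d):
        """Pearson X^2 on a 2x2 equals N(ad-bc)^2 / (r1 r2 c1 c2)."""
        t = rs.ContingencyTable(a, b, c, d)
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if 0 in (r1, r2, c1, c2):
            with pytest.raises(ValueError):
                rs.chi_square_test(t)
            return
        n = a + b + c + d
        want = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        stat, _ = rs.chi_square_test(t)
        assert stat == pytest.approx(want, abs=1e-9)


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher: sum hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_reproduces_published_full_both_contrast(self):
        t = rs.ContingencyTable.from_printed(220, 9.5, 91, 2.2)
        assert round(rs.fisher_exact_test(t), 4) == 0.0297

    def test_identical_rows_give_p_one(self):
        assert rs.fisher_exact_test(rs.ContingencyTable(7, 13, 7, 13)) == pytest.approx(1.0)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_enumeration(self, a, b, c, d):
        t = rs.ContingencyTable(a, b, c, d)
        want = fisher_two_sided_oracle(a, b, c, d)
        assert rs.fisher_exact_test(t) == pytest.approx(want, abs=1e-9)


class TestOddsRatio:
    def test_reproduces_published_crude_or(self):
        t = rs.ContingencyTable.from_printed(220, 9.5, 91, 2.2)
        assert round(rs.odds_ratio(t).odds_ratio, 2) == 4.70

    def test_direct_arithmetic(self):
        res = rs.odds_ratio(rs.ContingencyTable(89, 131, 19, 72))
        assert res.odds_ratio == pytest.approx(6408 / 2489)

    def test_symmetric_table_is_one(self):
        res = rs.odds_ratio(rs.ContingencyTable(12, 34, 12, 34))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_applies_haldane_correction(self):
        res = rs.odds_ratio(rs.ContingencyTable(5, 10, 0, 12))
        assert res.corrected and np.isfinite(res.odds_ratio)


class TestBootstrap:
    def test_all_true_collapses_to_unit_interval(self):
        assert rs.bootstrap_proportion_ci([True] * 20, B=500, seed=1) == (1.0, 1.0)

    def test_width_matches_normal_approximation(self):
        rng = np.random.default_rng(0)
        y = rng.random(220) < 0.405
        p = y.mean()
        lo, hi = rs.bootstrap_proportion_ci(y, B=10_000, seed=3)
        expect = 2 * 1.96 * np.sqrt(p * (1 - p) / y.size)
        assert (hi - lo) == pytest.approx(expect, rel=0.15)

    def test_identical_seed_identical_ci(self):
        y = [True, False, True, True, False]
        assert rs.bootstrap_proportion_ci(y, seed=7) == rs.bootstrap_proportion_ci(y, seed=7)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            rs.bootstrap_proportion_ci([])


def wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by enumerating all rank assignments."""
    nx, ny = len(x), len(y)
    combined = sorted(x + y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for pick in itertools.combinations(range(nx + ny), nx):
        xs = [combined[i] for i in pick]
        ys = [combined[i] for i in range(nx + ny) if i not in pick]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_extreme_separation_small_n(self):
        assert rs.wilcoxon_group_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        x = list(range(11))
        assert rs.wilcoxon_group_test(x, x) == pytest.approx(1.0)

    @given(
        x=st.lists(st.integers(0, 1000), min_size=2, max_size=4),
        y=st.lists(st.integers(0, 1000), min_size=2, max_size=4),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_exact_p_matches_rank_enumeration(self, x, y):
        if len(set(x + y)) < len(x) + len(y):
            return  # exact path is tie-free by construction
        assert rs.wilcoxon_group_test(x, y) == pytest.approx(
            wilcoxon_exact_oracle(x, y), abs=1e-12
        )

    def test_detects_planted_group_difference(self, default_cohort):
        """Per-patient deletion counts differ between groups at the planted
        effect size."""
        counts = default_cohort.truth.groupby("patient_id").size()
        groups = default_cohort.truth.groupby("patient_id").exposure_group.first()
        p = rs.wilcoxon_group_test(
            counts[groups == "high"], counts[groups == "low"]
        )
        assert p < 0.05


class TestAgeAssociation:
    def test_perfect_linear_recovery(self):
        ages = np.arange(3, 15, dtype=float)
        slope, p = rs.age_association(2.0 * ages + 1.0, ages)
        assert slope == pytest.approx(2.0) and p < 1e-12

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(1, 14, size=35)
        values = 2.0 * ages + rng.normal(0, 1.0, size=35)
        slope, _ = rs.age_association(values, ages)
        assert slope == pytest.approx(2.0, abs=0.3)

    def test_permutation_null_is_uniform(self):
        """p-values under permuted ages are U(0,1) (KS check)."""
        rng = np.random.default_rng(10)
        ages = rng.uniform(1, 14, size=30)
        values = rng.normal(size=30)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(ages)
            pvals.append(rs.age_association(values, perm)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            rs.age_association([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestMixedLogit:
    def test_zero_variance_limit_matches_plain_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = np.repeat([0.0, 1.0], 200)
        p = 1 / (1 + np.exp(-(-0.5 + 0.9 * x)))
        y = (rng.random(400) < p).astype(int)
        cluster = np.array([f"c{i // 10}" for i in range(400)])
        fit = rs.fit_mixed_logit(y, x, cluster)
        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.fixed_effect_or == pytest.approx(np.exp(logit.params[1]), rel=1e-3)
        assert fit.random_intercept_var < 1e-4

    def test_complete_separation_is_flagged(self):
        y = np.repeat([0, 1], 50)
        x = np.repeat([0, 1], 50)
        cluster = np.array([f"c{i // 5}" for i in range(100)])
        fit = rs.fit_mixed_logit(y, x, cluster)
        assert fit.separated

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's glmer with 25-point quadrature."""
        y, x, cl = simulate_mixed_logit_outcomes(
            odds_ratio=2.5, intercept_sd=0.8, seed=11
        )
        fit = rs.fit_mixed_logit(y, x, cl)
        csv = tmp_path / "mm.csv"
        import pandas as pd

        pd.DataFrame({"y": y, "x": x, "cl": cl}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x + (1|cl), data=d, family=binomial, nAGQ=25);"
            "cat(fixef(m)[2], as.numeric(VarCorr(m)$cl))"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        beta_r, var_r = map(float, res.stdout.split())
        assert np.log(fit.fixed_effect_or) == pytest.approx(beta_r, abs=1e-3)
        assert fit.random_intercept_var == pytest.approx(var_r, rel=1e-2)

    def test_wald_ci_brackets_point_estimate(self):
        y, x, cl = simulate_mixed_logit_outcomes(seed=2)
        fit = rs.fit_mixed_logit(y, x, cl)
        assert fit.ci_low <= fit.fixed_effect_or <= fit.ci_high


class TestPatientSummaries:
    def test_proportions_use_own_denominator(self, annotated_cohort, default_cohort):
        summaries = rs.patient_summaries(annotated_cohort, default_cohort.patients)
        assert len(summaries) == 35
        row = summaries.iloc[0]
        if row.n_off_target:
            assert row.prop_off_target_rag == pytest.approx(
                row.n_off_target_rag / row.n_off_target
            )

    def test_orphan_patient_errors(self, annotated_cohort):
        from ragdel.models import PatientRecord

        with pytest.raises(ValueError, match="unknown patients"):
            rs.patient_summaries(
                annotated_cohort, [PatientRecord("nobody", "high", 5.0)]
            )

    def test_median_of_counts(self):
        import pandas as pd

        df = pd.DataFrame(
            {"exposure_group": ["high"] * 3, "n": [5, 12, 39]}
        )
        med = rs.group_medians(df, "n")
        assert med.loc["high", "median"] == 12
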