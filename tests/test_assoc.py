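"""Tests for association analyses: Fisher screen, logistic ORs, MICE, Rubin."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mspira.assoc import (
    AssociationResult,
    ContingencyTable2x2,
    adjusted_pooled_or,
    bonferroni_threshold,
    fisher_exact_two_sided,
    fit_logistic_or,
    manhattan_table,
    mice_impute,
    pool_rubin,
)


def fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher enumeration with exact Fractions."""
    r1, r2, c1 = a + b, c + d, a + c
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pts = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k)) for k in range(lo, hi + 1)}
    obs = pts[a]
    tol = Fraction(10_000_001, 10_000_000)
    num = sum(v for v in pts.values() if v <= obs * tol)
    return num / sum(pts.values())


class TestFisher:
    def test_degenerate_margin(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_example_against_enumeration(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(1, 9, 11, 3))
        assert p == pytest.approx(float(fisher_oracle(1, 9, 11, 3)), abs=1e-12)

    def test_doubling_cells_decreases_p(self):
        p1 = fisher_exact_two_sided(ContingencyTable2x2(8, 2, 3, 7))
        p2 = fisher_exact_two_sided(ContingencyTable2x2(16, 4, 6, 14))
        assert p2 < p1

    def test_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            ours = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            theirs = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, abs=1e-7), (a, b, c, d)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 500) == pytest.approx(1e-4)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestManhattan:
    def test_constant_category_flagged_not_kept(self):
        mat = pd.DataFrame({"A01": [1, 1, 1, 1], "B02": [1, 0, 1, 0]})
        tab = manhattan_table(mat, np.array([1, 0, 1, 0]))
        row = tab.set_index("category")
        assert not row.loc["A01", "kept"] and row.loc["B02", "kept"]

    def test_planted_code_has_smallest_p(self, default_bundle):
        """On the default cohort the planted category should win the screen
        when tested against the latent progressor status."""
        from mspira.comorb import build_icd_matrix

        pids = list(default_bundle.patients["patient_id"])
        mat, _ = build_icd_matrix(default_bundle.diagnoses, pids)
        truth = default_bundle.truth.set_index("patient_id").loc[pids, "latent_progressor"]
        tab = manhattan_table(mat, truth.to_numpy())
        best = tab.loc[tab["kept"]].sort_values("p").iloc[0]
        assert best["category"] == "N31"
        assert best["prev_pira"] > best["prev_nopira"]

    def test_label_permutation_type_one_error(self, default_bundle):
        """Under permuted labels ~5% of kept categories fall below 0.05."""
        from mspira.comorb import build_icd_matrix, prevalence_filter

        pids = list(default_bundle.patients["patient_id"])
        mat, _ = build_icd_matrix(default_bundle.diagnoses, pids)
        kept, _ = prevalence_filter(mat)
        mat = mat[kept]
        y = default_bundle.truth.set_index("patient_id").loc[pids, "latent_progressor"].to_numpy()
        rng = np.random.default_rng(42)
        fracs = []
        for _ in range(30):
            perm = rng.permutation(y)
            tab = manhattan_table(mat, perm, lower=0.0, upper=1.0)
            fracs.append((tab["p"] < 0.05).mean())
        # Fisher is conservative for sparse tables: reject well under alpha
        assert np.mean(fracs) < 0.08


class TestLogisticOR:
    def test_crude_or_matches_cross_product(self):
        a, b, c, d = 20, 30, 15, 60
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1] * (a + b) + [0] * (c + d))
        res = fit_logistic_or(y, x)
        assert res.converged
        assert res.estimate == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_exposure_or_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 4000)
        x = rng.integers(0, 2, 4000)
        res = fit_logistic_or(y, x)
        assert res.ci_low < 1.0 < res.ci_high

    def test_separation_flagged(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0])
        res = fit_logistic_or(y, x)
        assert not res.converged and np.isnan(res.estimate)

    def test_rank_deficiency_rejected(self):
        y = np.array([1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError):
            fit_logistic_or(y, x, cov)


class TestRubinPooling:
    def test_worked_example(self):
        pooled = pool_rubin([1.0, 2.0], [0.5, 0.5])
        assert pooled.Qbar == 1.5
        assert pooled.W == 0.5
        assert pooled.B == pytest.approx(0.5)
        assert pooled.T == pytest.approx(1.25)

    def test_degenerate_between_variance(self):
        pooled = pool_rubin([1.0, 1.0, 1.0], [0.4, 0.4, 0.4])
        assert pooled.T == pooled.W and math.isinf(pooled.df)
        lo, hi = pooled.ci()
        assert lo == pytest.approx(1.0 - 1.96 * math.sqrt(0.4), rel=1e-3)

    def test_ci_widens_with_between_variance(self):
        widths = []
        for spread in (0.0, 0.5, 1.0):
            pooled = pool_rubin([1.0 - spread, 1.0 + spread], [0.5, 0.5])
            lo, hi = pooled.ci()
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_too_few_imputations_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [0.5])


class TestMICE:
    def test_no_missing_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, 0.1, 0.9]})
        out = mice_impute(df, m=3, iterations=2, seed=0)
        assert len(out) == 3
        for comp in out:
            pd.testing.assert_frame_equal(comp, df)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        df.loc[:9, "a"] = np.nan
        o1 = mice_impute(df, m=2, iterations=3, seed=7)
        o2 = mice_impute(df, m=2, iterations=3, seed=7)
        for x, y in zip(o1, o2):
            pd.testing.assert_frame_equal(x, y)

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            mice_impute(df, m=2, iterations=1)

    def test_imputation_tracks_conditional_distribution(self):
        """MCAR missingness on a variable with r=0.8 to an observed one:
        imputed values match the conditional mean within error."""
        rng = np.random.default_rng(3)
        n = 600
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        miss = rng.random(n) < 0.3
        df.loc[miss, "y"] = np.nan
        completed = mice_impute(df, m=10, iterations=5, seed=4)
        imp = np.array([c.loc[miss, "y"].to_numpy() for c in completed])
        true_cond_mean = 0.8 * x[miss]
        bias = (imp.mean(axis=0) - true_cond_mean).mean()
        assert abs(bias) < 0.1
        # per-chain draws carry the conditional noise (sd = sqrt(1-r^2) = 0.6)
        per_chain_sd = (imp - true_cond_mean).std(axis=1).mean()
        assert 0.4 < per_chain_sd < 0.9

    def test_categorical_column_imputed_with_observed_levels(self):
        rng = np.random.default_rng(5)
        n = 200
        g = rng.choice(["a", "b", "c"], size=n)
        x = (g == "a") * 1.0 + rng.normal(scale=0.3, size=n)
        df = pd.DataFrame({"g": g, "x": x})
        df.loc[: n // 4, "g"] = None
        out = mice_impute(df, m=2, iterations=3, seed=1)
        for comp in out:
            assert set(comp["g"]) <= {"a", "b", "c"}
            assert not comp["g"].isna().any()


class TestAdjustedPipeline:
    def test_planted_effect_recovered(self):
        """Adjusted MICE-pooled OR recovers a log-OR of 0.5 planted on a
        binary exposure, with covariate missingness."""
        rng = np.random.default_rng(6)
        n = 1200
        exp = (rng.random(n) < 0.3).astype(float)
        cov = rng.normal(size=n)
        logit = -1.2 + 0.5 * exp + 0.4 * cov
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        design = pd.DataFrame({"exposure": exp, "cov": cov})
        design.loc[rng.random(n) < 0.25, "cov"] = np.nan
        res = adjusted_pooled_or(
            y.astype(int), "exposure", design, impute_cols=("cov",), m=5, iterations=5, seed=0
        )
        assert res.converged
        assert res.ci_low < math.exp(0.5) < res.ci_high
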