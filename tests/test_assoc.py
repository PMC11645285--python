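import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pprskit import assoc
from pprskit.assoc import (AssocRecord, TransformSpec, assoc_scan, bh_fdr,
                           bonferroni_threshold, fisher_one_sided,
                           interaction_scan, ivw_meta, rank_inverse_normal,
                           select_proxy)
from tests.conftest import make_genotypes


def _rec(vid, beta, se, p=0.01, **kw):
    defaults = dict(trait="t", adjustment="none", effect_allele="A",
                    other_allele="G", eaf=0.3, n=100)
    defaults.update(kw)
    return AssocRecord(variant_id=vid, beta=beta, se=se, p=p, **defaults)


class TestRankInverseNormal:
    def test_middle_value_is_zero(self):
        out = rank_inverse_normal([10.0, 3.0, 7.0, 1.0, 5.0])
        assert out[4] == pytest.approx(0.0, abs=1e-12)  # 5.0 is the median

    def test_blom_three_values(self):
        # normal-quantile oracle on Blom scores (r - 3/8)/(n + 1/4)
        out = rank_inverse_normal([1.0, 2.0, 3.0])
        assert out == pytest.approx([-0.8694, 0.0, 0.8694], abs=1e-3)

    def test_ties_average_rank(self):
        out = rank_inverse_normal([5.0, 5.0, 7.0])
        assert out[0] == out[1]
        expected = stats.norm.ppf((1.5 - 0.375) / (3 + 1 - 0.75))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_nan_propagates(self):
        out = rank_inverse_normal([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_all_identical_errors(self):
        with pytest.raises(ValueError, match="identical"):
            rank_inverse_normal([4.0, 4.0, 4.0])

    def test_too_few_errors(self):
        with pytest.raises(ValueError, match="3 finite"):
            rank_inverse_normal([1.0, 2.0])

    def test_moments(self):
        rng = np.random.default_rng(0)
        out = rank_inverse_normal(rng.exponential(1, 10_000))
        assert abs(out.mean()) < 1e-8
        assert abs(out.var() - 1) < 0.02

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ranks(self, values):
        x = np.array(values)
        out = rank_inverse_normal(x)
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) > 0)


class TestAssocScanLinear:
    def test_closed_form_five_samples(self):
        # normal-equations oracle on a tiny worked matrix
        d = np.array([[0, 1, 2, 1, 0.0]]).T
        gm = make_genotypes(d)
        y = np.array([1.0, 2.0, 4.5, 2.5, 0.5])
        cov = np.array([0.1, -0.3, 0.2, 0.0, 0.4])
        X = np.column_stack([np.ones(5), cov, d[:, 0]])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        rec = assoc_scan(gm, y, cov, "linear")[0]
        assert rec.beta == pytest.approx(coef[2], abs=1e-10)
        resid = y - X @ coef
        sigma2 = resid @ resid / 2
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[2, 2])
        assert rec.se == pytest.approx(se, abs=1e-10)
        assert rec.n == 5

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, (200, 3)).astype(float)
        cov = rng.normal(0, 1, (200, 2))
        y = d[:, 0] * 0.3 + rng.normal(0, 1, 200)
        recs = assoc_scan(make_genotypes(d), y, cov, "linear")
        for j, rec in enumerate(recs):
            X = sm.add_constant(np.column_stack([cov, d[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert rec.beta == pytest.approx(fit.params[-1], abs=1e-10)
            assert rec.se == pytest.approx(fit.bse[-1], abs=1e-10)
            assert rec.p == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_null_p_uniform(self):
        # null-distribution simulation: many independent null variants
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, (500, 2000)).astype(float)
        y = rng.normal(0, 1, 500)
        recs = assoc_scan(make_genotypes(d, positions=range(1, 2001)), y)
        pvals = np.array([r.p for r in recs])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_beta_recovered(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, (20_000, 1)).astype(float)
        y = 0.2 * d[:, 0] + rng.normal(0, 1, 20_000)
        rec = assoc_scan(make_genotypes(d), y)[0]
        assert abs(rec.beta - 0.2) < 3 * rec.se

    def test_constant_dosage_flagged(self):
        d = np.column_stack([np.full(50, 1.0), np.random.default_rng(0)
                             .binomial(2, 0.4, 50)]).astype(float)
        recs = assoc_scan(make_genotypes(d), np.random.default_rng(1).normal(0, 1, 50))
        assert recs[0].note == "constant dosage" and np.isnan(recs[0].beta)
        assert np.isfinite(recs[1].beta)

    def test_missing_dosage_reduces_n(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, (100, 1)).astype(float)
        d[:10, 0] = np.nan
        rec = assoc_scan(make_genotypes(d), rng.normal(0, 1, 100))[0]
        assert rec.n == 90

    def test_missing_path_matches_clean_path(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, (300, 1)).astype(float)
        y = 0.2 * d[:, 0] + rng.normal(0, 1, 300)
        cov = rng.normal(0, 1, 300)
        clean = assoc_scan(make_genotypes(d), y, cov)[0]
        d2 = d.copy()
        d2 = np.column_stack([d2, d2])  # second column routed via missing path
        d2[0, 1] = np.nan
        both = assoc_scan(make_genotypes(d2), y, cov)
        assert both[0].beta == pytest.approx(clean.beta, abs=1e-12)


class TestAssocScanLogistic:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, (500, 2)).astype(float)
        lin = -1 + 0.4 * d[:, 0]
        y = (rng.random(500) < 1 / (1 + np.exp(-lin))).astype(float)
        recs = assoc_scan(make_genotypes(d), y, family="logistic")
        for j, rec in enumerate(recs):
            fit = sm.Logit(y, sm.add_constant(d[:, j])).fit(disp=0)
            assert rec.beta == pytest.approx(fit.params[-1], abs=1e-6)
            assert rec.se == pytest.approx(fit.bse[-1], rel=1e-5)

    def test_separation_flagged(self):
        d = np.array([[0, 0, 0, 0, 2, 2, 2, 2.0]]).T
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        rec = assoc_scan(make_genotypes(d), y, family="logistic")[0]
        assert rec.note in {"separation", "nonconvergence"}


class TestInteractionScan:
    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(7)
        n = 20_000
        d = rng.binomial(2, 0.3, (n, 1)).astype(float)
        e = rng.normal(0, 1, n)
        y = 0.1 * d[:, 0] + 0.2 * e + 0.1 * d[:, 0] * e + rng.normal(0, 1, n)
        rec = interaction_scan(make_genotypes(d), y, e)[0]
        assert abs(rec.beta - 0.1) < 3 * rec.se

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        n_sims, n = 1000, 1500
        rejected = 0
        for _ in range(n_sims):
            d = rng.binomial(2, 0.3, (n, 1)).astype(float)
            e = rng.normal(0, 1, n)
            y = 0.2 * d[:, 0] + 0.1 * e + rng.normal(0, 1, n)
            rec = interaction_scan(make_genotypes(d), y, e)[0]
            rejected += rec.p < 0.05
        assert 0.035 <= rejected / n_sims <= 0.065

    def test_hc3_close_to_classical_when_homoskedastic(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        n = 10_000
        d = rng.binomial(2, 0.3, (n, 1)).astype(float)
        e = rng.normal(0, 1, n)
        y = 0.1 * d[:, 0] + 0.1 * e + rng.normal(0, 1, n)
        rec = interaction_scan(make_genotypes(d), y, e)[0]
        X = np.column_stack([np.ones(n), d[:, 0], e, d[:, 0] * e])
        classical = sm.OLS(y, X).fit().bse[3]
        assert abs(rec.se - classical) / classical < 0.10

    def test_log_transform_requires_positive(self):
        d = np.random.default_rng(0).binomial(2, 0.3, (100, 1)).astype(float)
        y = np.random.default_rng(1).normal(0, 1, 100)  # not strictly positive
        with pytest.raises(ValueError, match="positive"):
            interaction_scan(make_genotypes(d), y, y, log_transform=True)


class TestIVWMeta:
    def test_single_study_identity(self):
        res = ivw_meta([(0.12, 0.04)])
        assert res.pooled_beta == pytest.approx(0.12)
        assert res.pooled_se == pytest.approx(0.04)
        assert res.k_studies == 1

    def test_equal_weights_arithmetic_mean(self):
        res = ivw_meta([(0.1, 0.1), (0.3, 0.1)])
        assert res.pooled_beta == pytest.approx(0.2, abs=1e-15)
        assert res.pooled_se == pytest.approx(0.1 / np.sqrt(2), abs=1e-15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            studies = [(rng.normal(), rng.uniform(0.01, 1)) for _ in range(5)]
            res = ivw_meta(studies)
            w = np.array([1 / s ** 2 for _, s in studies])
            b = np.array([b for b, _ in studies])
            assert res.pooled_beta == pytest.approx((w * b).sum() / w.sum(),
                                                    abs=1e-12)

    def test_pooled_se_shrinks_with_k(self):
        res = ivw_meta([(0.1, 0.2)] * 4)
        assert res.pooled_se == pytest.approx(0.2 / 2, abs=1e-15)
        assert res.pooled_se <= 0.2

    def test_pooled_within_hull(self):
        res = ivw_meta([(0.1, 0.3), (0.5, 0.05), (0.2, 0.1)])
        assert 0.1 <= res.pooled_beta <= 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no studies"):
            ivw_meta([])

    def test_bad_se_errors(self):
        with pytest.raises(ValueError, match="SE"):
            ivw_meta([(0.1, 0.0)])


class TestSelectProxy:
    def test_duplicate_column_chosen(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, (200, 1)).astype(float)
        other = rng.binomial(2, 0.3, (200, 1)).astype(float)
        gm = make_genotypes(np.column_stack([g, g, other]),
                            positions=[1000, 2000, 3000])
        assert select_proxy("v1", gm) == "v2"

    def test_none_when_below_threshold(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.3, (500, 3)).astype(float)
        gm = make_genotypes(d, positions=[1000, 2000, 3000])
        assert select_proxy("v1", gm, r2_min=0.4) is None

    def test_highest_r2_wins(self):
        rng = np.random.default_rng(13)
        n = 4000
        a = rng.binomial(1, 0.3, (n, 2))
        g = a.sum(1).astype(float)

        def tag(keep_p):
            keep = rng.random((n, 2)) < keep_p
            fresh = rng.binomial(1, 0.3, (n, 2))
            return np.where(keep, a, fresh).sum(1).astype(float)

        gm = make_genotypes(np.column_stack([g, tag(np.sqrt(0.6)),
                                             tag(np.sqrt(0.5))]),
                            positions=[1000, 2000, 3000])
        assert select_proxy("v1", gm) == "v2"

    def test_window_respected(self):
        g = np.random.default_rng(14).binomial(2, 0.3, (100, 1)).astype(float)
        gm = make_genotypes(np.column_stack([g, g]),
                            positions=[1000, 5_000_000])
        assert select_proxy("v1", gm, window_bp=1_000_000) is None

    def test_missing_target_errors(self):
        gm = make_genotypes(np.zeros((10, 1)) + 1.0)
        with pytest.raises(KeyError):
            select_proxy("nope", gm)


class TestMultipleTesting:
    def test_bonferroni_printed_threshold(self):
        # printed threshold: 0.05 / 19,535
        thr = bonferroni_threshold(0.05, 19_535)
        assert float(f"{thr:.3g}") == 2.56e-6

    def test_bonferroni_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_bonferroni_monotone(self):
        thrs = [bonferroni_threshold(0.05, m) for m in [1, 10, 100, 1000]]
        assert all(a > b for a, b in zip(thrs, thrs[1:]))

    def test_bonferroni_zero_m_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_bh_step_up(self):
        # step-up enumeration: all three pass at q=0.05
        flags = bh_fdr([0.01, 0.02, 0.04], q=0.05)
        assert flags.sum() == 3

    def test_bh_matches_enumeration(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            p = rng.uniform(0.001, 1, 12)
            flags = bh_fdr(p, q=0.05)
            # brute-force step-up: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            m = len(p)
            k_star = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= k * 0.05 / m:
                    k_star = k
            expected = np.zeros(m, dtype=bool)
            expected[order[:k_star]] = True
            assert np.array_equal(flags, expected)


class TestFisherOneSided:
    def test_worked_example(self):
        assert fisher_one_sided([[3, 1], [1, 3]]) == pytest.approx(17 / 70,
                                                                   abs=1e-12)

    def test_zero_margin(self):
        assert fisher_one_sided([[0, 0], [2, 3]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # all tables with N <= 12
        from itertools import product
        for a, b, c, d in product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            got = fisher_one_sided([[a, b], [c, d]])
            # upper tail of Hypergeom(N, row1, col1) at X >= a
            N, r1, c1 = a + b + c + d, a + b, a + c
            expected = stats.hypergeom.sf(a - 1, N, r1, c1)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[1, -1], [0, 2]])


class TestTransformSpec:
    def test_bad_offset(self):
        with pytest.raises(ValueError):
            TransformSpec(offset=0.5)

    def test_bad_kind(self):
        with pytest.raises(ValueError):
            TransformSpec(kind="boxcox")

    def test_zbeta_consistency(self):
        # |beta/se| consistent with p under the normal test
        rec = _rec("v1", beta=0.2, se=0.1,
                   p=float(2 * stats.norm.sf(2.0)))
        assert 2 * stats.norm.sf(abs(rec.z)) == pytest.approx(rec.p, abs=1e-6)
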