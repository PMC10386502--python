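"""Univariate logistic screen, multiple-testing adjustments, p-value ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import metaborank as mb
from metaborank.containers import AbundanceMatrix, SampleMetadata
from metaborank.univariate import bh_fdr_adjust, bonferroni_adjust, rank_by_pvalues


def _abundance(values):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return AbundanceMatrix(values, [f"S{i}" for i in range(n)],
                           [f"M{j:03d}" for j in range(p)], stage="scaled")


def _meta(y, age=None, sex=None):
    n = len(y)
    rng = np.random.default_rng(0)
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "outcome": y,
        "age": age if age is not None else rng.normal(52, 10, n).clip(20, 90),
        "sex": sex if sex is not None else np.where(rng.random(n) < 0.78, "F", "M"),
        "batch": ["B1"] * n,
    }))


def _bh_oracle(p):
    """Literal step-up: q_(i) = min_{j >= i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, i in enumerate(order):
        best = 1.0
        for j in range(pos, m):
            q = p[order[j]] * m / (j + 1)
            if q < best:
                best = q
        out[i] = best
    return out


class TestSingleFit:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        age = rng.normal(52, 10, n)
        sex = (rng.random(n) < 0.7).astype(float)
        eta = 0.8 * x + 0.02 * (age - 52) + 0.3 * sex - 0.1
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, se, p = mb.fit_univariate_logistic(y, x, np.column_stack([age, sex]))
        D = sm.add_constant(np.column_stack([x, age, sex]))
        ref = sm.Logit(y, D).fit(disp=0)
        assert beta == pytest.approx(ref.params[1], abs=1e-6)
        assert se == pytest.approx(ref.bse[1], abs=1e-6)
        assert p == pytest.approx(ref.pvalues[1], abs=1e-6)

    def test_scan_matches_statsmodels_per_feature(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n, p = 300, 8
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.5).astype(int)
        m = _abundance(X)
        meta = _meta(y)
        scan = mb.univariate_scan(m, meta)
        age_c = meta.age - meta.age.mean()
        sex = meta.sex_indicator
        for j in range(p):
            D = sm.add_constant(np.column_stack([X[:, j], age_c, sex]))
            ref = sm.Logit(y, D).fit(disp=0)
            assert scan.beta[j] == pytest.approx(ref.params[1], abs=1e-6)
            assert scan.raw_p[j] == pytest.approx(ref.pvalues[1], abs=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        n, p = 500, 200
        X = rng.standard_normal((n, p))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        scan = mb.univariate_scan(_abundance(X), _meta(y))
        ks = stats.kstest(scan.raw_p, "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_planted_coefficient(self):
        rng = np.random.default_rng(8)
        n, reps = 2000, 100
        betas = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
            scan = mb.univariate_scan(_abundance(x[:, None]), _meta(y))
            betas.append(scan.beta[0])
        assert np.mean(betas) == pytest.approx(1.0, abs=0.15)

    def test_constant_feature_scored_missing(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.zeros(100), rng.standard_normal(100)])
        y = (rng.random(100) < 0.5).astype(int)
        scan = mb.univariate_scan(_abundance(X), _meta(y))
        assert not np.isfinite(scan.raw_p[0])
        assert np.isfinite(scan.raw_p[1])
        with pytest.raises(ValueError, match="constant"):
            mb.fit_univariate_logistic(y, np.zeros(100), np.zeros((100, 2)))


class TestAdjustments:
    def test_bonferroni_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01], m=4), [0.04])
        np.testing.assert_allclose(bonferroni_adjust([0.4], m=4), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.0], m=100), [0.0])

    def test_bh_stepup_example(self):
        np.testing.assert_allclose(bh_fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_bh_matches_bruteforce_exactly(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 51)))
            assert np.array_equal(bh_fdr_adjust(p), _bh_oracle(p))

    def test_bh_close_to_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(30)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_adjustment_invariants(self, pvals):
        p = np.array(pvals)
        bh = bh_fdr_adjust(p)
        bonf = bonferroni_adjust(p)
        assert np.all(bh >= p - 1e-15)
        assert np.all(bonf >= bh - 1e-12)          # Bonferroni more conservative
        # monotone: sorting by p sorts both adjustments
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(bh[order]) >= -1e-15)
        assert np.all(np.diff(bonf[order]) >= -1e-15)

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestRanking:
    def test_raw_p_breaks_adjusted_ties(self):
        r = rank_by_pvalues([1.0, 1.0], [0.3, 0.2], ["A", "B"], "fdr")
        assert list(r.rank) == [2, 1]

    def test_plain_ordering(self):
        r = rank_by_pvalues([0.01, 0.5, 0.2], [0.01, 0.5, 0.2],
                            ["A", "B", "C"], "bonferroni")
        assert list(r.rank) == [1, 3, 2]

    def test_feature_id_breaks_full_ties(self):
        r = rank_by_pvalues([0.5, 0.5, 0.5], [0.1, 0.1, 0.1],
                            ["C", "A", "B"], "fdr")
        assert list(r.rank) == [3, 1, 2]

    def test_missing_pvalues_imputed_at_total(self):
        r = rank_by_pvalues([0.1, np.nan, 0.2], [0.1, np.nan, 0.2],
                            ["A", "B", "C"], "fdr")
        assert list(r.rank) == [1, 3, 2]
        assert list(r.imputed) == [False, True, False]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_by_pvalues([0.1], [0.1, 0.2], ["A", "B"], "fdr")
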