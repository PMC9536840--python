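import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import binom, fligner as scipy_fligner

from metpleio import enrichstats as es


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_binom_two_sided(x1, total, q0):
    """Probability-mass rule by full outcome enumeration."""
    probs = binom.pmf(np.arange(total + 1), total, q0)
    return float(probs[probs <= probs[x1] * (1 + 1e-9)].sum())


def oracle_hypergeom(a, b, c, d):
    """Enumerated central hypergeometric pmf over the table's support."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    amin, amax = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(amin, amax + 1)
    logw = (
        gammaln(row1 + 1) - gammaln(ks + 1) - gammaln(row1 - ks + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - ks + 1)
        - gammaln(n - row1 - col1 + ks + 1)
    )
    w = np.exp(logw - logw.max())
    return ks, w / w.sum(), logw


def oracle_fisher_p(a, b, c, d):
    ks, pmf, _ = oracle_hypergeom(a, b, c, d)
    obs = pmf[ks == a][0]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))


def oracle_cmle_or(a, b, c, d, tol=1e-12):
    """Bisection on the enumerated noncentral expectation."""
    ks, _, logw = oracle_hypergeom(a, b, c, d)
    if a == ks[0]:
        return 0.0
    if a == ks[-1]:
        return math.inf

    def expectation(log_theta):
        lp = logw + ks * log_theta
        lp -= lp.max()
        p = np.exp(lp)
        return float((ks * p).sum() / p.sum())

    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expectation(mid) < a:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return math.exp((lo + hi) / 2)


# ---------------------------------------------------------------------------
# Poisson rate test
# ---------------------------------------------------------------------------


class TestPoissonRate:
    def test_symmetric_null(self):
        res = es.poisson_rate_test(5, 1.0, 5, 1.0)
        assert res.statistic == 1.0
        assert res.p == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_enzyme_enrichment_example(self):
        # 68 hits in 24.29 Mb vs 213 in 1950 Mb: ~25-fold, CI ~ [20, 33]
        res = es.poisson_rate_test(68, 24.29, 213, 1950.0)
        assert res.statistic == pytest.approx(25.6, abs=0.2)
        assert res.p < 1e-15
        assert res.ci_low == pytest.approx(20.0, abs=1.0)
        assert res.ci_high == pytest.approx(33.0, abs=1.5)

    def test_zero_both_counts_error(self):
        with pytest.raises(ValueError):
            es.poisson_rate_test(0, 1.0, 0, 1.0)

    def test_nonpositive_exposure_error(self):
        with pytest.raises(ValueError):
            es.poisson_rate_test(1, 0.0, 1, 1.0)

    @pytest.mark.parametrize("l1,l2", [(1.0, 1.0), (2.0, 5.0)])
    def test_small_counts_match_enumeration(self, l1, l2):
        q0 = l1 / (l1 + l2)
        for total in range(1, 16):
            for x1 in range(total + 1):
                x2 = total - x1
                res = es.poisson_rate_test(x1, l1, x2, l2)
                assert res.p == pytest.approx(oracle_binom_two_sided(x1, total, q0), abs=1e-10)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x1, x2 = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            if x1 + x2 == 0:
                continue
            l1, l2 = rng.uniform(0.5, 50, 2)
            res = es.poisson_rate_test(x1, l1, x2, l2)
            assert res.ci_low <= res.statistic <= res.ci_high


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_balanced_table(self):
        res = es.fisher_exact(1, 1, 1, 1)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.p == 1.0

    def test_zero_cell_or_zero_finite_upper(self):
        res = es.fisher_exact(0, 5, 5, 5)
        assert res.statistic == 0.0
        assert res.ci_low == 0.0
        assert np.isfinite(res.ci_high)

    def test_degenerate_margin(self):
        res = es.fisher_exact(0, 0, 3, 4)
        assert res.p == 1.0
        assert math.isnan(res.statistic)

    def test_negative_cell_error(self):
        with pytest.raises(ValueError):
            es.fisher_exact(-1, 1, 1, 1)

    def test_matches_scipy_p(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if (a + b) in (0, a + b + c + d) or (a + c) in (0, a + b + c + d):
                continue
            res = es.fisher_exact(a, b, c, d, conf=None)
            assert res.p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            n = a + b + c + d
            if (a + b) in (0, n) or (a + c) in (0, n):
                continue
            res = es.fisher_exact(a, b, c, d, conf=None)
            assert res.p == pytest.approx(oracle_fisher_p(a, b, c, d), abs=1e-9)
            expected_or = oracle_cmle_or(a, b, c, d)
            if math.isinf(expected_or):
                assert math.isinf(res.statistic)
            else:
                assert res.statistic == pytest.approx(expected_or, abs=1e-6, rel=1e-6)

    def test_worked_example_vs_r(self):
        # R: fisher.test(matrix(c(12,3,2,9),2)) ->
        # p=0.004314174, cMLE OR=15.44496, CI [1.899944, 224.291]
        # (R's uniroot runs at lower precision; CI compared loosely)
        res = es.fisher_exact(12, 2, 3, 9)
        assert res.p == pytest.approx(0.004314174, abs=1e-8)
        assert res.statistic == pytest.approx(15.44496, rel=1e-4)
        assert res.ci_low == pytest.approx(1.899944, rel=1e-3)
        assert res.ci_high == pytest.approx(224.291, rel=3e-3)


# ---------------------------------------------------------------------------
# Wilson interval
# ---------------------------------------------------------------------------


class TestWilson:
    def test_zero_successes_low_zero(self):
        low, high = es.wilson_interval(0, 10)
        assert low == 0.0
        assert high > 0

    def test_all_successes_high_one(self):
        low, high = es.wilson_interval(10, 10)
        assert high == 1.0

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 100))
            k = int(rng.integers(0, n + 1))
            low, high = es.wilson_interval(k, n)
            assert low <= k / n <= high

    def test_endpoints_are_score_quadratic_roots(self):
        from scipy.optimize import brentq
        from scipy.stats import norm

        z = norm.ppf(0.975)
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(2, 80))
            k = int(rng.integers(1, n))
            phat = k / n

            def score(p):
                return (phat - p) ** 2 - z**2 * p * (1 - p) / n

            low, high = es.wilson_interval(k, n)
            r1 = brentq(score, 0, phat)
            r2 = brentq(score, phat, 1)
            assert low == pytest.approx(r1, abs=1e-10)
            assert high == pytest.approx(r2, abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 10), (0, 7), (50, 60), (1, 2)]:
            low, high = es.wilson_interval(k, n)
            sl, sh = proportion_confint(k, n, method="wilson")
            assert low == pytest.approx(sl, abs=1e-12)
            assert high == pytest.approx(sh, abs=1e-12)


# ---------------------------------------------------------------------------
# Fligner-Killeen
# ---------------------------------------------------------------------------


class TestFligner:
    def test_identical_groups(self):
        g = np.arange(10.0)
        stat, p = es.fligner_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tenfold_spread_detected(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(0, 10, 50)
        _, p = es.fligner_test(g1, g2)
        assert p < 0.01

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0, 2, 30)
        s1, _ = es.fligner_test(g1, g2)
        s2, _ = es.fligner_test(g1 + 100.0, g2)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g1 = rng.normal(0, 1, int(rng.integers(5, 40)))
            g2 = rng.normal(0, rng.uniform(0.5, 3), int(rng.integers(5, 40)))
            stat, p = es.fligner_test(g1, g2)
            sstat, sp = scipy_fligner(g1, g2)
            assert stat == pytest.approx(sstat, rel=1e-9)
            assert p == pytest.approx(sp, rel=1e-9)

    def test_permutation_oracle_agreement(self):
        rng = np.random.default_rng(8)
        g1 = rng.normal(0, 1, 25)
        g2 = rng.normal(0, 1.8, 25)
        stat, p = es.fligner_test(g1, g2)
        pooled = np.concatenate([g1, g2])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s, _ = es.fligner_test(perm[:25], perm[25:])
            count += s >= stat
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(0.02, mc_err + 0.01)

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            es.fligner_test([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# enrichment tables
# ---------------------------------------------------------------------------


class TestBuildTables:
    def _calls(self):
        return pd.DataFrame(
            [
                # v1 discordant with one discordant + one concordant pair
                {"variant_id": "v1", "met_a": "a", "met_b": "b", "pair_class": "discordant", "variant_class": "discordant"},
                {"variant_id": "v1", "met_a": "a", "met_b": "c", "pair_class": "concordant", "variant_class": "discordant"},
                {"variant_id": "v2", "met_a": "a", "met_b": "b", "pair_class": "concordant", "variant_class": "concordant"},
                {"variant_id": "v3", "met_a": ".", "met_b": ".", "pair_class": ".", "variant_class": "neither"},
                {"variant_id": "v4", "met_a": "b", "met_b": "c", "pair_class": "concordant", "variant_class": "concordant"},
            ]
        )

    def _annotations(self):
        return pd.DataFrame(
            [
                {"variant_id": "v1", "gene_id": "E1", "gene_type": "enzyme"},
                {"variant_id": "v2", "gene_id": "T1", "gene_type": "transporter"},
                {"variant_id": "v3", "gene_id": "G1", "gene_type": "general"},
                {"variant_id": "v4", "gene_id": "G2", "gene_type": "general"},
            ]
        )

    def test_gene_type_table_hand_counted(self):
        tables = es.build_enrichment_tables(self._calls(), self._annotations())
        assert tables["gene_type"].tolist() == [[1, 0], [1, 1]]

    def test_row_sums_equal_class_counts(self):
        calls = self._calls()
        tables = es.build_enrichment_tables(calls, self._annotations())
        per_variant = calls[calls["variant_class"] != "neither"].groupby("variant_id")[
            "variant_class"
        ].first()
        assert tables["gene_type"][0].sum() == (per_variant == "discordant").sum()
        assert tables["gene_type"][1].sum() == (per_variant == "concordant").sum()

    def test_between_table_defining_pairs(self):
        between = pd.DataFrame(
            [
                {"gene_id": "E1", "met_a": "a", "met_b": "b", "label": "between"},
                {"gene_id": "E1", "met_a": "a", "met_b": "c", "label": "upstream"},
            ]
        )
        tables = es.build_enrichment_tables(self._calls(), self._annotations(), between)
        # v1 is the only enzyme variant; its defining (discordant) pair is
        # (a, b), labelled between
        assert tables["between"].tolist() == [[1, 0], [0, 0]]

    def test_no_discordant_fisher_p_one(self):
        calls = self._calls()
        calls.loc[calls["variant_class"] == "discordant", "variant_class"] = "concordant"
        calls.loc[calls["pair_class"] == "discordant", "pair_class"] = "concordant"
        tables = es.build_enrichment_tables(calls, self._annotations())
        res = es.fisher_exact(*tables["gene_type"].ravel())
        assert res.p == 1.0
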