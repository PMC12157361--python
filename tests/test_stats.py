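import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from circlescan import stats as cs


def table_to_xy(a, b, c, d):
    """2x2 [[a,b],[c,d]]: rows are x=1/x=0, columns outcome 1/0."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x, y


class TestLogistic:
    def test_saturated_2x2_or_equals_cross_product(self):
        x, y = table_to_xy(10, 5, 2, 8)
        res = cs.fit_logistic(x, y)
        assert res[0].odds_ratio == pytest.approx(8.0, rel=1e-6)

    def test_independent_covariate_gives_or_one(self):
        x, y = table_to_xy(10, 10, 10, 10)
        res = cs.fit_logistic(x, y)
        assert res[0].odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_matches_generic_optimizer_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 60
            X = rng.normal(size=(n, 2))
            beta_true = np.array([0.3, -0.5, 0.8])
            eta = beta_true[0] + X @ beta_true[1:]
            y = (rng.random(n) < expit(eta)).astype(float)
            res = cs.fit_logistic(X, y)

            def nll(beta):
                e = beta[0] + X @ beta[1:]
                return -np.sum(y * e - np.logaddexp(0, e))

            opt = minimize(nll, np.zeros(3), method="BFGS")
            np.testing.assert_allclose(
                [r.log_odds for r in res], opt.x[1:], atol=1e-5
            )

    def test_constant_column_rejected(self):
        x = np.ones(20)
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError, match="constant"):
            cs.fit_logistic(x, y)

    def test_separated_data_raises_advising_firth(self):
        x, y = table_to_xy(10, 0, 0, 10)
        with pytest.raises(cs.SeparationError, match="[Ff]irth"):
            cs.fit_logistic(x, y)


class TestFirth:
    def test_2x2_equals_half_cell_corrected_cross_product(self):
        x, y = table_to_xy(10, 5, 2, 8)
        res = cs.fit_firth_logistic(x, y)
        expected = (10.5 * 8.5) / (5.5 * 2.5)
        assert res[0].odds_ratio == pytest.approx(expected, rel=1e-6)

    def test_finite_on_completely_separated_table(self):
        x, y = table_to_xy(10, 0, 0, 10)
        res = cs.fit_firth_logistic(x, y)
        assert math.isfinite(res[0].log_odds)
        expected = (10.5 * 10.5) / (0.5 * 0.5)
        assert res[0].odds_ratio == pytest.approx(expected, rel=1e-6)

    def test_penalty_vanishes_at_large_n(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(-0.3 + 0.9 * x)).astype(float)
        mle = cs.fit_logistic(x, y)[0].log_odds
        firth = cs.fit_firth_logistic(x, y, profile_ci=False)[0].log_odds
        assert firth == pytest.approx(mle, rel=0.01)

    def test_profile_ci_brackets_estimate_and_covers_null_behaviour(self):
        x, y = table_to_xy(10, 5, 2, 8)
        res = cs.fit_firth_logistic(x, y)[0]
        lo, hi = np.log(res.ci95[0]), np.log(res.ci95[1])
        assert lo < res.log_odds < hi

    def test_singular_design_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(np.linalg.LinAlgError):
            cs.fit_firth_logistic(X, y, add_intercept=True)


class TestBHFDR:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            cs.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cs.bh_fdr([0.37]), [0.37])

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(cs.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_order_invariance_and_dominance(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = cs.bh_fdr(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(cs.bh_fdr(p[perm]), q[perm])
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_fdr([0.5, 1.2])


class TestMannWhitney:
    def test_fully_shifted_small_samples_exact(self):
        u, p = cs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_symmetry_under_swap(self):
        x, y = [1.0, 3.0, 5.0, 9.0], [2.0, 4.0, 8.0]
        _, p1 = cs.mann_whitney(x, y)
        _, p2 = cs.mann_whitney(y, x)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_on_large_samples(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        u, p = cs.mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(cs.mann_whitney(x, y)[1])
        assert 0.3 < np.mean(np.array(ps) < 0.5) < 0.7

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.mann_whitney([], [1.0])


class TestOr2x2:
    def test_printed_count_example(self):
        odds, p = cs.or_2x2(31, 84, 4, 56)
        assert odds == pytest.approx(1736 / 336)
        assert p < 0.05

    def test_balanced_table_null(self):
        odds, p = cs.or_2x2(10, 10, 10, 10)
        assert odds == 1.0 and p == pytest.approx(1.0)

    def test_zero_cell_gets_half_correction(self):
        odds, _ = cs.or_2x2(10, 0, 0, 10)
        assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_exact_p_matches_brute_force_hypergeometric(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            a, b, c, d = (int(v) for v in rng.integers(0, 13, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = cs.or_2x2(a, b, c, d)
            # enumerate all tables with the same margins
            r1, r2, c1 = a + b, c + d, a + c
            probs = {}
            for k in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs[k] = (
                    math.comb(r1, k) * math.comb(r2, c1 - k)
                    / math.comb(r1 + r2, c1)
                )
            p_obs = probs[a]
            brute = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(brute, rel=1e-7)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cs.or_2x2(0, 0, 0, 0)


class TestCox:
    def _toy(self):
        # two groups, distinct event times (no ties)
        return pd.DataFrame(
            {
                "time": [1.0, 2.5, 3.1, 4.7, 5.2, 6.9, 8.0, 9.4],
                "event": [1, 1, 0, 1, 1, 1, 0, 1],
                "x": [1, 0, 1, 0, 1, 0, 1, 0],
            }
        )

    def test_matches_brute_force_partial_likelihood(self):
        df = self._toy()
        res = cs.fit_cox(df, ["x"])[0]

        times = df["time"].to_numpy()
        events = df["event"].to_numpy()
        x = df["x"].to_numpy(dtype=float)

        def neg_pl(beta):
            ll = 0.0
            for i in np.where(events == 1)[0]:
                risk = times >= times[i]
                ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-3, 3, 60001)
        beta_hat = grid[np.argmin([neg_pl(b) for b in grid])]
        assert math.log(res.hazard_ratio) == pytest.approx(beta_hat, abs=1e-4)

    def test_rank_invariance_under_time_scaling(self):
        df = self._toy()
        hr1 = cs.fit_cox(df, ["x"])[0].hazard_ratio
        df2 = df.assign(time=df["time"] * 2.0)
        hr2 = cs.fit_cox(df2, ["x"])[0].hazard_ratio
        assert hr1 == pytest.approx(hr2, rel=1e-9)

    def test_null_covariate_mean_hr_near_one(self):
        rng = np.random.default_rng(6)
        hrs = []
        for _ in range(10):
            n = 500
            df = pd.DataFrame(
                {
                    "time": rng.exponential(10, n),
                    "event": np.ones(n, dtype=int),
                    "x": (rng.random(n) < 0.5).astype(float),
                }
            )
            hrs.append(cs.fit_cox(df, ["x"])[0].hazard_ratio)
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.1)

    def test_no_events_rejected(self):
        df = self._toy().assign(event=0)
        with pytest.raises(ValueError):
            cs.fit_cox(df, ["x"])


class TestEncodings:
    def test_amplification_reference_level(self):
        s = pd.Series(["ecdna", "other_focal", "none", "ecdna"])
        enc = cs.encode_amplification(s)
        assert list(enc.columns) == ["amp_ecdna", "amp_none"]
        assert enc["amp_ecdna"].tolist() == [1.0, 0.0, 0.0, 1.0]

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            cs.encode_amplification(pd.Series(["ecdna", "weird"]))

    def test_rare_feature_encoded_present_absent(self):
        s = pd.Series([0.0] * 8 + [3.0, 5.0], name="sig")
        enc = cs.encode_feature(s)
        assert enc.tolist() == [0.0] * 8 + [1.0, 1.0]

    def test_prevalent_feature_encoded_by_median(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], name="sig")
        enc = cs.encode_feature(s)
        assert enc.tolist() == [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]


class TestAssociationSuite:
    def _cohort(self, n=800, seed=7):
        rng = np.random.default_rng(seed)
        wgd = (rng.random(n) < 0.4).astype(float)
        p = expit(-2.2 + math.log(4.0) * wgd)
        return pd.DataFrame(
            {
                "is_wgd": wgd,
                "age": rng.normal(65, 10, n),
                "ecdna": (rng.random(n) < p).astype(float),
                "null_feature": rng.random(n),
            }
        )

    MODELS = [
        {
            "name": "features",
            "outcome": "ecdna",
            "terms": [
                {"col": "is_wgd", "encode": "binary"},
                {"col": "age", "encode": "continuous"},
            ],
        }
    ]

    def test_recovers_injected_or_and_orders_q(self):
        table = cs.run_association_suite(self._cohort(), self.MODELS)
        wgd_row = table[table["term"] == "is_wgd"].iloc[0]
        assert 2.5 < wgd_row["odds_ratio"] < 6.5
        assert np.all(table["q"] >= table["p"] - 1e-12)

    def test_permuting_samples_leaves_results_unchanged(self):
        cohort = self._cohort()
        t1 = cs.run_association_suite(cohort, self.MODELS)
        t2 = cs.run_association_suite(
            cohort.sample(frac=1.0, random_state=0), self.MODELS
        )
        np.testing.assert_allclose(t1["odds_ratio"], t2["odds_ratio"], rtol=1e-9)

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="nope"):
            cs.run_association_suite(
                self._cohort(),
                [{"name": "m", "outcome": "ecdna", "terms": [{"col": "nope"}]}],
            )

    def test_firth_method_dispatch(self):
        table = cs.run_association_suite(
            self._cohort(),
            [dict(self.MODELS[0], method="firth")],
        )
        assert len(table) == 2 and np.isfinite(table["odds_ratio"]).all()
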