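"""Chained-equations engine: samplers against brute-force oracles, fill
distribution, trace bookkeeping, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from mipcr import (
    UnivariateModelSpec,
    draw_bayes_norm,
    draw_pmm,
    initial_fill,
    run_mice,
)
from mipcr.engine import raw_builder

from conftest import make_small_incomplete


def brute_force_bayes_norm(y_obs, X_obs, X_mis, ridge, rng):
    """Literal transcription of the posterior-draw formulas, kept free of the
    production code path (explicit inverse instead of Cholesky solves) but
    consuming the rng stream in the same order."""
    n_obs, q = X_obs.shape
    s = X_obs.T @ X_obs + ridge * np.eye(q)
    beta_hat = np.linalg.inv(s) @ X_obs.T @ y_obs
    ssr = float((y_obs - X_obs @ beta_hat) @ (y_obs - X_obs @ beta_hat))
    sigma2 = ssr / rng.chisquare(max(n_obs - q, 1))
    z = rng.standard_normal(q)
    chol = np.linalg.cholesky(s)
    beta_draw = beta_hat + np.sqrt(sigma2) * np.linalg.inv(chol.T) @ z
    return X_mis @ beta_draw + rng.standard_normal(X_mis.shape[0]) * np.sqrt(sigma2)


class TestInitialFill:
    def test_fills_from_observed_support(self, small_incomplete):
        state = initial_fill(small_incomplete, seed=0)
        col = small_incomplete.values.columns[0]
        mis = small_incomplete.values[col].isna().to_numpy()
        observed = set(small_incomplete.values[col].dropna())
        assert set(state.filled[mis, 0]) <= observed
        assert not np.isnan(state.filled).any()

    def test_complete_data_unchanged(self, small_incomplete):
        complete = make_small_incomplete(miss_cols=(), seed=1)
        state = initial_fill(complete, seed=0)
        assert np.array_equal(state.filled, complete.values.to_numpy())

    def test_fill_frequencies_match_observed(self):
        """Over many draws, fill frequencies track the empirical observed
        distribution (exact multinomial oracle)."""
        inc = make_small_incomplete(n=40, miss_cols=(0,), prop=0.5, seed=3)
        col = inc.values.columns[0]
        obs = inc.values[col].dropna().to_numpy()
        n_mis = int(inc.values[col].isna().sum())
        counts = {v: 0 for v in obs}
        reps = 2000
        rng_seeds = range(reps)
        for s in rng_seeds:
            state = initial_fill(inc, seed=s)
            for v in state.filled[inc.values[col].isna().to_numpy(), 0]:
                counts[v] += 1
        freqs = np.array([counts[v] for v in obs]) / (reps * n_mis)
        # each observed value should be drawn ~uniformly (1/len(obs) each)
        assert np.abs(freqs - 1 / len(obs)).max() < 4 * np.sqrt(
            (1 / len(obs)) * (1 - 1 / len(obs)) / (reps * n_mis)
        )

    def test_fully_missing_column_rejected(self, small_incomplete):
        small_incomplete.values.iloc[:, 1] = np.nan
        with pytest.raises(ValueError):
            initial_fill(small_incomplete, seed=0)


class TestBayesNorm:
    def test_zero_noise_limit_recovers_exact_line(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = X @ np.array([2.0, -1.5])  # no noise: SSR = 0
        Xm = np.column_stack([np.ones(5), np.linspace(-2, 2, 5)])
        imp = draw_bayes_norm(y, X, Xm, ridge=0.0, rng=np.random.default_rng(1))
        assert np.allclose(imp, Xm @ np.array([2.0, -1.5]), atol=1e-8)

    def test_intercept_only_posterior_predictive(self):
        """Large-n intercept-only imputations reproduce the data's mean and
        variance (Monte Carlo check against the closed-form limit)."""
        rng = np.random.default_rng(2)
        y = rng.normal(3.0, 2.0, size=10_000)
        X = np.ones((10_000, 1))
        Xm = np.ones((20_000, 1))
        imp = draw_bayes_norm(y, X, Xm, ridge=0.0, rng=np.random.default_rng(3))
        assert imp.mean() == pytest.approx(3.0, abs=0.1)
        assert imp.std(ddof=1) == pytest.approx(2.0, rel=0.05)

    def test_matches_brute_force_on_same_stream(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(60), rng.standard_normal((60, 3))])
        y = X @ rng.standard_normal(4) + rng.standard_normal(60)
        Xm = np.column_stack([np.ones(10), rng.standard_normal((10, 3))])
        got = draw_bayes_norm(y, X, Xm, ridge=1e-8, rng=np.random.default_rng(7))
        want = brute_force_bayes_norm(y, X, Xm, 1e-8, np.random.default_rng(7))
        assert np.allclose(got, want, atol=1e-8)

    def test_singular_design_needs_ridge(self):
        X = np.ones((20, 2))  # duplicated intercept: singular
        y = np.arange(20.0)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            draw_bayes_norm(y, X, X[:2], ridge=0.0, rng=np.random.default_rng(0))
        draw_bayes_norm(y, X, X[:2], ridge=1e-5, rng=np.random.default_rng(0))


class TestPmm:
    def test_exact_match_single_donor_zero_noise(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        y = X @ np.array([1.0, 2.0])
        Xm = X[[4]]
        imp = draw_pmm(y, X, Xm, ridge=0.0, donors=1, rng=np.random.default_rng(0))
        assert imp[0] == y[4]

    def test_support_containment_and_skew(self):
        """PMM imputations are always observed values, so they respect the
        support of a skewed target (unlike the normal sampler)."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = np.exp(1.0 + 0.8 * x + 0.3 * rng.standard_normal(200))  # y > 0
        X = np.column_stack([np.ones(200), x])
        Xm = np.column_stack([np.ones(50), rng.standard_normal(50)])
        imp = draw_pmm(y, X, Xm, donors=5, rng=np.random.default_rng(6))
        assert set(imp) <= set(y)
        assert imp.min() > 0

    def test_donor_pool_validation(self):
        X = np.ones((5, 1))
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            draw_pmm(y, X, X, donors=6, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            draw_pmm(y, X, X, donors=0, rng=np.random.default_rng(0))


class TestRunMice:
    def _specs(self, inc, method="bayes-norm"):
        cols = list(inc.values.columns)
        return [
            UnivariateModelSpec(
                target=t,
                builder=raw_builder([i for i, c in enumerate(cols) if c != t]),
                method=method,
            )
            for t in cols
            if inc.values[t].isna().any()
        ]

    def test_complete_data_round_trip(self):
        complete = make_small_incomplete(miss_cols=(), seed=1)
        res = run_mice(complete, [], m=3, maxit=2, seed=0)
        assert len(res.completed) == 3
        assert res.traces.empty
        for c in res.completed:
            assert c.equals(complete.values)

    def test_trace_shape_and_observed_immutability(self):
        inc = make_small_incomplete(miss_cols=(0, 2), seed=2)
        res = run_mice(inc, self._specs(inc), m=4, maxit=6, seed=1)
        assert len(res.traces) == 4 * 2 * 6  # m x targets x maxit
        obs_mask = inc.values.notna()
        for comp in res.completed:
            assert not comp.isna().any().any()
            pd.testing.assert_frame_equal(
                comp.where(obs_mask), inc.values.where(obs_mask)
            )

    def test_seed_exact_reproducibility(self):
        inc = make_small_incomplete(miss_cols=(0, 1), seed=4)
        a = run_mice(inc, self._specs(inc), m=2, maxit=3, seed=9)
        b = run_mice(inc, self._specs(inc), m=2, maxit=3, seed=9)
        for x, y in zip(a.completed, b.completed):
            assert x.equals(y)
        assert a.traces.equals(b.traces)

    def test_pmm_imputations_stay_in_observed_support(self):
        inc = make_small_incomplete(miss_cols=(0,), seed=5)
        res = run_mice(inc, self._specs(inc, "pmm"), m=2, maxit=4, seed=2)
        col = inc.values.columns[0]
        mis = inc.values[col].isna()
        observed = set(inc.values[col].dropna())
        for comp in res.completed:
            assert set(comp.loc[mis, col]) <= observed

    def test_unknown_target_rejected(self, small_incomplete):
        bad = [UnivariateModelSpec(target="nope", builder=raw_builder([1]))]
        with pytest.raises(ValueError):
            run_mice(small_incomplete, bad, m=1, maxit=1, seed=0)
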