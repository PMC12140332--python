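"""Batch Bayesian optimizer: acquisition math, surrogate, loop contracts."""

import numpy as np
import pytest
from scipy.stats import norm

from softinverse import bayesopt as bo


class TestSearchSpace:
    def test_encode_decode_round_trip(self, rng):
        space = bo.SearchSpace(
            [
                bo.Dimension("E", 1e2, 1e10, "log10"),
                bo.Dimension("C", 0.0, 50.0),
            ]
        )
        u = rng.random((40, 2))
        assert np.allclose(space.encode(space.decode(u)), u, atol=1e-12)
        assert space.decode(np.array([0.5, 0.5])) == pytest.approx([1e6, 25.0])

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            bo.Dimension("x", 1.0, 0.0)
        with pytest.raises(ValueError):
            bo.Dimension("x", -1.0, 1.0, "log10")


class TestAcquisition:
    def test_reduces_to_probability_of_improvement_at_t0(self, rng):
        """At t = 0 the MGF criterion is exactly Phi((L_min - mean)/sd)."""
        for _ in range(100):
            mean = rng.normal(0, 2)
            sd = rng.uniform(0.01, 3)
            lmin = rng.normal(0, 2)
            got = bo.mgf_acquisition(
                bo.SurrogatePrediction(np.array([mean]), np.array([sd**2])), lmin, 0.0
            )[0]
            assert got == pytest.approx(norm.cdf((lmin - mean) / sd), rel=1e-12)

    def test_closed_form_example(self):
        got = bo.mgf_acquisition(
            bo.SurrogatePrediction(np.array([1.0]), np.array([1.0])), 1.0, 1.0
        )[0]
        assert got == pytest.approx(norm.cdf(1.0) * np.exp(-0.5), rel=1e-12)

    def test_vanishing_uncertainty_no_improvement(self):
        got = bo.mgf_acquisition(
            bo.SurrogatePrediction(np.array([2.0]), np.array([0.0])), 1.0, 0.5
        )[0]
        assert got == 0.0

    def test_temperature_rewards_uncertainty(self):
        lo = bo.log_mgf_acquisition(1.0, 0.1, 0.0, 2.0)
        hi = bo.log_mgf_acquisition(1.0, 1.0, 0.0, 2.0)
        assert hi > lo


class TestTemperature:
    def test_lognormal_moments(self):
        t = bo.sample_temperature(np.random.default_rng(7), size=100_000)
        assert (t > 0).all()
        assert np.median(t) == pytest.approx(1.0, rel=0.02)
        assert t.mean() == pytest.approx(np.exp(0.5), rel=0.02)


class TestSurrogate:
    def test_constant_targets(self):
        X = np.random.default_rng(0).random((12, 2))
        s = bo.ForestSurrogate(seed=0).fit(X, np.full(12, 3.5))
        pred = s.predict(np.random.default_rng(1).random((5, 2)))
        assert np.allclose(pred.mean, 3.5)
        assert np.allclose(pred.variance, 0.0)

    def test_variance_grows_away_from_data(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 1)) * 0.3  # clustered on the left
        y = np.sin(10 * X[:, 0])
        s = bo.ForestSurrogate(seed=0).fit(X, y)
        near = s.predict(np.array([[0.15]])).variance[0]
        far = s.predict(np.array([[0.95]])).variance[0]
        assert far >= near

    def test_insufficient_data(self):
        with pytest.raises(bo.InsufficientDataError):
            bo.ForestSurrogate(seed=0).fit(np.array([[0.5]]), np.array([1.0]))

    def test_refit_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 2))
        y = X.sum(axis=1)
        q = rng.random((10, 2))
        p1 = bo.ForestSurrogate(seed=5).fit(X, y).predict(q)
        p2 = bo.ForestSurrogate(seed=5).fit(X, y).predict(q)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.variance, p2.variance)


class _StubSurrogate:
    """Deterministic surrogate with a unique acquisition maximum at x = 0.7."""

    def predict(self, X):
        X = np.atleast_2d(X)
        mean = (X[:, 0] - 0.7) ** 2
        return bo.SurrogatePrediction(mean=mean, variance=np.full(len(X), 1e-4))


class TestProposeBatch:
    def test_finds_stub_maximum(self):
        space = bo.SearchSpace([bo.Dimension("x", 0.0, 1.0)])
        best, t = bo.propose_batch(
            _StubSurrogate(), space, 1, loss_min=0.0,
            rng=np.random.default_rng(0), temperatures=[0.0],
        )
        assert abs(best[0, 0] - 0.7) < 0.02

    def test_batch_contracts(self):
        space = bo.SearchSpace([bo.Dimension("x", 0.0, 1.0), bo.Dimension("y", 0.0, 1.0)])
        best, t = bo.propose_batch(
            _StubSurrogate(), space, 8, loss_min=0.0, rng=np.random.default_rng(1)
        )
        assert best.shape == (8, 2)
        assert (best >= 0).all() and (best <= 1).all()
        assert t.shape == (8,)

    def test_seeded_batches_identical(self):
        space = bo.SearchSpace([bo.Dimension("x", 0.0, 1.0)])
        b1, t1 = bo.propose_batch(
            _StubSurrogate(), space, 4, 0.0, np.random.default_rng(9)
        )
        b2, t2 = bo.propose_batch(
            _StubSurrogate(), space, 4, 0.0, np.random.default_rng(9)
        )
        assert np.array_equal(b1, b2) and np.array_equal(t1, t2)


class TestOptimize:
    SPACE = bo.SearchSpace([bo.Dimension("x", 0.0, 10.0)])

    def test_quadratic_minimum(self):
        """Finds |x - 3| <= 0.1 within a budget of 60 (full ten-seed sweep
        runs with the benchmark acceptance suite)."""
        best, _ = bo.optimize(
            lambda p: (p["x"] - 3.0) ** 2,
            self.SPACE,
            bo.OptimizerConfig(batch_size=4, budget=60, seed=0),
        )
        assert abs(best.values[0] - 3.0) <= 0.1

    def test_log_encoded_analytic_minimum(self):
        space = bo.SearchSpace([bo.Dimension("x", 1e2, 1e10, "log10")])
        best, _ = bo.optimize(
            lambda p: (np.log10(p["x"]) - 5.0) ** 2,
            space,
            bo.OptimizerConfig(batch_size=4, budget=60, seed=1),
        )
        assert 10**4.9 <= best.values[0] <= 10**5.1

    def test_budget_equal_to_initial_design(self):
        best, hist = bo.optimize(
            lambda p: (p["x"] - 3.0) ** 2,
            self.SPACE,
            bo.OptimizerConfig(batch_size=4, budget=4, n_initial=4, seed=0),
        )
        assert len(hist.losses) == 4
        assert np.isnan(hist.temperatures).all()

    def test_best_so_far_non_increasing_and_deterministic(self):
        cfg = bo.OptimizerConfig(batch_size=4, budget=40, seed=11)
        _, h1 = bo.optimize(lambda p: (p["x"] - 3.0) ** 2, self.SPACE, cfg)
        _, h2 = bo.optimize(lambda p: (p["x"] - 3.0) ** 2, self.SPACE, cfg)
        assert np.array_equal(h1.losses, h2.losses)
        assert (np.diff(h1.best_so_far) <= 0).all()

    def test_failing_objective_recorded_as_inf(self):
        def bad(p):
            if p["x"] > 5:
                raise RuntimeError("solver blew up")
            return (p["x"] - 3.0) ** 2

        with pytest.warns(UserWarning, match="objective failed"):
            best, hist = bo.optimize(
                bad, self.SPACE, bo.OptimizerConfig(batch_size=4, budget=30, seed=4)
            )
        assert np.isinf(hist.losses).any()
        assert best.values[0] <= 5.0

    def test_parallel_matches_sequential(self):
        cfg_seq = bo.OptimizerConfig(batch_size=4, budget=28, seed=2, n_jobs=1)
        cfg_par = bo.OptimizerConfig(batch_size=4, budget=28, seed=2, n_jobs=2)
        _, h1 = bo.optimize(lambda p: (p["x"] - 3.0) ** 2, self.SPACE, cfg_seq)
        _, h2 = bo.optimize(lambda p: (p["x"] - 3.0) ** 2, self.SPACE, cfg_par)
        assert np.array_equal(h1.losses, h2.losses)
        assert np.array_equal(h1.X, h2.X)

    def test_fixed_temperature_mode(self):
        cfg = bo.OptimizerConfig(batch_size=3, budget=20, seed=0, t_mode="fixed", t_fixed=2.0)
        _, hist = bo.optimize(lambda p: (p["x"] - 3.0) ** 2, self.SPACE, cfg)
        recorded = hist.temperatures[~np.isnan(hist.temperatures)]
        assert (recorded == 2.0).all()
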