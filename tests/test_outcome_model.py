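"""Posterior model checks against conjugate closed forms and a Gibbs oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from castsim import (
    ARMS,
    ArmPrior,
    OutcomeData,
    fit_baseline_adjusted,
    prob_best,
    prob_margin,
    update_posterior,
)

from conftest import make_data


class TestUpdatePosterior:
    def test_no_data_reproduces_prior(self, prior):
        draws = update_posterior(prior, OutcomeData({}), n_draws=50_000, seed=1)
        for arm in ARMS:
            col = draws.column(arm)
            # prior N(50, 20^2); MC error on the mean ~ 20/sqrt(50k) = 0.09
            assert col.mean() == pytest.approx(50.0, abs=0.3)
            assert col.std() == pytest.approx(20.0, abs=0.3)

    def test_data_overwhelm_prior(self, prior):
        data = OutcomeData({"boot": np.full(400, 60.0) + np.linspace(-1, 1, 400)})
        draws = update_posterior(prior, data, n_draws=20_000, seed=2)
        assert draws.column("boot").mean() == pytest.approx(60.0, abs=0.1)

    def test_known_variance_conjugate_closed_form(self, prior):
        # fix sigma^2 = 400, n = 100, sample mean 55: the posterior of the arm
        # mean is exactly normal with precision 1/20^2 + 100/400
        y = np.full(100, 55.0)
        y[:50] += 2.0
        y[50:] -= 2.0
        draws = update_posterior(
            prior, OutcomeData({"brace": y}), n_draws=100_000, seed=3, sigma2_fixed=400.0
        )
        prec = 1.0 / 400.0 + 100.0 / 400.0
        mean = (50.0 / 400.0 + 100.0 * 55.0 / 400.0) / prec
        var = 1.0 / prec
        col = draws.column("brace")
        se_mean = np.sqrt(var / col.size)
        assert abs(col.mean() - mean) < 3 * se_mean
        assert col.var() == pytest.approx(var, rel=0.05)

    def test_marginal_and_gibbs_routes_agree(self, prior, rng):
        """The i.i.d. marginal sampler and the two-block Gibbs sampler target
        the same posterior; their moments must agree within MC error."""
        data = make_data(rng, (50, 52, 55, 60), (80, 70, 60, 90))
        d1 = update_posterior(prior, data, n_draws=40_000, seed=4, method="marginal")
        d2 = update_posterior(prior, data, n_draws=40_000, seed=5, method="gibbs")
        for arm in ARMS:
            se = d1.column(arm).std() / np.sqrt(40_000)
            assert abs(d1.column(arm).mean() - d2.column(arm).mean()) < 6 * se
            assert d1.column(arm).std() == pytest.approx(d2.column(arm).std(), rel=0.05)
        assert d1.sigma2.mean() == pytest.approx(d2.sigma2.mean(), rel=0.02)

    def test_posterior_mean_converges_to_sample_mean(self, prior, rng):
        y = rng.normal(63.0, 20.0, 5000)
        draws = update_posterior(prior, OutcomeData({"boot": y}), 20_000, seed=6)
        assert draws.column("boot").mean() == pytest.approx(y.mean(), abs=0.15)

    def test_rejects_bad_inputs(self, prior):
        with pytest.raises(ValueError, match="non-finite"):
            OutcomeData({"boot": np.array([50.0, np.nan])})
        with pytest.raises(ValueError, match="n_draws"):
            update_posterior(prior, OutcomeData({}), n_draws=0, seed=0)
        with pytest.raises(ValueError):
            ArmPrior(mean_sd=-1)


class TestProbFunctionals:
    @staticmethod
    def _draws_from_normals(mus, sds, n=200_000, seed=0):
        rng = np.random.default_rng(seed)
        theta = rng.normal(mus, sds, size=(n, len(mus)))
        from castsim import PosteriorDraws

        return PosteriorDraws(theta, np.full(n, 400.0), tuple(ARMS[: len(mus)]))

    def test_single_candidate_is_certain(self):
        d = self._draws_from_normals([50, 51, 52, 53], [2, 2, 2, 2], n=100)
        assert prob_best(d, ["brace"]) == {"brace": 1.0}

    def test_symmetric_posteriors_split_evenly(self):
        d = self._draws_from_normals([50] * 4, [2] * 4, seed=1)
        pb = prob_best(d)
        assert sum(pb.values()) == pytest.approx(1.0)
        for v in pb.values():
            assert v == pytest.approx(0.25, abs=0.005)

    def test_two_arm_closed_form(self):
        # theta1 ~ N(50, 2^2), theta2 ~ N(51, 2^2):
        # Pr(theta2 > theta1) = Phi(1 / sqrt(8)) = 0.6382
        d = self._draws_from_normals([50, 51], [2, 2], seed=2)
        expected = norm.cdf(1 / np.sqrt(8))
        se = np.sqrt(expected * (1 - expected) / 200_000)
        pb = prob_best(d, ["tubular bandage", "boot"])
        assert abs(pb["boot"] - expected) < 3 * se

    def test_margin_closed_form(self):
        # N(60,2^2) vs N(50,2^2), margin 8: Phi(2/sqrt(8)) = 0.7602
        d = self._draws_from_normals([50, 60], [2, 2], seed=3)
        expected = norm.cdf(2 / np.sqrt(8))
        se = np.sqrt(expected * (1 - expected) / 200_000)
        assert abs(prob_margin(d, "boot", "tubular bandage", 8.0) - expected) < 3 * se

    def test_margin_edge_cases(self):
        d = self._draws_from_normals([50, 50], [2, 2], seed=4)
        assert prob_margin(d, "boot", "tubular bandage", 0.0) == pytest.approx(0.5, abs=0.01)
        assert prob_margin(d, "boot", "tubular bandage", np.inf) == 0.0
        with pytest.raises(ValueError):
            prob_margin(d, "boot", "boot", 0.0)
        with pytest.raises(KeyError):
            prob_margin(d, "boot", "nope", 0.0)

    def test_margin_complementarity_and_monotonicity(self):
        d = self._draws_from_normals([50, 53], [3, 3], seed=5)
        a, b = "boot", "tubular bandage"
        assert prob_margin(d, a, b, 0.0) + prob_margin(d, b, a, 0.0) == pytest.approx(1.0)
        margins = [-10, -5, 0, 3, 8, 15, 40]
        probs = [prob_margin(d, a, b, m) for m in margins]
        assert all(p1 >= p2 for p1, p2 in zip(probs, probs[1:]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mus=st.lists(st.floats(30, 70), min_size=4, max_size=4),
        seed=st.integers(0, 2**20),
    )
    def test_prob_best_sums_to_one(self, mus, seed):
        d = self._draws_from_normals(mus, [3] * 4, n=2000, seed=seed)
        assert sum(prob_best(d).values()) == pytest.approx(1.0)


class TestBaselineAdjusted:
    def test_parameter_recovery(self, prior, rng):
        # truth: slope 0.5, arm offsets (0, 10) on two arms, n = 2000
        n = 1000
        b1, b2 = rng.normal(50, 15, n), rng.normal(50, 15, n)
        med = np.median(np.concatenate([b1, b2]))
        y1 = 50 + 0.5 * (b1 - med) + rng.normal(0, 10, n)
        y2 = 60 + 0.5 * (b2 - med) + rng.normal(0, 10, n)
        data = OutcomeData(
            {"tubular bandage": y1, "boot": y2},
            baselines={"tubular bandage": b1, "boot": b2},
        )
        draws = fit_baseline_adjusted(data, prior, n_draws=4000, seed=7)
        assert draws.slope.mean() == pytest.approx(0.5, abs=0.05)
        contrast = (draws.column("boot") - draws.column("tubular bandage")).mean()
        assert contrast == pytest.approx(10.0, abs=0.5)

    def test_null_covariate_matches_unadjusted(self, prior, rng):
        n = 800
        y = {a: rng.normal(m, 20, n) for a, m in zip(ARMS, (50, 50, 55, 60))}
        b = {a: rng.normal(50, 20, n) for a in ARMS}  # independent of outcome
        adj = fit_baseline_adjusted(OutcomeData(y, b), prior, 20_000, seed=8)
        unadj = update_posterior(prior, OutcomeData(y), 20_000, seed=9)
        for arm in ARMS:
            se = unadj.column(arm).std() / np.sqrt(20_000)
            # two independent MC estimates plus slope-estimation noise
            assert abs(adj.column(arm).mean() - unadj.column(arm).mean()) < 8 * se

    def test_constant_baseline_equals_unadjusted(self, prior, rng):
        y = {a: rng.normal(55, 20, 200) for a in ARMS[:2]}
        b = {a: np.full(200, 47.0) for a in ARMS[:2]}
        adj = fit_baseline_adjusted(OutcomeData(y, b), prior, 15_000, seed=10)
        unadj = update_posterior(prior, OutcomeData(y), 15_000, seed=11)
        for arm in ARMS[:2]:
            se = unadj.column(arm).std() / np.sqrt(15_000)
            assert abs(adj.column(arm).mean() - unadj.column(arm).mean()) < 6 * se

    def test_missing_baselines_rejected(self, prior):
        data = OutcomeData({"boot": np.array([50.0, 55.0])})
        with pytest.raises(ValueError, match="update_posterior"):
            fit_baseline_adjusted(data, prior, 10, seed=0)

    def test_fixed_zero_slope_reduces_to_unadjusted(self, prior, rng):
        y = {a: rng.normal(55, 20, 300) for a in ARMS[:2]}
        b = {a: rng.normal(50, 10, 300) for a in ARMS[:2]}
        adj = fit_baseline_adjusted(
            OutcomeData(y, b), prior, 15_000, seed=12, slope_fixed=0.0
        )
        unadj = update_posterior(prior, OutcomeData(y), 15_000, seed=12)
        for arm in ARMS[:2]:
            assert adj.column(arm).mean() == pytest.approx(
                unadj.column(arm).mean(), abs=0.1
            )
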