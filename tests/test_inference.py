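import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from delaydisc import cohort as sc
from delaydisc import inference as inf
from delaydisc import task_engine as te
from delaydisc.errors import ValidationError
from tests.conftest import QUICK_MCMC


class TestHyperbolicValue:
    def test_immediate_reward_undiscounted(self):
        assert inf.hyperbolic_value(200, 0, 0.08) == 200

    def test_hand_computed_value(self):
        assert inf.hyperbolic_value(200, 15, 0.08) == pytest.approx(90.9091, abs=1e-4)

    def test_zero_rate_never_discounts(self):
        for t in (0, 15, 1000):
            assert inf.hyperbolic_value(200, t, 0.0) == 200

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            inf.hyperbolic_value(200, 10, -0.1)


class TestChoiceProbability:
    def test_indifference_gives_half(self):
        assert inf.choice_probability(100, 100, 2.0) == 0.5

    def test_unit_logistic(self):
        assert inf.choice_probability(0, 1, 1.0) == pytest.approx(0.73106, abs=1e-5)

    def test_zero_temperature_is_pure_noise(self):
        assert inf.choice_probability(0, 150, 0.0) == 0.5

    def test_symmetry(self):
        p = inf.choice_probability(10, 20, 0.3)
        q = inf.choice_probability(20, 10, 0.3)
        assert p + q == pytest.approx(1.0)


def _rhat_oracle(chains):
    """Textbook potential-scale-reduction, coded independently."""
    chains = [list(c) for c in chains]
    m = len(chains)
    n = len(chains[0])
    means = [sum(c) / n for c in chains]
    grand = sum(means) / m
    w = sum(sum((x - mu) ** 2 for x in c) / (n - 1) for c, mu in zip(chains, means)) / m
    b = n * sum((mu - grand) ** 2 for mu in means) / (m - 1)
    var_plus = (n - 1) / n * w + b / n
    return (var_plus / w) ** 0.5


class TestGelmanRubin:
    def test_hand_computed_example(self):
        assert inf.gelman_rubin([[1, 2, 3, 4], [2, 3, 4, 5]]) == pytest.approx(1.0247, abs=1e-4)

    def test_identical_chains_give_shrink_below_one(self):
        chains = [[1.0, 2.0, 3.0, 4.0]] * 2
        assert inf.gelman_rubin(chains) == pytest.approx(np.sqrt(3 / 4))

    def test_matches_oracle_on_random_chains(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            chains = rng.normal(size=(rng.integers(2, 5), rng.integers(3, 40)))
            assert inf.gelman_rubin(chains) == pytest.approx(_rhat_oracle(chains), abs=1e-9)

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 5000))
        assert 0.99 <= inf.gelman_rubin(chains) <= 1.05

    def test_errors(self):
        with pytest.raises(ValidationError):
            inf.gelman_rubin([[1, 2, 3]])
        with pytest.raises(ValidationError):
            inf.gelman_rubin([[1, 1], [1, 1]])


def _waic_oracle(ll):
    """Two-pass reference WAIC without overflow protection."""
    ll = np.asarray(ll, dtype=float)
    lppd = float(np.sum(np.log(np.mean(np.exp(ll), axis=0))))
    p = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return {"lppd": lppd, "p_waic": p, "waic": -2 * (lppd - p)}


class TestWaic:
    def test_constant_matrix(self):
        out = inf.waic(np.full((5, 2), -1.0))
        assert out["lppd"] == pytest.approx(-2.0)
        assert out["p_waic"] == pytest.approx(0.0)
        assert out["waic"] == pytest.approx(4.0)

    def test_hand_computed_example(self):
        out = inf.waic(np.log([[0.5], [0.25]]))
        assert out["lppd"] == pytest.approx(-0.98083, abs=1e-5)
        assert out["p_waic"] == pytest.approx(0.24023, abs=1e-5)
        assert out["waic"] == pytest.approx(2.44211, abs=1e-5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            ll = rng.normal(-1, 0.5, size=(rng.integers(2, 30), rng.integers(1, 15)))
            mine = inf.waic(ll)
            ref = _waic_oracle(ll)
            for key in mine:
                assert mine[key] == pytest.approx(ref[key], abs=1e-9)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_duplicating_draws_preserves_lppd(self, seed):
        rng = np.random.default_rng(seed)
        ll = rng.normal(-2, 1, size=(6, 4))
        doubled = np.vstack([ll, ll])
        assert inf.waic(doubled)["lppd"] == pytest.approx(inf.waic(ll)["lppd"], abs=1e-9)

    def test_overflow_safety(self):
        ll = np.array([[-1e4, -2e4], [-1.5e4, -2.5e4]])
        out = inf.waic(ll)
        assert np.isfinite(out["waic"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            inf.waic(np.empty((0, 0)))


def _stub_fit(pointwise):
    pointwise = np.asarray(pointwise, dtype=float)
    return inf.PosteriorFit(
        spec=inf.DiscountModelSpec(),
        mcmc=QUICK_MCMC,
        participants=["p"],
        k_cols=["all"],
        draws={},
        rhat={},
        pointwise_loglik=pointwise,
        waic=inf.waic(pointwise),
        converged=True,
    )


class TestCompareModels:
    def test_large_delta_prefers_lower_waic(self):
        # WAIC pair 2311 vs 3220: delta 909, lower preferred
        a = _stub_fit(np.log(np.full((4, 2), 0.6)))
        b = _stub_fit(np.log(np.full((4, 2), 0.002)))
        cmp_ = inf.compare_models(a, b)
        assert cmp_.delta_waic > 10 and cmp_.preferred == "a"
        assert cmp_.delta_waic == pytest.approx(abs(cmp_.waic_a - cmp_.waic_b))

    def test_small_delta_indistinguishable(self):
        a = _stub_fit(np.log(np.full((4, 2), 0.50)))
        b = _stub_fit(np.log(np.full((4, 2), 0.52)))
        assert inf.compare_models(a, b).preferred == "indistinguishable"

    def test_identical_matrices_give_zero_delta(self):
        ll = np.random.default_rng(0).normal(-1, 0.3, size=(8, 5))
        cmp_ = inf.compare_models(_stub_fit(ll), _stub_fit(ll))
        assert cmp_.delta_waic == 0

    def test_mismatched_observations_rejected(self):
        with pytest.raises(ValidationError):
            inf.compare_models(_stub_fit(np.full((4, 2), -1.0)), _stub_fit(np.full((4, 3), -1.0)))


class TestFitHierarchical:
    def test_fit_converges_and_reports_all_diagnostics(self, small_split_fit, small_direct_data):
        fit = small_split_fit
        n_p = small_direct_data["choices"]["participant_id"].nunique()
        # one rhat per sampled parameter: 2 k + 1 temp per participant, plus
        # hypers (mu_log_k per condition, sigma_log_k, mu/sigma_log_temp)
        assert len(fit.rhat) == 3 * n_p + 5
        assert fit.converged
        assert fit.pointwise_loglik.shape == (
            QUICK_MCMC.n_chains * QUICK_MCMC.n_samples_per_chain,
            len(small_direct_data["choices"]),
        )

    def test_split_fit_recovers_generating_parameters(self, small_split_fit, small_direct_data):
        truth = small_direct_data["truth"].set_index("participant_id")
        mu = small_split_fit.draws["mu_log_k"].reshape(-1, 2).mean(axis=0)
        assert mu[0] == pytest.approx(truth["log_k_immediate"].mean(), abs=0.3)
        assert mu[1] == pytest.approx(truth["log_k_non_immediate"].mean(), abs=0.3)
        k = inf.extract_k_estimates(small_split_fit).pivot(
            index="participant_id", columns="condition", values="k"
        )
        from scipy.stats import spearmanr

        est = np.r_[k["immediate"][truth.index], k["non_immediate"][truth.index]]
        true = np.r_[
            np.exp(truth["log_k_immediate"]), np.exp(truth["log_k_non_immediate"])
        ]
        assert spearmanr(est, true).statistic >= 0.8

    def test_always_ll_participant_shrinks_to_low_k(self, small_direct_data):
        choices = small_direct_data["choices"].copy()
        patient = choices["participant_id"] == "positive_001"
        choices.loc[patient, "choice"] = "LL"
        spec = inf.DiscountModelSpec(k_structure="joint", time_basis="objective")
        fit = inf.fit_hierarchical(choices, spec, QUICK_MCMC)
        k = inf.extract_k_estimates(fit).set_index("participant_id")["k"]
        assert k["positive_001"] < k.mean()

    def test_seeded_fit_is_deterministic(self, small_direct_data):
        choices = small_direct_data["choices"]
        spec = inf.DiscountModelSpec(k_structure="joint")
        mcmc = inf.McmcConfig(n_chains=2, n_samples_per_chain=100, n_warmup=100, seed=5)
        a = inf.fit_hierarchical(choices, spec, mcmc).summary()
        b = inf.fit_hierarchical(choices, spec, mcmc).summary()
        pd.testing.assert_frame_equal(a, b)

    def test_subjective_basis_requires_complete_perception(self, small_direct_data):
        spec = inf.DiscountModelSpec(k_structure="split_by_condition", time_basis="subjective")
        with pytest.raises(ValidationError):
            inf.fit_hierarchical(small_direct_data["choices"], spec, QUICK_MCMC)
        partial = pd.DataFrame(
            {"participant_id": ["positive_001"], "condition": ["immediate"], "alpha": [1.0], "beta": [1.0]}
        )
        with pytest.raises(ValidationError):
            inf.fit_hierarchical(small_direct_data["choices"], spec, QUICK_MCMC, partial)


class TestExtractKEstimates:
    def test_structure_by_model(self, small_split_fit, small_direct_data):
        tab = inf.extract_k_estimates(small_split_fit)
        n_p = small_direct_data["choices"]["participant_id"].nunique()
        assert len(tab) == 2 * n_p
        assert set(tab["condition"]) == {"immediate", "non_immediate"}

    def test_joint_fit_refuses_condition_split(self, small_direct_data):
        spec = inf.DiscountModelSpec(k_structure="joint")
        mcmc = inf.McmcConfig(n_chains=2, n_samples_per_chain=50, n_warmup=50, seed=1)
        fit = inf.fit_hierarchical(small_direct_data["choices"], spec, mcmc)
        tab = inf.extract_k_estimates(fit)
        assert (tab.groupby("participant_id").size() == 1).all()
        with pytest.raises(ValidationError):
            inf.extract_k_estimates(fit, by_condition=True)
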