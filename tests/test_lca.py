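import math

import numpy as np
import pandas as pd
import pytest

from obesity_lca.cohort_builder import build_temporal_features
from obesity_lca.lca import (
    PosteriorMatrix,
    _em_single,
    fit_em,
    ic_table_from_values,
    log_likelihood,
    membership_summary,
    percent_reduction,
    sweep_models,
)
from obesity_lca.scenarios import match_permutation, recovery_config
from obesity_lca.synthetic_cohort import generate_cases


def brute_force_ll(y, pi, rho):
    """Plain-arithmetic mixture likelihood, enumerated row by row."""
    total = 0.0
    for row in y:
        mix = 0.0
        for k in range(len(pi)):
            term = pi[k]
            for j, v in enumerate(row):
                term *= rho[k][j] if v else (1.0 - rho[k][j])
            mix += term
        total += math.log(mix)
    return total


class TestLogLikelihood:
    def test_fair_coin_single_indicator(self):
        y = np.array([[0], [1], [1], [0]])
        assert log_likelihood(y, [1.0], [[0.5]]) == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=(6, 3))
        pi = np.array([0.3, 0.7])
        rho = rng.uniform(0.1, 0.9, size=(2, 3))
        assert log_likelihood(y, pi, rho) == pytest.approx(brute_force_ll(y, pi, rho), abs=1e-10)

    def test_additive_over_duplicated_rows(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=(5, 4))
        pi, rho = np.array([0.4, 0.6]), rng.uniform(0.2, 0.8, (2, 4))
        single = log_likelihood(y, pi, rho)
        doubled = log_likelihood(np.vstack([y, y]), pi, rho)
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros((3, 2)), [0.5, 0.5], [[0.1, 0.2, 0.3]] * 2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.array([[0, 2]]), [1.0], [[0.5, 0.5]])


class TestFitEM:
    def test_one_class_closed_form(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=(50, 4))
        model, posterior = fit_em(y, K=1, n_starts=2, seed=0)
        np.testing.assert_allclose(model.pi, [1.0], atol=1e-12)
        np.testing.assert_allclose(
            model.rho[0], np.clip(y.mean(axis=0), 1e-6, 1 - 1e-6), atol=1e-9
        )
        assert (posterior.tau == 1.0).all()

    def test_trace_monotone_every_iteration(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=(200, 6))
        model, _ = fit_em(y, K=3, n_starts=5, seed=1)
        trace = np.array(model.ll_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_reported_likelihood_matches_parameters(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=(150, 5))
        model, _ = fit_em(y, K=2, n_starts=3, seed=2)
        assert log_likelihood(y, model.pi, model.rho) == pytest.approx(
            model.log_likelihood, abs=1e-8
        )

    def test_information_criterion_identities_exact(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=(120, 5))
        for K in (1, 2, 4):
            model, _ = fit_em(y, K=K, n_starts=3, seed=3)
            P = (K - 1) + K * 5
            assert model.n_params == P
            assert model.aic == -2 * model.log_likelihood + 2 * P
            assert model.bic == -2 * model.log_likelihood + P * math.log(120)

    def test_posterior_rows_sum_to_one_and_partition(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, size=(100, 4))
        _, posterior = fit_em(y, K=3, n_starts=3, seed=4)
        np.testing.assert_allclose(posterior.tau.sum(axis=1), 1.0, atol=1e-9)
        sizes = np.bincount(posterior.assigned_class, minlength=3)
        assert sizes.sum() == 100

    def test_classes_ordered_by_descending_weight(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, size=(300, 5))
        model, _ = fit_em(y, K=3, n_starts=5, seed=5)
        assert (np.diff(model.pi) <= 1e-12).all()

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, size=(80, 4)).astype(float)
        pi0 = np.array([0.2, 0.3, 0.5])
        rho0 = rng.uniform(0.2, 0.8, (3, 4))
        perm = [2, 0, 1]
        a = _em_single(y, pi0, rho0, max_iter=200, tol=1e-8)
        b = _em_single(y, pi0[perm], rho0[perm], max_iter=200, tol=1e-8)
        np.testing.assert_allclose(a[0][perm], b[0], atol=1e-9)
        np.testing.assert_allclose(a[1][perm], b[1], atol=1e-9)

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 2), dtype=int), K=3)

    def test_parameter_recovery_two_well_separated_classes(self):
        config = recovery_config(seed=55, n_cases=2000, k=2, n_items=8)
        cases, truth = generate_cases(config)
        fm = build_temporal_features(cases, config.vocabulary)
        model, _ = fit_em(fm, K=2, n_starts=5, seed=6)
        perm = match_permutation(config.item_probs, model.rho)
        assert np.abs(model.pi[list(perm)] - config.mixing_weights).max() <= 0.03
        assert np.abs(model.rho[list(perm)] - config.item_probs).max() <= 0.05


class TestSweep:
    def test_percent_reduction_arithmetic(self):
        assert percent_reduction(402_634, 395_335) == 1.81
        assert percent_reduction(404_015, 397_179) == 1.69

    def test_constant_ic_selects_smallest_k(self):
        table = ic_table_from_values([3, 4, 5], [100.0] * 3, [120.0] * 3)
        assert np.isnan(table["pct_reduction_AIC"].iloc[0])
        assert (table["pct_reduction_AIC"].iloc[1:] == 0).all()
        assert (table["pct_reduction_BIC"].iloc[1:] == 0).all()

    def test_sweep_selects_true_class_count(self):
        config = recovery_config(seed=77, n_cases=1500, k=2, n_items=8)
        cases, _ = generate_cases(config)
        fm = build_temporal_features(cases, config.vocabulary)
        sweep = sweep_models(fm, k_min=1, k_max=3, n_starts=4, seed=7)
        assert sweep.selected_K == 2
        bics = [sweep.models[k].bic for k in sorted(sweep.models)]
        assert sweep.models[sweep.selected_K].bic == min(bics)
        assert list(sweep.ic_table["K"]) == [1, 2, 3]


class TestMembershipSummary:
    def test_one_hot_posteriors(self):
        tau = np.eye(3)[[0, 0, 1, 2, 2, 2]]
        mean, sd, flags = membership_summary(PosteriorMatrix(tau, [f"p{i}" for i in range(6)]))
        np.testing.assert_allclose(np.diag(mean), 100.0)
        np.testing.assert_allclose(mean.to_numpy()[~np.eye(3, dtype=bool)], 0.0)
        np.testing.assert_allclose(sd.to_numpy(), 0.0)
        assert not flags.to_numpy().any()

    def test_hand_built_posterior(self):
        tau = np.array(
            [[0.9, 0.1], [0.7, 0.3], [0.2, 0.8], [0.4, 0.6]]
        )
        mean, sd, flags = membership_summary(PosteriorMatrix(tau, list("abcd")))
        # assigned: a,b -> 0; c,d -> 1
        assert mean.loc[0, 0] == pytest.approx(80.0)
        assert mean.loc[0, 1] == pytest.approx(20.0)
        assert mean.loc[1, 1] == pytest.approx(70.0)
        assert sd.loc[0, 0] == pytest.approx(10.0)
        assert sd.loc[1, 1] == pytest.approx(10.0)
        assert flags.loc[0, 1] and flags.loc[1, 0]

    def test_row_sums_conserve_probability(self):
        rng = np.random.default_rng(15)
        tau = rng.dirichlet(np.ones(4), size=50)
        mean, _, _ = membership_summary(PosteriorMatrix(tau, [str(i) for i in range(50)]))
        sums = mean.dropna(how="all").sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_empty_class_flagged_not_raised(self):
        tau = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1]])
        mean, _, _ = membership_summary(PosteriorMatrix(tau, ["a", "b"]))
        assert mean.loc[1].isna().all() and mean.loc[2].isna().all()
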