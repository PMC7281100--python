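"""Likelihood, priors, Gibbs sampler and the exact enumeration oracle.

The deepest checks pin the collapsed likelihood and the exact posterior
against a brute-force enumeration of the full production matrix Z computed
directly from the generative definitions (tests/oracle.py).
"""

import numpy as np
import pytest

from pathmet import (
    InputError,
    MetabolicModel,
    Parameters,
    UnattainableObservationError,
    exact_posterior,
    gibbs_sample_posterior,
    log_likelihood_w_given_a,
    log_prior_a,
    phi,
)
from pathmet.inference import _GibbsWorkspace, bin_log_probs, exact_state_distribution
from conftest import random_observation, random_small_model
from oracle import brute_likelihood, brute_posterior


def _single_met_model():
    return MetabolicModel.from_masses(["p1"], ["m1"], [100.0], [[1]])


class TestPhi:
    @pytest.mark.parametrize(
        "n,mu,expected", [(0, 0.5, 0.0), (1, 0.5, 0.5), (2, 0.5, 0.75), (3, 0.2, 1 - 0.8**3)]
    )
    def test_values(self, n, mu, expected):
        assert phi(n, mu) == pytest.approx(expected, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            phi(-1, 0.5)

    def test_monotone_in_count_and_mu(self):
        ns = np.arange(0, 12)
        for mu in (0.1, 0.5, 0.9, 1.0):
            vals = phi(ns, mu)
            assert (np.diff(vals) >= 0).all()
        mus = np.linspace(0, 1, 21)
        for n in (1, 2, 5):
            vals = np.array([phi(n, m) for m in mus])
            assert (np.diff(vals) >= -1e-15).all()


class TestLikelihood:
    def test_all_inactive_all_unobserved_is_certain(self, tiny_model):
        w = np.zeros(tiny_model.n_bins, dtype=int)
        a = np.zeros(tiny_model.n_pathways, dtype=int)
        assert log_likelihood_w_given_a(tiny_model, w, a, 0.5, 0.9) == 0.0

    def test_all_inactive_with_observation_is_impossible(self, tiny_model):
        w = np.zeros(tiny_model.n_bins, dtype=int)
        w[0] = 1
        a = np.zeros(tiny_model.n_pathways, dtype=int)
        assert log_likelihood_w_given_a(tiny_model, w, a, 0.5, 0.9) == -np.inf

    def test_single_pathway_single_bin(self):
        model = _single_met_model()
        ll = log_likelihood_w_given_a(model, [1], [1], mu=0.5, gamma=1.0)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_complementarity_per_bin(self):
        """p(w_k=0|a) + p(w_k=1|a) = 1 for every bin and state."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_small_model(rng)
            a = rng.integers(0, 2, model.n_pathways)
            mu, gamma = rng.uniform(0.05, 0.95), rng.uniform(0.1, 1.0)
            log_p0, log_p1 = bin_log_probs(model, a, mu, gamma)
            np.testing.assert_allclose(
                np.exp(log_p0) + np.exp(log_p1), 1.0, atol=1e-12
            )

    def test_matches_brute_force_z_enumeration(self, tiny_model):
        """Collapsed likelihood equals the sum over all production matrices."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.integers(0, 2, 2)
            w = rng.integers(0, 2, tiny_model.n_bins)
            mu, gamma = rng.uniform(0.1, 0.9), rng.uniform(0.2, 1.0)
            expected = brute_likelihood(tiny_model, w, a, mu, gamma)
            got = log_likelihood_w_given_a(tiny_model, w, a, mu, gamma)
            if expected == 0.0:
                assert got == -np.inf
            else:
                assert got == pytest.approx(np.log(expected), abs=1e-10)

    def test_activating_pathway_never_decreases_observation_prob(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            model = random_small_model(rng)
            a = rng.integers(0, 2, model.n_pathways)
            i = int(rng.integers(model.n_pathways))
            a0, a1 = a.copy(), a.copy()
            a0[i], a1[i] = 0, 1
            _, lp1_off = bin_log_probs(model, a0, 0.5, 0.9)
            _, lp1_on = bin_log_probs(model, a1, 0.5, 0.9)
            assert (lp1_on >= lp1_off - 1e-12).all()


class TestPrior:
    def test_fixed_half(self):
        p = Parameters(lambda_mode="fixed", lambda_value=0.5)
        assert log_prior_a([1, 0], p) == pytest.approx(np.log(0.25))

    def test_beta_uniform_single_pathway(self):
        p = Parameters(lambda_mode="beta", alpha=1.0, beta=1.0)
        assert log_prior_a([1], p) == pytest.approx(np.log(0.5))

    def test_degenerate_lambda(self):
        p1 = Parameters(lambda_mode="fixed", lambda_value=1.0)
        assert log_prior_a([1, 1], p1) == 0.0
        assert log_prior_a([1, 0], p1) == -np.inf
        p0 = Parameters(lambda_mode="fixed", lambda_value=0.0)
        assert log_prior_a([0, 0], p0) == 0.0
        assert log_prior_a([1, 0], p0) == -np.inf


class TestExactPosterior:
    def test_forced_single_pathway(self):
        model = _single_met_model()
        p = Parameters(lambda_mode="fixed", lambda_value=0.5, mu=0.5, gamma=1.0)
        assert exact_posterior(model, [1], p)[0] == pytest.approx(1.0, abs=1e-14)

    def test_two_term_bayes_by_hand(self):
        # w=0: p(a=1)p(w=0|a=1) = 0.5*0.5, p(a=0)p(w=0|a=0) = 0.5*1 -> 1/3
        model = _single_met_model()
        p = Parameters(lambda_mode="fixed", lambda_value=0.5, mu=0.5, gamma=1.0)
        assert exact_posterior(model, [0], p)[0] == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("mode", ["fixed", "beta"])
    def test_matches_brute_force(self, tiny_model, mode):
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = rng.integers(0, 2, tiny_model.n_bins)
            # keep w attainable: bin of m4 (only on p2) etc. all bins reachable
            params = Parameters(
                lambda_mode=mode,
                lambda_value=0.4,
                mu=float(rng.uniform(0.2, 0.8)),
                gamma=float(rng.uniform(0.3, 1.0)),
            )
            np.testing.assert_allclose(
                exact_posterior(tiny_model, w, params),
                brute_posterior(tiny_model, w, params),
                atol=1e-10,
            )

    def test_refuses_large_models(self):
        rng = np.random.default_rng(0)
        from pathmet import generate_random_model

        model = generate_random_model(21, 25, 3.0, 0.0, seed=rng)
        with pytest.raises(InputError, match="enumeration"):
            exact_posterior(model, np.zeros(model.n_bins, int), Parameters())

    def test_state_distribution_normalizes(self, tiny_model):
        _, logp = exact_state_distribution(
            tiny_model, np.zeros(tiny_model.n_bins, int), Parameters()
        )
        assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)


class TestGibbs:
    def test_unique_evidence_forces_activity(self, fig1):
        """A bin explainable by a single pathway pins that pathway active."""
        model, w = fig1
        params = Parameters(n_samples=400, n_burn_in=50, seed=2)
        samples = gibbs_sample_posterior(model, w, params)
        i2 = model.pathway_ids.index("pathway_2")
        assert (samples.draws[:, i2] == 1).all()
        assert samples.pathway_posterior[i2] == 1.0

    def test_figure1_ordering(self, fig1):
        model, w = fig1
        params = Parameters(n_samples=1000, n_burn_in=100, seed=4)
        samples = gibbs_sample_posterior(model, w, params)
        p1, p2 = samples.pathway_posterior
        assert p2 >= 0.5
        assert p2 > p1

    def test_seed_determinism(self, fig1):
        model, w = fig1
        params = Parameters(n_samples=300, n_burn_in=50, seed=9)
        s1 = gibbs_sample_posterior(model, w, params)
        s2 = gibbs_sample_posterior(model, w, params)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        np.testing.assert_array_equal(s1.lambda_draws, s2.lambda_draws)

    def test_unattainable_observation_names_bin(self, tiny_model):
        # m4 pathway-less and alone in its bin, then observe that bin
        model = MetabolicModel.from_masses(
            tiny_model.pathway_ids,
            tiny_model.metabolite_ids,
            [100.0, 200.0, 300.0, 400.0],
            np.array([[1, 1, 1, 0], [0, 1, 0, 0]]),
            ppm_tol=15.0,
        )
        k = int(model.bin_of_metabolite[3])
        w = np.zeros(model.n_bins, int)
        w[k] = 1
        with pytest.raises(UnattainableObservationError, match=f"bin {k}"):
            gibbs_sample_posterior(model, w, Parameters(seed=0))

    def test_retained_draw_count_and_posterior_mean(self, fig1):
        model, w = fig1
        params = Parameters(n_samples=250, n_burn_in=100, seed=1)
        s = gibbs_sample_posterior(model, w, params)
        assert s.draws.shape == (150, model.n_pathways)
        np.testing.assert_allclose(s.pathway_posterior, s.draws.mean(axis=0))

    def test_converges_to_exact_posterior(self):
        """Gibbs means agree with 2^I enumeration within 3x the MC error."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            model = random_small_model(rng, max_pathways=6, max_metabolites=20)
            data = random_observation(model, rng)
            params = Parameters(n_samples=4000, n_burn_in=200, seed=int(rng.integers(2**31)))
            samples = gibbs_sample_posterior(model, data.w, params)
            exact = exact_posterior(model, data.w, params)
            tol = 3 * np.maximum(samples.mc_se, 2e-3)
            assert (np.abs(samples.pathway_posterior - exact) <= tol).all()

    def test_incremental_update_matches_full_recomputation(self):
        """The per-pathway conditional uses only affected bins; it must equal
        the difference of full likelihood recomputations exactly."""
        rng = np.random.default_rng(13)
        for _ in range(15):
            model = random_small_model(rng)
            data = random_observation(model, rng)
            ws = _GibbsWorkspace(model, data.w.w)
            a = np.ones(model.n_pathways, dtype=np.int64)
            # random walk through attainable states
            for _ in range(10):
                i = int(rng.integers(model.n_pathways))
                n = model.pathway_count_per_metabolite(a)
                got = ws.conditional_log_odds(n, int(a[i]), i, 0.5, 0.9)
                a1, a0 = a.copy(), a.copy()
                a1[i], a0[i] = 1, 0
                full = log_likelihood_w_given_a(
                    model, data.w.w, a1, 0.5, 0.9
                ) - log_likelihood_w_given_a(model, data.w.w, a0, 0.5, 0.9)
                if np.isfinite(full):
                    assert got == pytest.approx(full, abs=1e-9)
                else:
                    assert got == full
                # move to a random attainable neighbour
                if np.isfinite(
                    log_likelihood_w_given_a(model, data.w.w, a1, 0.5, 0.9)
                ):
                    a = a1 if rng.random() < 0.5 else a

    def test_fixed_lambda_mode_runs_without_lambda_draws(self, fig1):
        model, w = fig1
        s = gibbs_sample_posterior(
            model, w, Parameters(lambda_mode="fixed", n_samples=200, n_burn_in=50, seed=3)
        )
        assert s.lambda_draws is None

    def test_multi_chain_pools_draws(self, fig1):
        model, w = fig1
        s = gibbs_sample_posterior(
            model, w, Parameters(n_samples=200, n_burn_in=100, n_chains=2, seed=3)
        )
        assert s.draws.shape[0] == 200


class TestFigure1Robustness:
    """The pathway ordering on the worked example is robust to mu."""

    @pytest.mark.parametrize("mu", [0.25, 0.5, 0.75])
    def test_ordering_stable_under_mu(self, fig1, mu):
        model, w = fig1
        params = Parameters(lambda_mode="fixed", lambda_value=0.5, mu=mu)
        p1, p2 = exact_posterior(model, w, params)
        assert p2 == pytest.approx(1.0, abs=1e-12)  # unique evidence pins it
        assert p2 > p1
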