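"""Unit and property tests for the Bayesian association engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from sklearn.base import clone

from raretag.model import (
    AssociationPriors,
    RareVariantAssociation,
    log_beta_marginal,
    log_evidence_assoc_exact,
    log_evidence_assoc_sampled,
    log_evidence_given_z,
    log_evidence_null,
    log_prior_z,
    model_posterior,
    moi_posterior,
    overall_bf_and_pp,
    pathogenic_configuration,
    variant_posterior,
)

from .conftest import random_instance
from .oracle import brute_force_log_evidence, brute_force_variant_posterior


class TestBetaMarginal:
    def test_empty_sample_has_unit_evidence(self):
        assert log_beta_marginal(0, 0, 2.5, 7.0) == pytest.approx(0.0)

    def test_uniform_prior_hand_integral(self):
        # 1 case, 2 controls, uniform rate: 1/((n+1) C(n,k)) = 1/12
        assert log_beta_marginal(1, 2, 1, 1) == pytest.approx(np.log(1 / 12))

    @pytest.mark.parametrize("n1,n0,a,b", [(3, 5, 1, 1), (0, 4, 2, 3), (7, 2, 0.5, 9)])
    def test_matches_quadrature(self, n1, n0, a, b):
        integrand = lambda t: t**n1 * (1 - t) ** n0 * beta_dist.pdf(t, a, b)
        val, _ = quad(integrand, 0, 1)
        assert log_beta_marginal(n1, n0, a, b) == pytest.approx(np.log(val), rel=1e-8)

    def test_rejects_nonpositive_hyperparameters(self):
        with pytest.raises(ValueError):
            log_beta_marginal(1, 1, 0.0, 1.0)
        with pytest.raises(ValueError):
            log_beta_marginal(1, -1, 1.0, 1.0)


class TestNullEvidence:
    def test_hand_value_uniform(self, uniform_priors):
        # 2 cases, 2 controls, uniform: B(3,3)/B(1,1) = 1/30
        y = np.array([1, 1, 0, 0], dtype=bool)
        assert log_evidence_null(y, uniform_priors) == pytest.approx(np.log(1 / 30))

    def test_permutation_invariance(self, default_priors):
        rng = np.random.default_rng(0)
        y = rng.random(30) < 0.3
        perm = rng.permutation(30)
        assert log_evidence_null(y, default_priors) == pytest.approx(
            log_evidence_null(y[perm], default_priors)
        )

    def test_all_controls_handled(self, default_priors):
        assert np.isfinite(log_evidence_null(np.zeros(5, dtype=bool), default_priors))

    def test_empty_rejected(self, default_priors):
        with pytest.raises(ValueError):
            log_evidence_null(np.empty(0, dtype=bool), default_priors)


class TestEvidenceGivenZ:
    def test_all_zero_configuration_reduces_to_null(self, default_priors):
        y = np.array([1, 0, 1, 0, 0], dtype=bool)
        x = np.zeros(5, dtype=bool)
        assert log_evidence_given_z(y, x, default_priors) == pytest.approx(
            log_evidence_null(y, default_priors)
        )

    @pytest.mark.parametrize(
        "x,expected",
        [([1, 0, 0, 0], 1 / 24), ([1, 1, 0, 0], 1 / 9)],
    )
    def test_hand_enumeration_uniform(self, uniform_priors, x, expected):
        y = np.array([1, 1, 0, 0], dtype=bool)
        got = log_evidence_given_z(y, np.array(x, dtype=bool), uniform_priors)
        assert got == pytest.approx(np.log(expected))


class TestPriorZ:
    @pytest.mark.parametrize(
        "z,expected", [((0, 0), 1 / 3), ((1, 0), 1 / 6), ((1, 1), 1 / 3)]
    )
    def test_k2_uniform_omega(self, uniform_priors, z, expected):
        assert log_prior_z(np.array(z), 2, uniform_priors) == pytest.approx(
            np.log(expected)
        )

    @given(k=st.integers(1, 8), w_a=st.floats(0.3, 4), w_b=st.floats(0.3, 4))
    @settings(max_examples=30, deadline=None)
    def test_normalises_over_hypercube(self, k, w_a, w_b):
        priors = AssociationPriors(w_a=w_a, w_b=w_b)
        total = 0.0
        for code in range(2**k):
            z = (code >> np.arange(k)) & 1
            total += np.exp(log_prior_z(z, k, priors))
        assert total == pytest.approx(1.0, rel=1e-9)


class TestPathogenicConfiguration:
    G = np.array([[1, 0], [0, 1], [2, 0], [1, 1], [0, 0]])

    def test_dominant_any_selected_allele(self):
        x = pathogenic_configuration(self.G, np.array([1, 0]), "dominant")
        assert x.tolist() == [1, 0, 1, 1, 0]

    def test_recessive_requires_two_alleles(self):
        x = pathogenic_configuration(self.G, np.array([1, 0]), "recessive")
        assert x.tolist() == [0, 0, 1, 0, 0]

    def test_recessive_compound_het_counts(self):
        x = pathogenic_configuration(self.G, np.array([1, 1]), "recessive")
        # subject 3 carries one het at each selected variant
        assert x.tolist() == [0, 0, 1, 1, 0]

    def test_unknown_moi_rejected(self):
        with pytest.raises(ValueError):
            pathogenic_configuration(self.G, np.array([1, 0]), "codominant")

    @given(st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_z_and_recessive_implies_dominant(self, code_a, code_b):
        rng = np.random.default_rng(7)
        G = rng.choice([0, 1, 2], size=(15, 10), p=[0.6, 0.3, 0.1])
        za = (code_a >> np.arange(10)) & 1
        zb = za | ((code_b >> np.arange(10)) & 1)
        for moi in ("dominant", "recessive"):
            xa = pathogenic_configuration(G, za, moi)
            xb = pathogenic_configuration(G, zb, moi)
            assert np.all(xb >= xa)  # adding variants never clears x
        z0 = np.zeros(10, dtype=int)
        assert not pathogenic_configuration(G, z0, "dominant").any()
        xd = pathogenic_configuration(G, za, "dominant")
        xr = pathogenic_configuration(G, za, "recessive")
        assert np.all(xd >= xr)


class TestExactEvidence:
    def test_k0_collapses_to_null(self, default_priors):
        y = np.array([1, 0, 0], dtype=bool)
        got = log_evidence_assoc_exact(y, np.zeros((3, 0)), "dominant", default_priors)
        assert got == pytest.approx(log_evidence_null(y, default_priors))

    def test_worked_four_subject_fixture(self, uniform_priors):
        """Hand enumeration of the 4 z-vectors gives BF = 1.861."""
        y = np.array([1, 1, 0, 0], dtype=bool)
        G = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
        log_ev = log_evidence_assoc_exact(y, G, "dominant", uniform_priors)
        expected = (1 / 3) * (1 / 30) + 2 * (1 / 6) * (1 / 24) + (1 / 3) * (1 / 9)
        assert log_ev == pytest.approx(np.log(expected))
        log_bf = log_ev - log_evidence_null(y, uniform_priors)
        assert np.exp(log_bf) == pytest.approx(1.861, abs=5e-4)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_independent_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        y, G, moi, priors = random_instance(rng, k_max=6, n=20)
        got = log_evidence_assoc_exact(y, G, moi, priors)
        want = brute_force_log_evidence(
            y.tolist(), G.tolist(), moi,
            priors.a0, priors.b0, priors.a1, priors.b1, priors.w_a, priors.w_b,
        )
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_k_above_cap_rejected(self, default_priors):
        G = np.zeros((4, default_priors.k_max_exact + 1), dtype=int)
        with pytest.raises(ValueError, match="k_max_exact"):
            log_evidence_assoc_exact(
                np.array([1, 0, 0, 0], dtype=bool), G, "dominant", default_priors
            )


class TestSampler:
    @pytest.mark.parametrize("seed", range(4))
    def test_within_three_stderr_of_enumeration(self, seed, default_priors):
        rng = np.random.default_rng(100 + seed)
        G = rng.choice([0, 1, 2], size=(40, 12), p=[0.75, 0.2, 0.05])
        y = rng.random(40) < 0.3
        exact = log_evidence_assoc_exact(y, G, "dominant", default_priors)
        est, se, _ = log_evidence_assoc_sampled(
            y, G, "dominant", default_priors, n_steps=800, seed=seed
        )
        assert abs(est - exact) < 3 * max(se, 1e-3)

    def test_seeded_reproducibility(self, default_priors):
        rng = np.random.default_rng(5)
        G = rng.choice([0, 1], size=(30, 8), p=[0.8, 0.2])
        y = rng.random(30) < 0.4
        a = log_evidence_assoc_sampled(y, G, "dominant", default_priors, 300, seed=9)
        b = log_evidence_assoc_sampled(y, G, "dominant", default_priors, 300, seed=9)
        assert a == b

    def test_more_steps_shrink_stderr(self, default_priors):
        rng = np.random.default_rng(6)
        G = rng.choice([0, 1], size=(30, 8), p=[0.8, 0.2])
        y = rng.random(30) < 0.4
        _, se_small, _ = log_evidence_assoc_sampled(
            y, G, "dominant", default_priors, 150, seed=3
        )
        _, se_big, _ = log_evidence_assoc_sampled(
            y, G, "dominant", default_priors, 2400, seed=3
        )
        assert se_big < se_small


class TestPosteriorSummaries:
    def test_unit_bf_returns_prior(self, default_priors):
        _, pp = overall_bf_and_pp({"dominant:high": 0.0}, default_priors)
        assert pp == pytest.approx(default_priors.pi)

    def test_pp_monotone_in_bf(self, default_priors):
        pps = [
            overall_bf_and_pp({"m": lbf}, default_priors)[1]
            for lbf in np.linspace(-5, 25, 12)
        ]
        assert all(0.0 <= p <= 1.0 for p in pps)
        assert np.all(np.diff(pps) > 0)

    def test_model_posterior_uniform_for_equal_bfs(self, default_priors):
        post = model_posterior(
            {"dominant:high": 2.0, "recessive:high": 2.0}, default_priors
        )
        assert post["dominant:high"] == pytest.approx(0.5)

    def test_dominated_model_takes_nearly_all_mass(self, default_priors):
        post = model_posterior(
            {"dominant:high": 12.0, "recessive:high": 2.0}, default_priors
        )
        assert post["dominant:high"] > 0.9999

    def test_single_model_gets_unit_mass(self, default_priors):
        assert moi_posterior({"recessive:pooled": 3.0}, default_priors) == {
            "recessive": pytest.approx(1.0)
        }

    def test_moi_posterior_sums_to_one(self, default_priors):
        post = moi_posterior(
            {"dominant:high": 1.0, "dominant:pooled": 0.5, "recessive:high": -1.0},
            default_priors,
        )
        assert sum(post.values()) == pytest.approx(1.0)


class TestVariantPosterior:
    def test_case_only_variant_rises_above_prior(self, uniform_priors):
        y = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        G = np.array([[1], [1], [1], [0], [0], [0]])
        post = variant_posterior(y, G, "dominant", uniform_priors)
        assert post[0] > 0.5  # prior mean is 1/2 under uniform omega

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(40 + seed)
        y, G, moi, priors = random_instance(rng, k_max=5, n=18)
        got = variant_posterior(y, G, moi, priors)
        want = brute_force_variant_posterior(
            y.tolist(), G.tolist(), moi,
            priors.a0, priors.b0, priors.a1, priors.b1, priors.w_a, priors.w_b,
        )
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_k0_gives_empty(self, default_priors):
        y = np.array([1, 0], dtype=bool)
        assert variant_posterior(y, np.zeros((2, 0)), "dominant", default_priors).size == 0


class TestEstimator:
    def _fit_small(self, **kwargs):
        rng = np.random.default_rng(1)
        X = rng.choice([0, 1], size=(40, 4), p=[0.85, 0.15])
        y = rng.random(40) < 0.3
        impact = np.array(["high", "high", "moderate_deleterious", "moderate_deleterious"])
        return RareVariantAssociation(**kwargs).fit(X, y, impact_class=impact)

    def test_fitted_attributes_and_ranges(self):
        est = self._fit_small()
        assert 0.0 <= est.pp_ <= 1.0
        assert sum(est.moi_posterior_.values()) == pytest.approx(1.0)
        assert set(est.log_bf_per_model_) == {
            "dominant:high", "dominant:moderate_deleterious", "dominant:pooled",
            "recessive:high", "recessive:moderate_deleterious", "recessive:pooled",
        }
        valid = ~np.isnan(est.variant_posteriors_)
        assert ((est.variant_posteriors_[valid] >= 0)
                & (est.variant_posteriors_[valid] <= 1)).all()

    def test_sklearn_clone_roundtrip(self):
        est = RareVariantAssociation(pi=0.01, b0=4.0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_input_validation(self):
        est = RareVariantAssociation()
        with pytest.raises(ValueError):
            est.fit(np.array([[3, 0]]), np.array([1]))
        with pytest.raises(ValueError):
            est.fit(np.zeros((3, 2)), np.zeros(4))

    def test_result_requires_fit(self):
        with pytest.raises(AttributeError):
            RareVariantAssociation().result()

    def test_individual_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.choice([0, 1, 2], size=(30, 3), p=[0.8, 0.15, 0.05])
        y = rng.random(30) < 0.4
        perm = rng.permutation(30)
        a = RareVariantAssociation().fit(X, y)
        b = RareVariantAssociation().fit(X[perm], y[perm])
        assert a.log_bf_ == pytest.approx(b.log_bf_)
        assert a.pp_ == pytest.approx(b.pp_)
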