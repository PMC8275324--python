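"""Unit and property tests for the likelihood model and classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from scdoublet import (
    ErrorModel,
    LocusPriors,
    ReadCounts,
    ado_transition,
    amplification_prob,
    beta_binomial_loglik,
    classify,
    doublet_prior_from_rate,
    doublet_vaf_prior,
    droplet_locus_loglik,
    log_posterior_objective,
    omega_matrix,
    posterior_doublet_prob,
    singlet_vaf_prior,
)
from scdoublet.model import (
    SIGMA_DOUBLET,
    SIGMA_SINGLET,
    THETA_DOUBLET,
    THETA_SINGLET,
    LikelihoodResult,
)

import oracles


class TestDoubletPriorFromRate:
    def test_vanishing_capture_rate(self):
        assert doublet_prior_from_rate(1e-8) < 1e-7

    @pytest.mark.parametrize(
        "lam, expected",
        [(1.0, 1.0 / 3.0), (0.1, 1.0 / 21.0)],
    )
    def test_poisson_arithmetic(self, lam, expected):
        assert doublet_prior_from_rate(lam) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.0, -1.0])
    def test_nonpositive_rate_rejected(self, lam):
        with pytest.raises(ValueError):
            doublet_prior_from_rate(lam)


class TestVafPriors:
    def test_singlet_point_mass_and_uniform(self):
        pri = LocusPriors.global_triple([1, 0, 0], ["L0"])
        assert singlet_vaf_prior(pri, "L0") == {0.0: 1.0, 0.5: 0.0, 1.0: 0.0}
        uni = LocusPriors.global_triple([1 / 3, 1 / 3, 1 / 3], ["L0"])
        dist = singlet_vaf_prior(uni, "L0")
        assert all(p == pytest.approx(1 / 3) for p in dist.values())

    def test_unknown_locus_raises(self, uniform_priors):
        with pytest.raises(KeyError):
            singlet_vaf_prior(uniform_priors(1), "nope")

    def test_doublet_prior_uniform_convolution(self, uniform_priors):
        dist = doublet_vaf_prior(uniform_priors(1), "L000")
        expected = {0.0: 1 / 9, 0.25: 2 / 9, 0.5: 3 / 9, 0.75: 2 / 9, 1.0: 1 / 9}
        for f, p in expected.items():
            assert dist[f] == pytest.approx(p, abs=1e-12)

    def test_doublet_prior_two_wildtype_cells(self):
        pri = LocusPriors.global_triple([1, 0, 0], ["L0"])
        dist = doublet_vaf_prior(pri, "L0")
        assert dist[0.0] == pytest.approx(1.0)

    @given(
        mu_raw=st.tuples(
            st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_half_vaf_mass_counts_ordered_pairs(self, mu_raw):
        # f = 1/2 aggregates (het, het), (hom, wt) and (wt, hom)
        mu = np.asarray(mu_raw) / sum(mu_raw)
        pri = LocusPriors.global_triple(mu, ["L0"])
        dist = doublet_vaf_prior(pri, "L0")
        assert dist[0.5] == pytest.approx(mu[1] ** 2 + 2 * mu[0] * mu[2], rel=1e-9)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)


class TestAdoTransition:
    @pytest.mark.parametrize("z,support", [(0, SIGMA_SINGLET), (1, SIGMA_DOUBLET)])
    def test_no_dropout_is_identity(self, z, support):
        for x in support:
            assert ado_transition(x, z, 0.0) == {x: 1.0}

    def test_het_singlet_closed_form(self):
        # enumerating dropout of (1 var, 1 ref) conditioned on >= 1 retained
        beta = 0.13
        dist = ado_transition(0.5, 0, beta)
        denom = 1 - beta**2
        assert dist[0.5] == pytest.approx((1 - beta) ** 2 / denom, rel=1e-12)
        assert dist[0.0] == pytest.approx(beta * (1 - beta) / denom, rel=1e-12)
        assert dist[1.0] == pytest.approx(beta * (1 - beta) / denom, rel=1e-12)

    def test_doublet_support_union_is_theta(self):
        union = set()
        for x in SIGMA_DOUBLET:
            union |= set(ado_transition(x, 1, 0.3))
        assert union == set(THETA_DOUBLET)

    @pytest.mark.parametrize("z", [0, 1])
    @pytest.mark.parametrize("beta", [0.0, 0.01, 0.05, 0.25, 0.6, 0.95])
    def test_normalization_and_support(self, z, beta):
        sigma = SIGMA_DOUBLET if z else SIGMA_SINGLET
        theta = THETA_DOUBLET if z else THETA_SINGLET
        for x in sigma:
            dist = ado_transition(x, z, beta)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
            assert set(dist) <= set(theta)

    def test_illegal_vaf_rejected(self):
        with pytest.raises(ValueError):
            ado_transition(0.25, 0, 0.1)  # 1/4 is not a singlet VAF


class TestAmplificationProb:
    @pytest.mark.parametrize(
        "y, expected",
        [(0.0, 0.015), (1.0, 1 - 0.0073), (0.5, 0.015 + 0.9777 * 0.5)],
    )
    def test_linear_interpolation(self, y, expected):
        assert amplification_prob(y, 0.015, 0.0073) == pytest.approx(expected)


class TestBetaBinomial:
    @pytest.mark.parametrize("c", [0, 1, 10, 100])
    @pytest.mark.parametrize("p,s", [(0.3, 15.0), (0.5, 1.0), (0.9, 200.0)])
    def test_pmf_normalizes(self, c, p, s):
        total = sum(
            math.exp(beta_binomial_loglik(v, c, p, s)) for v in range(c + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_trial(self):
        assert beta_binomial_loglik(0, 0, 0.3, 15.0) == 0.0

    def test_large_precision_approaches_binomial(self):
        c, p, s = 50, 0.3, 1e6
        tv = 0.5 * sum(
            abs(math.exp(beta_binomial_loglik(v, c, p, s)) - binom.pmf(v, c, p))
            for v in range(c + 1)
        )
        assert tv < 1e-3

    def test_large_counts_do_not_overflow(self):
        val = beta_binomial_loglik(40_000, 100_000, 0.4, 15.0)
        assert math.isfinite(val)

    @pytest.mark.parametrize("v,c,p", [(5, 3, 0.5), (1, 2, 0.0), (1, 2, 1.0)])
    def test_domain_errors(self, v, c, p):
        with pytest.raises(ValueError):
            beta_binomial_loglik(v, c, p, 15.0)


class TestDropletLocusLoglik:
    def test_matches_bruteforce_joint_table(self, rng):
        """Log-sum-exp marginalisation equals linear-space enumeration."""
        for _ in range(50):
            c = int(rng.integers(1, 31))
            v = int(rng.integers(0, c + 1))
            z = int(rng.integers(0, 2))
            mu = rng.dirichlet([1.0, 1.0, 1.0])
            err = ErrorModel(
                beta=float(rng.uniform(0, 0.5)),
                alpha_fp=float(rng.uniform(0, 0.05)),
                alpha_fn=float(rng.uniform(0, 0.05)),
                s=float(rng.uniform(1, 50)),
            )
            priors = LocusPriors.global_triple(mu, ["L0"])
            got = droplet_locus_loglik(v, c, z, priors, "L0", err)
            want = oracles.joint_loglik(v, c, z, tuple(mu), err)
            assert got == pytest.approx(want, abs=1e-10)

    def test_zero_coverage_is_uninformative(self, uniform_priors, default_err):
        pri = uniform_priors(1)
        for z in (0, 1):
            assert droplet_locus_loglik(0, 0, z, pri, "L000", default_err) == 0.0

    def test_quarter_vaf_favours_doublet(self, uniform_priors):
        # VAF 1/4 lies on the doublet support but not the singlet one
        err = ErrorModel(beta=0.0, alpha_fp=1e-6, alpha_fn=1e-6, s=1e6)
        pri = uniform_priors(1)
        ll1 = droplet_locus_loglik(25, 100, 1, pri, "L000", err)
        ll0 = droplet_locus_loglik(25, 100, 0, pri, "L000", err)
        assert ll1 > ll0


class TestOmegaMatrix:
    def test_all_zero_coverage_gives_zero_omega(self, uniform_priors, default_err):
        counts = ReadCounts(
            droplet_ids=np.array(["d0", "d1"], dtype=object),
            locus_ids=np.array(["L000", "L001"], dtype=object),
            total=np.zeros((2, 2), dtype=int),
            alt=np.zeros((2, 2), dtype=int),
        )
        res = omega_matrix(counts, uniform_priors(2), default_err)
        assert np.all(res.omega == 0.0)

    def test_antisymmetry_under_hypothesis_swap(self):
        rng = np.random.default_rng(5)
        ll0 = rng.normal(size=(4, 3))
        ll1 = rng.normal(size=(4, 3))
        ids = np.arange(4), np.arange(3)
        fwd = LikelihoodResult(ids[0], ids[1], ll0, ll1)
        rev = LikelihoodResult(ids[0], ids[1], ll1, ll0)
        np.testing.assert_allclose(fwd.omega, -rev.omega)

    def test_matches_scalar_marginal(self, small_counts, default_err, rng):
        mu = rng.dirichlet(np.ones(3), size=small_counts.m)
        priors = LocusPriors(locus_ids=small_counts.locus_ids, mu=mu)
        res = omega_matrix(small_counts, priors, default_err)
        for i in range(small_counts.n):
            for j in range(small_counts.m):
                v, c = small_counts.alt[i, j], small_counts.total[i, j]
                locus = small_counts.locus_ids[j]
                want = droplet_locus_loglik(
                    v, c, 1, priors, locus, default_err
                ) - droplet_locus_loglik(v, c, 0, priors, locus, default_err)
                assert res.omega[i, j] == pytest.approx(want, abs=1e-10)

    def test_quarter_vaf_row_is_positive(self, uniform_priors):
        err = ErrorModel(beta=0.0, alpha_fp=1e-6, alpha_fn=1e-6, s=1e6)
        counts = ReadCounts(
            droplet_ids=np.array(["d0"], dtype=object),
            locus_ids=np.array(["L000"], dtype=object),
            total=np.array([[100]]),
            alt=np.array([[25]]),
        )
        res = omega_matrix(counts, uniform_priors(1), err)
        assert res.omega[0, 0] > 0

    def test_mismatched_loci_rejected(self, small_counts, default_err):
        priors = LocusPriors.global_triple([1 / 3, 1 / 3, 1 / 3], ["A", "B", "C"])
        with pytest.raises(ValueError):
            omega_matrix(small_counts, priors, default_err)


def _random_result(rng, n, m=4):
    return LikelihoodResult(
        droplet_ids=np.array([f"d{i}" for i in range(n)], dtype=object),
        locus_ids=np.array([f"L{j}" for j in range(m)], dtype=object),
        log_lik_singlet=rng.normal(-5, 2, size=(n, m)),
        log_lik_doublet=rng.normal(-5, 2, size=(n, m)),
    )


class TestClassify:
    def test_matches_exhaustive_maximization(self, rng):
        """The per-droplet rule attains the global optimum over 2^n."""
        for n in (2, 5, 8, 10):
            res = _random_result(rng, n)
            delta = float(rng.uniform(0.05, 0.5))
            calls = classify(res, delta)
            got = tuple(c.z for c in calls)
            want, want_obj = oracles.best_assignment_bruteforce(
                res.log_lik_singlet, res.log_lik_doublet, delta
            )
            assert got == want
            assert log_posterior_objective(res, got, delta) == pytest.approx(
                want_obj
            )

    def test_even_prior_reduces_to_sign_with_tie_to_singlet(self):
        res = LikelihoodResult(
            droplet_ids=np.array(["a", "b", "c"], dtype=object),
            locus_ids=np.array(["L"], dtype=object),
            log_lik_singlet=np.array([[-1.0], [-2.0], [-3.0]]),
            log_lik_doublet=np.array([[-2.0], [-2.0], [-1.0]]),
        )
        zs = [c.z for c in classify(res, 0.5)]
        assert zs == [0, 0, 1]  # omega = -1, 0 (tie -> singlet), +2

    def test_zero_omega_low_prior_all_singlet(self, rng):
        res = _random_result(rng, 6)
        res = LikelihoodResult(
            res.droplet_ids,
            res.locus_ids,
            res.log_lik_singlet,
            res.log_lik_singlet,  # omega == 0
        )
        assert all(c.z == 0 for c in classify(res, 0.3))

    def test_calls_monotone_in_doublet_prior(self, rng):
        res = _random_result(rng, 40)
        called = None
        for delta in (0.02, 0.1, 0.3, 0.45):
            now = {c.droplet_id for c in classify(res, delta) if c.z}
            if called is not None:
                assert called <= now
            called = now

    @pytest.mark.parametrize("delta", [0.0, 1.0, -0.2])
    def test_invalid_prior_rejected(self, rng, delta):
        with pytest.raises(ValueError):
            classify(_random_result(rng, 2), delta)

    def test_posterior_consistent_with_call(self, rng):
        for call in classify(_random_result(rng, 30), 0.2):
            assert (call.posterior > 0.5) == bool(call.z)
            assert call.posterior == pytest.approx(
                1.0 / (1.0 + math.exp(-call.score))
            )


class TestPosteriorDoubletProb:
    def test_anchor_points(self):
        assert posterior_doublet_prob(0.0) == 0.5
        assert posterior_doublet_prob(1000.0) == pytest.approx(1.0, abs=1e-12)
        assert posterior_doublet_prob(-1000.0) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_complement_symmetry(self, score):
        total = posterior_doublet_prob(score) + posterior_doublet_prob(-score)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestCertaintyLimit:
    def test_noiseless_scores_diverge_with_loci(self, uniform_priors):
        """Clean singlet data drives scores to -inf as m grows; a VAF-1/4
        signature does the opposite.  (Wild-type rows are used for the
        singlet: a doublet must then be wt+wt, whose prior mass mu_wt^2 is
        strictly below the singlet's mu_wt, so every locus adds log mu_wt.)
        """
        err = ErrorModel(beta=0.0, alpha_fp=1e-6, alpha_fn=1e-6, s=1e6)
        prev_singlet, prev_doublet = 0.0, 0.0
        for m in (5, 20, 60):
            pri = uniform_priors(m)
            ids = pri.locus_ids
            het = ReadCounts(
                droplet_ids=np.array(["d0"], dtype=object),
                locus_ids=ids,
                total=np.full((1, m), 100),
                alt=np.zeros((1, m), dtype=int),
            )
            quarter = ReadCounts(
                droplet_ids=np.array(["d0"], dtype=object),
                locus_ids=ids,
                total=np.full((1, m), 100),
                alt=np.full((1, m), 25),
            )
            s_row = omega_matrix(het, pri, err).row_omega()[0]
            d_row = omega_matrix(quarter, pri, err).row_omega()[0]
            assert s_row < prev_singlet
            assert d_row > prev_doublet
            prev_singlet, prev_doublet = s_row, d_row


class TestReadCountsContainer:
    def test_alt_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="alt > total"):
            ReadCounts(
                droplet_ids=np.array(["d0"], dtype=object),
                locus_ids=np.array(["L0"], dtype=object),
                total=np.array([[5]]),
                alt=np.array([[6]]),
            )

    def test_label_alignment_reorders_columns(self):
        import pandas as pd

        alt = pd.DataFrame([[1, 2]], index=["d0"], columns=["A", "B"])
        total = pd.DataFrame([[20, 10]], index=["d0"], columns=["B", "A"])
        rc = ReadCounts.from_frames(alt, total)
        assert rc.total[0].tolist() == [10, 20]

    def test_label_set_mismatch_rejected(self):
        import pandas as pd

        alt = pd.DataFrame([[1]], index=["d0"], columns=["A"])
        total = pd.DataFrame([[2]], index=["d0"], columns=["B"])
        with pytest.raises(ValueError):
            ReadCounts.from_frames(alt, total)
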