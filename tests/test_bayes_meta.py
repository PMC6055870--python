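"""Quadrature and MCMC engines for Bayesian meta-analysis."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

import mapmeta as mm
from mapmeta.bayes_meta import GridDensity, NormalPrior, PointMass
from mapmeta.heterogeneity_priors import HeterogeneityPrior
from mapmeta.trial_data import EffectEstimate

HN1 = HeterogeneityPrior.half_normal(1.0)
HN05 = HeterogeneityPrior.half_normal(0.5)
IG1000 = HeterogeneityPrior.inverse_gamma(1 / 1000, 1.0)


def est(label, log_or, se):
    return EffectEstimate.from_components(label, log_or, se)


class TestFixedEffect:
    def test_adult_pool_with_vague_prior_matches_frequentist(self, adult_mi):
        res = mm.bayes_fixed_effect(adult_mi, mm.BayesConfig())
        fe = mm.fixed_effect_meta(adult_mi)
        assert abs(res.summary.mean - fe.estimate) < 0.01
        assert abs(res.summary.cred_low - fe.ci_low) < 0.02
        assert abs(res.summary.cred_high - fe.ci_high) < 0.02

    def test_flat_prior_limit_is_exactly_frequentist(self, adult_mi):
        cfg = mm.BayesConfig(effect_prior=NormalPrior.flat())
        res = mm.bayes_fixed_effect(adult_mi, cfg)
        fe = mm.fixed_effect_meta(adult_mi)
        assert res.summary.mean == pytest.approx(fe.estimate, abs=1e-12)
        assert res.summary.cred_low == pytest.approx(fe.ci_low, abs=1e-9)

    def test_conjugate_two_precision_hand_example(self):
        # single study 0.5 (se 0.2 -> var 0.04) against prior N(0, 0.04):
        # equal precisions average the prior mean and the estimate.
        mi = mm.MetaInput.from_estimates([est("s", 0.5, 0.2)])
        cfg = mm.BayesConfig(effect_prior=NormalPrior(0.0, 0.04))
        res = mm.bayes_fixed_effect(mi, cfg)
        assert res.summary.mean == pytest.approx(0.25, abs=1e-12)

    def test_monotone_prior_influence(self, adult_mi):
        fe = mm.fixed_effect_meta(adult_mi).estimate
        gaps = [
            abs(mm.bayes_fixed_effect(
                adult_mi, mm.BayesConfig(effect_prior=NormalPrior(0.5, v))
            ).summary.mean - fe)
            for v in (0.5, 2.0, 10.0, 100.0)
        ]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestSummarizePosterior:
    def test_standard_normal_grid(self):
        g = GridDensity.from_normal(0.0, 1.0, 2001)
        s = mm.summarize_posterior(g, 0.95)
        assert abs(s.median) < 1e-4
        assert s.cred_low == pytest.approx(-1.95996, abs=5e-3)
        assert s.cred_high == pytest.approx(1.95996, abs=5e-3)

    def test_shifted_normal_mean(self):
        g = GridDensity.from_normal(1.0, 2.0, 2001)
        assert mm.summarize_posterior(g).mean == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_against_root_finding_oracle(self):
        # 0.5 N(-1, 0.1^2) + 0.5 N(1, 0.1^2)
        def cdf(x):
            return 0.5 * stats.norm.cdf(x, -1, 0.1) + 0.5 * stats.norm.cdf(x, 1, 0.1)

        x = np.linspace(-2.0, 2.0, 4001)
        dens = 0.5 * stats.norm.pdf(x, -1, 0.1) + 0.5 * stats.norm.pdf(x, 1, 0.1)
        s = mm.summarize_posterior(GridDensity(x, dens).normalized(), 0.95)
        lo = optimize.brentq(lambda v: cdf(v) - 0.025, -2, 0)
        hi = optimize.brentq(lambda v: cdf(v) - 0.975, 0, 2)
        assert -0.2 < s.median < 0.2
        assert s.cred_low == pytest.approx(lo, abs=5e-3)
        assert s.cred_high == pytest.approx(hi, abs=5e-3)

    def test_unnormalized_grid_rejected(self):
        x = np.linspace(-3, 3, 101)
        with pytest.raises(ValueError, match="not normalized"):
            mm.summarize_posterior(GridDensity(x, 2 * stats.norm.pdf(x)))

    def test_grid_invariants_enforced(self):
        with pytest.raises(ValueError):
            GridDensity(np.array([0.0, 0.0, 1.0]), np.ones(3))
        with pytest.raises(ValueError):
            GridDensity(np.linspace(0, 1, 3), np.array([1.0, -0.5, 1.0]))


class TestTauPosterior:
    def test_two_studies_cannot_move_the_prior_much(self, dyspepsia_mi):
        cfg = mm.BayesConfig(heterogeneity_prior=HN1)
        post = mm.marginal_tau_posterior(dyspepsia_mi, cfg)
        prior_mass = HN1.cdf_tau(0.1)
        post_mass = post.cdf(0.1)
        assert abs(post_mass - prior_mass) < 0.15

    def test_point_mass_prior_returns_marker(self, adult_mi):
        cfg = mm.BayesConfig(heterogeneity_prior=HeterogeneityPrior.point(0.3))
        out = mm.marginal_tau_posterior(adult_mi, cfg)
        assert isinstance(out, PointMass)
        assert out.value == 0.3

    def test_tau_recovery_in_large_meta_analysis(self):
        rng = np.random.default_rng(5)
        tau_true, sigma = 0.5, 0.15
        deltas = 0.2 + tau_true * rng.standard_normal(50)
        ests = [
            est(f"s{i}", float(rng.normal(d, sigma)), sigma)
            for i, d in enumerate(deltas)
        ]
        cfg = mm.BayesConfig(heterogeneity_prior=HN1)
        post = mm.marginal_tau_posterior(mm.MetaInput.from_estimates(ests), cfg)
        assert 0.35 < post.quantile(0.5) < 0.65


class TestRandomEffects:
    def test_point_mass_zero_matches_fixed_effect(self, adult_mi):
        cfg = mm.BayesConfig(heterogeneity_prior=HeterogeneityPrior.point(0.0))
        re = mm.bayes_random_effects(adult_mi, cfg)
        fe = mm.bayes_fixed_effect(adult_mi, mm.BayesConfig())
        assert abs(re.summary.mean - fe.summary.mean) < 1e-6
        assert abs(re.summary.cred_low - fe.summary.cred_low) < 1e-3

    def test_interval_width_tracks_assumed_heterogeneity(self, trials):
        mi = mm.MetaInput.from_trials(mm.adult_trials() + [trials["scenario1"]])
        widths = {}
        for prior in (HN1, HN05, IG1000):
            s = mm.bayes_random_effects(mi, mm.BayesConfig(heterogeneity_prior=prior)).summary
            widths[prior.label] = s.cred_high - s.cred_low
        assert widths["HN(1)"] > widths["HN(0.5)"] > widths["IG(0.001,1)"]

    def test_two_identical_studies_centre_on_common_estimate(self):
        # exact symmetry statement: with a flat effect prior the posterior
        # sits on the common estimate for any heterogeneity prior
        e = est("s", 0.3, 0.2)
        mi = mm.MetaInput.from_estimates([e, est("s2", 0.3, 0.2)])
        for prior in (HN05, IG1000):
            cfg = mm.BayesConfig(
                effect_prior=NormalPrior.flat(), heterogeneity_prior=prior
            )
            res = mm.bayes_random_effects(mi, cfg)
            assert abs(res.summary.mean - 0.3) < 1e-3

    def test_grid_refinement_stability(self, trials):
        mi = mm.MetaInput.from_trials(mm.adult_trials() + [trials["scenario2"]])
        coarse = mm.bayes_random_effects(
            mi, mm.BayesConfig(heterogeneity_prior=HN05)
        ).summary.mean
        fine = mm.bayes_random_effects(
            mi, mm.BayesConfig(heterogeneity_prior=HN05, n_tau=800, n_delta=1600)
        ).summary.mean
        assert abs(fine - coarse) < 1e-4

    def test_missing_heterogeneity_prior_rejected(self, adult_mi):
        with pytest.raises(ValueError, match="heterogeneity_prior"):
            mm.bayes_random_effects(adult_mi, mm.BayesConfig())


class TestMcmc:
    CFG = dict(chains=4, iterations=4000, seed=42)

    def test_single_trial_posterior_matches_observed_log_or(self, trials):
        res = mm.mcmc_binomial_logit([trials["bond"]], mm.BayesConfig(**self.CFG))
        assert abs(res.summary("delta").mean - 0.74) < 0.05
        assert res.rhat["delta"] < 1.05

    def test_engine_agreement_on_adult_fixture(self, adult_mi):
        res = mm.mcmc_binomial_logit(mm.adult_trials(), mm.BayesConfig(**self.CFG))
        quad = mm.bayes_fixed_effect(adult_mi, mm.BayesConfig())
        tol = max(0.02, 3 * res.mc_se("delta"))
        assert abs(res.summary("delta").mean - quad.summary.mean) < tol

    def test_random_model_tau_posterior_agrees_with_quadrature(self, trials):
        battery = mm.adult_trials() + [trials["scenario2"]]
        cfg = mm.BayesConfig(heterogeneity_prior=HN05, **self.CFG)
        res = mm.mcmc_binomial_logit(battery, cfg, "random")
        quad = mm.bayes_random_effects(mm.MetaInput.from_trials(battery), cfg)
        assert abs(res.summary("delta").mean - quad.summary.mean) < max(
            0.02, 3 * res.mc_se("delta")
        )
        assert abs(res.summary("tau").median - quad.summary.tau_summary.median) < 0.05

    def test_seed_is_mandatory_and_reproducible(self, trials):
        with pytest.raises(ValueError, match="seed"):
            mm.mcmc_binomial_logit([trials["bond"]], mm.BayesConfig())
        cfg = mm.BayesConfig(chains=2, iterations=1000, seed=9)
        a = mm.mcmc_binomial_logit([trials["bond"]], cfg)
        b = mm.mcmc_binomial_logit([trials["bond"]], cfg)
        assert np.array_equal(a.draws["delta"], b.draws["delta"])

    def test_single_chain_rejected(self, trials):
        with pytest.raises(ValueError, match="chains"):
            mm.mcmc_binomial_logit(
                [trials["bond"]], mm.BayesConfig(chains=1, iterations=500, seed=1)
            )


def test_simulation_based_calibration_random_effects():
    """Posterior CDF at the true effect is uniform over prior draws (SBC).

    Three studies of within-study SD 0.3; parameters drawn from the fitted
    model's own priors (effect N(0,10), heterogeneity HN(0.5)).
    """
    rng = np.random.default_rng(77)
    cfg = mm.BayesConfig(heterogeneity_prior=HN05, n_tau=200, n_delta=400)
    sigma, n_rep = 0.3, 200
    pits = np.empty(n_rep)
    for r in range(n_rep):
        tau = abs(rng.normal(0.0, 0.5))
        delta = rng.normal(0.0, math.sqrt(10.0))
        y = rng.normal(delta, math.sqrt(tau**2 + sigma**2), size=3)
        mi = mm.MetaInput.from_estimates(
            [est(f"s{i}", float(v), sigma) for i, v in enumerate(y)]
        )
        res = mm.bayes_random_effects(mi, cfg)
        pits[r] = res.grid.cdf(delta)
    counts, _ = np.histogram(pits, bins=10, range=(0.0, 1.0))
    chi2 = float(((counts - n_rep / 10) ** 2 / (n_rep / 10)).sum())
    assert stats.chi2.sf(chi2, 9) > 0.01
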