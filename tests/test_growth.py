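import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from spermarche import (
    AnimalRecord,
    FixedPrior,
    GrowthParams,
    MCMCConfig,
    PriorSpec,
    Source,
    UniformPrior,
    compute_dic,
    fit_model,
    growth_mean,
    log_likelihood,
    run_mcmc,
)

TABLE_PARAMS = GrowthParams(alpha=4.96, beta=0.078, gamma=5.89)


def record(age, length, bcs=None, rid="r"):
    return AnimalRecord(
        animal_id=rid,
        source=Source.IN_VIVO,
        age_months=age,
        left_length_cm=length,
        right_length_cm=length,
        mean_length_cm=length,
        bcs=bcs,
    )


class TestGrowthMean:
    def test_midpoint_at_inflection_age(self):
        assert growth_mean(TABLE_PARAMS, 5.89) == pytest.approx(4.96 / 2)

    def test_value_at_median_study_age(self):
        # one-line arithmetic oracle for the logistic curve
        expected = 4.96 / (1 + math.exp(-0.078 * (25.5 - 5.89)))
        assert growth_mean(TABLE_PARAMS, 25.5) == pytest.approx(expected)
        assert growth_mean(TABLE_PARAMS, 25.5) == pytest.approx(4.077, abs=5e-4)

    def test_unit_bcs_delta_product_reduces_to_plain_curve(self):
        with_bcs = GrowthParams(alpha=4.96, beta=0.078, gamma=5.89, delta=0.25)
        assert growth_mean(with_bcs, 30.0, bcs=4.0) == pytest.approx(
            growth_mean(TABLE_PARAMS, 30.0)
        )

    def test_bcs_and_delta_must_come_together(self):
        with pytest.raises(ValueError, match="bcs"):
            growth_mean(TABLE_PARAMS, 30.0, bcs=4.0)
        with pytest.raises(ValueError, match="bcs"):
            growth_mean(
                GrowthParams(alpha=4.96, beta=0.078, gamma=5.89, delta=0.3), 30.0
            )

    @given(
        alpha=st.floats(0.5, 15.0),
        beta=st.floats(0.01, 0.3),
        gamma=st.floats(-20.0, 60.0),
    )
    def test_strictly_increasing_and_bounded_by_asymptote(self, alpha, beta, gamma):
        params = GrowthParams(alpha=alpha, beta=beta, gamma=gamma)
        # keep |beta * (age - gamma)| well below exp's float64 saturation,
        # where consecutive curve values collapse to alpha exactly
        ages = np.linspace(1.0, 60.0, 80)
        mu = growth_mean(params, ages)
        assert np.all(np.diff(mu) > 0)
        assert np.all(mu > 0) and np.all(mu < alpha)
        # in the saturated tail the bound still holds, non-strictly
        assert growth_mean(params, 1e6) <= alpha

    def test_approaches_asymptote(self):
        assert growth_mean(TABLE_PARAMS, 1e4) == pytest.approx(4.96, abs=1e-9)

    @given(bcs_lo=st.floats(2.5, 3.5), bcs_gap=st.floats(0.5, 1.5))
    def test_higher_bcs_never_below_lower_bcs_past_inflection(self, bcs_lo, bcs_gap):
        params = GrowthParams(alpha=4.96, beta=0.078, gamma=5.89, delta=0.3)
        ages = np.linspace(6.0, 120.0, 80)  # above gamma
        lo = growth_mean(params, ages, bcs=np.full_like(ages, bcs_lo))
        hi = growth_mean(params, ages, bcs=np.full_like(ages, bcs_lo + bcs_gap))
        assert np.all(hi >= lo)


class TestLogLikelihood:
    def test_standard_normal_density_at_zero_residual(self):
        params = GrowthParams(alpha=3.0, beta=0.1, gamma=10.0, sigma=1.0)
        mu = growth_mean(params, 20.0)
        value = log_likelihood(params, [record(20.0, mu)])
        assert value == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-9)
        assert value == pytest.approx(-0.91894, abs=1e-5)

    def test_one_sigma_residual(self):
        params = GrowthParams(alpha=3.0, beta=0.1, gamma=10.0, sigma=1.0)
        mu = growth_mean(params, 20.0)
        value = log_likelihood(params, [record(20.0, mu + 1.0)])
        assert value == pytest.approx(-0.5 * math.log(2 * math.pi) - 0.5, abs=1e-9)

    def test_additive_over_records(self, sim_cohort):
        params = GrowthParams(alpha=4.96, beta=0.078, gamma=5.89, sigma=0.3)
        single = log_likelihood(params, sim_cohort)
        doubled = log_likelihood(params, list(sim_cohort) * 2)
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_null_variant_maximized_at_sample_mean(self):
        cohort = [record(a, l, rid=f"r{i}")
                  for i, (a, l) in enumerate([(15, 2.5), (25, 3.5), (40, 4.5)])]
        sample_mean = np.mean([r.mean_length_cm for r in cohort])
        grid = np.linspace(1.0, 6.0, 501)
        lls = [
            log_likelihood(
                GrowthParams(alpha=a, beta=0.1, gamma=1.0, sigma=0.5),
                cohort,
                variant="null",
            )
            for a in grid
        ]
        assert grid[int(np.argmax(lls))] == pytest.approx(sample_mean, abs=0.01)

    def test_missing_bcs_error_names_records(self):
        params = GrowthParams(alpha=4.96, beta=0.078, gamma=5.89, delta=0.3)
        cohort = [record(20.0, 3.0, bcs=4.0, rid="ok"),
                  record(25.0, 3.5, rid="nobcs")]
        with pytest.raises(ValueError, match="nobcs"):
            log_likelihood(params, cohort, variant="increment_bcs")


class TestComputeDic:
    toy = [record(10.0, 3.0, rid="t1"), record(20.0, 4.0, rid="t2")]

    def test_single_draw_degenerate_posterior(self):
        chains = {"alpha": np.array([3.4]), "sigma": np.array([0.8])}
        dic, p_d = compute_dic(chains, self.toy, "null")
        dev = -2 * sum(
            norm.logpdf(r.mean_length_cm, 3.4, 0.8) for r in self.toy
        )
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(dev, abs=1e-9)

    def test_two_draw_hand_computation(self):
        draws_alpha = np.array([3.0, 4.0])
        draws_sigma = np.array([1.0, 0.5])
        chains = {"alpha": draws_alpha, "sigma": draws_sigma}
        dic, p_d = compute_dic(chains, self.toy, "null")
        # independent arithmetic oracle via scipy's normal density
        devs = [
            -2 * sum(norm.logpdf(r.mean_length_cm, a, s) for r in self.toy)
            for a, s in zip(draws_alpha, draws_sigma)
        ]
        d_bar = np.mean(devs)
        d_at_mean = -2 * sum(
            norm.logpdf(r.mean_length_cm, 3.5, 0.75) for r in self.toy
        )
        assert p_d == pytest.approx(d_bar - d_at_mean, abs=1e-9)
        assert dic == pytest.approx(2 * d_bar - d_at_mean, abs=1e-9)

    def test_empty_chains_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dic({"alpha": np.array([]), "sigma": np.array([])},
                        self.toy, "null")


class TestRunMcmc:
    def test_seeded_determinism(self, sim_cohort, light_mcmc):
        a = run_mcmc(sim_cohort, "increment", config=light_mcmc)
        b = run_mcmc(sim_cohort, "increment", config=light_mcmc)
        for name in a.chains:
            assert np.array_equal(a.chains[name], b.chains[name])
        assert a.dic == b.dic

    def test_conjugate_normal_mean_closed_form(self, sim_cohort):
        """Null model with sigma pinned at 1 and a flat prior on the mean:
        the posterior is Normal(sample mean, 1/n) in closed form."""
        priors = PriorSpec(alpha=UniformPrior(-100.0, 100.0),
                           sigma=FixedPrior(1.0))
        config = MCMCConfig(n_chains=2, n_iterations=8000, n_burnin=2000, seed=13)
        res = run_mcmc(sim_cohort, "null", priors=priors, config=config)
        pooled = res.pooled("alpha")
        lengths = [r.mean_length_cm for r in sim_cohort]
        import arviz as az

        ess = float(az.ess(res.chains["alpha"]))
        mcse = pooled.std() / np.sqrt(ess)
        assert abs(pooled.mean() - np.mean(lengths)) < 3 * mcse
        assert pooled.std() == pytest.approx(1 / np.sqrt(len(lengths)), rel=0.15)
        assert "sigma" in res.fixed and "sigma" not in res.chains

    def test_summaries_are_ordered_and_dic_identity(self, sim_cohort, light_mcmc):
        res = run_mcmc(sim_cohort, "increment", config=light_mcmc)
        for s in res.summaries.values():
            assert s.ci_lower <= s.median <= s.ci_upper
        assert res.dic == pytest.approx(res.mean_deviance + res.p_d, abs=1e-9)

    def test_identical_lengths_rejected(self):
        cohort = [record(a, 3.0, rid=f"r{i}") for i, a in enumerate([10, 20, 30])]
        with pytest.raises(ValueError, match="unidentifiable"):
            run_mcmc(cohort, "null", config=MCMCConfig(seed=0))

    def test_fixed_beta_contract(self, sim_cohort, light_mcmc):
        with pytest.raises(ValueError, match="fixed_beta"):
            run_mcmc(sim_cohort, "increment_bcs", config=light_mcmc)
        with pytest.raises(ValueError, match="only meaningful"):
            run_mcmc(sim_cohort, "increment", config=light_mcmc, fixed_beta=0.08)


class TestFitModel:
    def test_null_posterior_median_near_small_sample_mean(self):
        cohort = [record(a, l, rid=f"r{i}")
                  for i, (a, l) in enumerate([(15, 2.0), (25, 3.0), (40, 4.0)])]
        config = MCMCConfig(n_chains=2, n_iterations=11000, n_burnin=1000, seed=21)
        res = fit_model(cohort, "null", config=config)
        assert res.summaries["alpha"].median == pytest.approx(3.0, abs=0.2)

    def test_bcs_variant_needs_beta_source(self, sim_cohort, light_mcmc):
        with pytest.raises(ValueError, match="beta source"):
            fit_model(sim_cohort, "increment_bcs", config=light_mcmc)

    def test_delta_dic_against_itself_is_zero(self, sim_cohort, light_mcmc):
        res = fit_model(sim_cohort, "null", config=light_mcmc)
        again = fit_model(sim_cohort, "null", config=light_mcmc, reference=res)
        assert again.delta_dic == pytest.approx(0.0, abs=1e-12)

    def test_bcs_variant_pins_beta_at_increment_mode(self, sim_cohort, light_mcmc):
        from spermarche import posterior_mode

        inc = fit_model(sim_cohort, "increment", config=light_mcmc)
        bcs = fit_model(
            sim_cohort, "increment_bcs", config=light_mcmc,
            increment_result=inc, reference=inc,
        )
        assert bcs.fixed["beta"] == pytest.approx(
            posterior_mode(inc.pooled("beta"))
        )
        assert "beta" not in bcs.chains
        assert set(bcs.chains) == {"alpha", "gamma", "delta", "sigma"}
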