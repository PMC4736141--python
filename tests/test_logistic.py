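import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from spermarche import (
    AnimalRecord,
    Source,
    compare_predictors,
    bootstrap_thresholds,
    fit_logistic,
    invert_threshold,
    predict_prob,
    table_fixture,
    threshold_pair,
)
from spermarche.logistic import LogisticFitResult


def unit_fit(intercept=0.0, slope=1.0):
    return LogisticFitResult(
        predictor="x", intercept=intercept, slope=slope,
        se_intercept=1.0, se_slope=1.0, p_wald_slope=0.5,
        loglik=-1.0, aic=6.0, pseudo_r2={}, n=4, converged=True,
    )


def bernoulli_nll(x, y):
    def nll(b):
        p = expit(b[0] + b[1] * x)
        return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    return nll


class TestFitLogistic:
    def test_symmetric_toy_gives_flat_half_probability(self):
        fit = fit_logistic([0, 0, 1, 1], [0, 1, 0, 1])
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert predict_prob(fit, 0.7) == pytest.approx(0.5, abs=1e-8)

    def test_perfect_separation_is_flagged(self):
        fit = fit_logistic([1, 2, 3, 4], [0, 0, 1, 1])
        assert not fit.converged

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_likelihood_maximum(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(3.0, 1.0, 50)
        y = (rng.random(50) < expit(-4.0 + 1.5 * x)).astype(float)
        fit = fit_logistic(x, y)
        opt = minimize(
            bernoulli_nll(x, y), [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.converged
        assert fit.intercept == pytest.approx(opt.x[0], abs=1e-4)
        assert fit.slope == pytest.approx(opt.x[1], abs=1e-4)
        assert fit.loglik == pytest.approx(-opt.fun, abs=1e-6)

    def test_aic_identity_and_pseudo_r2_ranges(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 5, 60)
        y = (rng.random(60) < expit(-5 + 2 * x)).astype(float)
        fit = fit_logistic(x, y)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 4, abs=1e-12)
        assert 0 <= fit.pseudo_r2["mcfadden"] < 1
        assert 0 <= fit.pseudo_r2["nagelkerke"] <= 1
        assert 0 <= fit.pseudo_r2["tjur"] <= 1
        assert 0 < fit.p_wald_slope <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="no outcome variation"):
            fit_logistic([1, 2, 3], [1, 1, 1])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_logistic([1, 2], [0, 1])


class TestPredictAndInvert:
    def test_logit_midpoint(self):
        assert predict_prob(unit_fit(), 0.0) == pytest.approx(0.5)
        assert predict_prob(unit_fit(intercept=-3.0), 3.0) == pytest.approx(0.5)

    def test_inverse_logit_closed_form(self):
        assert predict_prob(unit_fit(), math.log(99)) == pytest.approx(0.99)

    def test_invert_at_half_is_zero(self):
        assert invert_threshold(unit_fit(), 0.5) == pytest.approx(0.0)

    def test_invert_unit_logistic_at_99_percent(self):
        assert invert_threshold(unit_fit(), 0.99) == pytest.approx(
            math.log(99), abs=1e-12
        )

    @given(
        intercept=st.floats(-10.0, 10.0),
        slope=st.floats(0.1, 8.0),
        p=st.sampled_from([0.01, 0.5, 0.99]),
    )
    def test_roundtrip_identity(self, intercept, slope, p):
        fit = unit_fit(intercept, slope)
        assert predict_prob(fit, invert_threshold(fit, p)) == pytest.approx(
            p, abs=1e-9
        )

    def test_zero_slope_threshold_undefined(self):
        with pytest.raises(ValueError, match="threshold undefined"):
            invert_threshold(unit_fit(slope=0.0), 0.99)

    def test_prediction_refused_for_unconverged_fit(self):
        bad = LogisticFitResult(
            predictor="x", intercept=0.0, slope=60.0, se_intercept=1.0,
            se_slope=1.0, p_wald_slope=0.5, loglik=-1.0, aic=6.0,
            pseudo_r2={}, n=4, converged=False,
        )
        with pytest.raises(ValueError, match="non-converged"):
            predict_prob(bad, 1.0)


class TestThresholdPair:
    def test_ordering_for_positive_slope(self):
        pair = threshold_pair(unit_fit(intercept=-8.0, slope=3.0))
        assert pair.lower_cm < pair.upper_cm

    def test_rounding_half_up_one_decimal(self):
        pair = threshold_pair(unit_fit(intercept=-8.0, slope=3.0))
        fit = unit_fit(intercept=-8.0, slope=3.0)
        assert predict_prob(fit, pair.upper_cm) == pytest.approx(0.99, abs=1e-9)
        assert predict_prob(fit, pair.lower_cm) == pytest.approx(0.01, abs=1e-9)
        # half-up policy on a constructed .x5 case
        from spermarche.logistic import _round_half_up

        assert _round_half_up(1.65, 1) == 1.7
        assert _round_half_up(1.64999, 1) == 1.6

    @given(scale=st.floats(0.2, 5.0), shift=st.floats(-3.0, 3.0))
    def test_affine_equivariance_of_thresholds(self, scale, shift):
        """Rescaling the predictor transforms the thresholds accordingly."""
        rng = np.random.default_rng(17)
        x = rng.uniform(0.5, 5.5, 120)
        y = (rng.random(120) < expit(-11.28 + 4.18 * x)).astype(float)
        base = threshold_pair(fit_logistic(x, y))
        scaled = threshold_pair(fit_logistic(scale * x + shift, y))
        assert scaled.upper_cm == pytest.approx(scale * base.upper_cm + shift, rel=1e-4, abs=1e-5)
        assert scaled.lower_cm == pytest.approx(scale * base.lower_cm + shift, rel=1e-4, abs=1e-5)


class TestComparePredictors:
    def test_identical_predictors_tie(self):
        rng = np.random.default_rng(4)
        records = []
        for i in range(40):
            v = float(rng.uniform(13, 48))
            records.append(
                AnimalRecord(
                    animal_id=f"c{i}", source=Source.CASTRATION,
                    age_months=v, left_length_cm=v, right_length_cm=v,
                    mean_length_cm=v,
                    sperm_present=bool(rng.random() < expit(-6 + 0.25 * v)),
                )
            )
        cmp_ = compare_predictors(records)
        assert cmp_.aic_difference == pytest.approx(0.0, abs=1e-9)

    def test_length_step_beats_random_age(self):
        """Outcome is a noisy step in length and a fair coin in age."""
        rng = np.random.default_rng(5)
        records = []
        for i in range(60):
            length = float(rng.uniform(1, 6))
            # steep but not separating: 5% label noise
            p = 0.95 if length > 3.0 else 0.05
            records.append(
                AnimalRecord(
                    animal_id=f"c{i}", source=Source.CASTRATION,
                    age_months=float(rng.uniform(12, 100)),
                    left_length_cm=length, right_length_cm=length,
                    mean_length_cm=length,
                    sperm_present=bool(rng.random() < p),
                )
            )
        cmp_ = compare_predictors(records)
        assert cmp_.preferred == "mean_length_cm"
        assert cmp_.length_fit.aic < cmp_.age_fit.aic

    def test_excised_fixture_snapshot(self, exp2_fixture):
        """Regression values for the deterministic organ-table fixture."""
        cmp_ = compare_predictors(exp2_fixture)
        assert cmp_.preferred == "mean_length_cm"
        assert cmp_.length_fit.converged and cmp_.age_fit.converged
        assert cmp_.length_fit.n == 28
        # frozen snapshot of this fixture's fit (not literature values)
        assert cmp_.length_fit.aic == pytest.approx(24.359, abs=1e-3)
        assert cmp_.age_fit.aic == pytest.approx(29.990, abs=1e-3)
        assert cmp_.thresholds is not None
        assert cmp_.thresholds.lower_rounded == 1.5
        assert cmp_.thresholds.upper_rounded == 4.3

    def test_missing_outcome_rejected(self, exp1_fixture):
        with pytest.raises(ValueError, match="sperm outcome missing"):
            compare_predictors(exp1_fixture)


class TestBootstrapThresholds:
    def test_seeded_and_sane(self, exp2_fixture):
        cmp_ = compare_predictors(exp2_fixture)
        x = [r.mean_length_cm for r in exp2_fixture]
        a = bootstrap_thresholds(cmp_.length_fit, x, n_boot=100, seed=9)
        b = bootstrap_thresholds(cmp_.length_fit, x, n_boot=100, seed=9)
        assert a == b
        assert a["n_used"] + a["n_dropped"] == 100
        assert a["lower_cm"]["median"] < a["upper_cm"]["median"]
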