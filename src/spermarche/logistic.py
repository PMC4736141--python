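"""Logistic models of sperm presence and management thresholds.

The probability that an excised organ pair contains sperm is modelled as
a binomial GLM with logit link in a single predictor — the animal's age
(months) or its mean testicular length (cm).  Fits are compared by AIC,
Wald significance of the slope and pseudo-R² (McFadden, Nagelkerke and
Tjur are all reported; Nagelkerke is the headline value).

The fitted length curve is inverted into a pair of management cut-offs:
the length above which sperm production is near-certain (fitted
probability 0.99) and the length below which it is near-impossible
(0.01).  An optional parametric bootstrap yields median-curve thresholds
with percentile intervals.

Estimation is delegated to :mod:`statsmodels` (IRLS); separation and
other non-convergence is detected and flagged on the result rather than
returned as silent garbage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .records import AnimalRecord

__all__ = [
    "LogisticFitResult",
    "ThresholdPair",
    "PredictorComparison",
    "fit_logistic",
    "predict_prob",
    "invert_threshold",
    "threshold_pair",
    "bootstrap_thresholds",
    "compare_predictors",
]

_SLOPE_DIVERGENCE = 50.0


@dataclass(frozen=True)
class LogisticFitResult:
    """A single-predictor binomial-logit fit.

    ``aic = -2 loglik + 4`` always (two estimated parameters).  When
    ``converged`` is False (separation or failed IRLS) the estimates are
    the last-iteration values and standard errors may be meaningless;
    downstream prediction refuses to use such a fit.
    """

    predictor: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_wald_slope: float
    loglik: float
    aic: float
    pseudo_r2: dict[str, float]
    n: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "p_wald_slope": self.p_wald_slope,
            "loglik": self.loglik,
            "aic": self.aic,
            "pseudo_r2": dict(self.pseudo_r2),
            "n": self.n,
            "converged": self.converged,
        }


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ThresholdPair:
    """Management cut-offs from an inverted sperm-presence curve.

    ``upper_cm``/``lower_cm`` are the exact lengths where the fitted
    probability equals 0.99 and 0.01; ``rounding`` declares the decimals
    used by the rounded accessors (half-up, one decimal by default).
    """

    upper_cm: float
    lower_cm: float
    rounding: int = 1

    @property
    def upper_rounded(self) -> float:
        return _round_half_up(self.upper_cm, self.rounding)

    @property
    def lower_rounded(self) -> float:
        return _round_half_up(self.lower_cm, self.rounding)

    def to_dict(self) -> dict:
        return {
            "upper_cm": self.upper_cm,
            "lower_cm": self.lower_cm,
            "upper_rounded": self.upper_rounded,
            "lower_rounded": self.lower_rounded,
            "rounding": self.rounding,
        }


def fit_logistic(
    x: Sequence[float],
    y: Sequence[int],
    predictor: str = "x",
) -> LogisticFitResult:
    """Maximum-likelihood binomial-logit fit of y on a single predictor.

    Requires at least three observations and both outcome classes.
    IRLS via statsmodels; quasi-complete separation (statsmodels'
    separation warning, a diverging slope beyond 50 in absolute value, or
    non-convergence) yields ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("no outcome variation: y contains a single class")

    X = sm.add_constant(x)
    separated = False
    converged = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-12
            )
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        llf = float(res.llf)
        converged = bool(getattr(res, "converged", True))
    except PerfectSeparationError:
        separated = True
        params = np.array([np.nan, np.nan])
        bse = np.array([np.nan, np.nan])
        pvals = np.array([np.nan, np.nan])
        llf = 0.0

    intercept, slope = float(params[0]), float(params[1])
    ok = converged and not separated and abs(slope) <= _SLOPE_DIVERGENCE

    aic = -2.0 * llf + 4.0
    p_bar = float(np.mean(y))
    ll_null = float(
        np.sum(y) * np.log(p_bar) + np.sum(1.0 - y) * np.log(1.0 - p_bar)
    )
    mcfadden = 1.0 - llf / ll_null if ll_null != 0 else np.nan
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - llf) / n)
    nagelkerke = cox_snell / (1.0 - math.exp(2.0 * ll_null / n))
    if np.isfinite(intercept):
        fitted = expit(intercept + slope * x)
        tjur = float(np.mean(fitted[y == 1]) - np.mean(fitted[y == 0]))
    else:
        tjur = np.nan

    return LogisticFitResult(
        predictor=predictor,
        intercept=intercept,
        slope=slope,
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        p_wald_slope=float(pvals[1]),
        loglik=llf,
        aic=aic,
        pseudo_r2={
            "mcfadden": float(mcfadden),
            "nagelkerke": float(nagelkerke),
            "tjur": tjur,
        },
        n=int(n),
        converged=ok,
    )


def predict_prob(fit: LogisticFitResult, x: float | np.ndarray):
    """Fitted probability at x (inverse-logit of the linear predictor)."""
    if not fit.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    p = expit(fit.intercept + fit.slope * np.asarray(x, dtype=float))
    return float(p) if np.isscalar(x) else p


def invert_threshold(fit: LogisticFitResult, p: float) -> float:
    """Predictor value at which the fitted probability equals p.

    ``x = (logit(p) - intercept) / slope``; the round trip
    ``predict_prob(fit, x) == p`` holds to numerical precision.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if fit.slope == 0.0:
        raise ValueError("threshold undefined: slope is zero")
    return float((logit(p) - fit.intercept) / fit.slope)


def threshold_pair(
    fit: LogisticFitResult,
    upper_p: float = 0.99,
    lower_p: float = 0.01,
    rounding: int = 1,
) -> ThresholdPair:
    """Invert the fitted curve at the near-certain (0.99) and
    near-impossible (0.01) probabilities."""
    return ThresholdPair(
        upper_cm=invert_threshold(fit, upper_p),
        lower_cm=invert_threshold(fit, lower_p),
        rounding=rounding,
    )


def bootstrap_thresholds(
    fit: LogisticFitResult,
    x: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Parametric-bootstrap median-curve thresholds.

    Resamples outcomes from the fitted probabilities, refits, and inverts
    each replicate curve at 0.99/0.01; returns the median threshold and a
    95% percentile interval for both cut-offs.  Replicates that separate
    or fail to converge are dropped (their count is reported).
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    probs = expit(fit.intercept + fit.slope * x)
    uppers, lowers = [], []
    dropped = 0
    for _ in range(n_boot):
        yb = (rng.random(x.size) < probs).astype(float)
        if len(np.unique(yb)) < 2:
            dropped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = fit_logistic(x, yb, predictor=fit.predictor)
        if not fb.converged or fb.slope == 0.0:
            dropped += 1
            continue
        uppers.append(invert_threshold(fb, 0.99))
        lowers.append(invert_threshold(fb, 0.01))
    if not uppers:
        raise RuntimeError("every bootstrap replicate failed to converge")
    uppers = np.array(uppers)
    lowers = np.array(lowers)
    return {
        "n_boot": n_boot,
        "n_used": int(uppers.size),
        "n_dropped": dropped,
        "upper_cm": {
            "median": float(np.median(uppers)),
            "ci_lower": float(np.percentile(uppers, 2.5)),
            "ci_upper": float(np.percentile(uppers, 97.5)),
        },
        "lower_cm": {
            "median": float(np.median(lowers)),
            "ci_lower": float(np.percentile(lowers, 2.5)),
            "ci_upper": float(np.percentile(lowers, 97.5)),
        },
    }


@dataclass(frozen=True)
class PredictorComparison:
    """Side-by-side fits of sperm presence on length and on age."""

    length_fit: LogisticFitResult
    age_fit: LogisticFitResult
    aic_difference: float  # age AIC minus length AIC; positive favours length
    preferred: str
    thresholds: ThresholdPair | None
    bootstrap: dict | None = None

    def to_dict(self) -> dict:
        return {
            "length_fit": self.length_fit.to_dict(),
            "age_fit": self.age_fit.to_dict(),
            "aic_difference": self.aic_difference,
            "preferred": self.preferred,
            "thresholds": None if self.thresholds is None else self.thresholds.to_dict(),
            "bootstrap": self.bootstrap,
        }


def compare_predictors(
    records: Sequence[AnimalRecord],
    n_boot: int = 0,
    seed: int = 0,
) -> PredictorComparison:
    """Fit sperm presence on mean length and on age and compare by AIC.

    Every record must carry a sperm outcome (excised-organ material).
    The preferred predictor is the one with the lower AIC.  Thresholds
    are inverted from the length fit when it converged with a nonzero
    slope; with ``n_boot > 0`` a parametric bootstrap of the thresholds
    is attached.
    """
    missing = [r.animal_id for r in records if r.sperm_present is None]
    if missing:
        raise ValueError(
            "sperm outcome missing for records: " + ", ".join(missing)
        )
    lengths = np.array([r.mean_length_cm for r in records])
    ages = np.array([r.age_months for r in records])
    y = np.array([int(r.sperm_present) for r in records])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        length_fit = fit_logistic(lengths, y, predictor="mean_length_cm")
        age_fit = fit_logistic(ages, y, predictor="age_months")

    aic_difference = age_fit.aic - length_fit.aic
    preferred = "mean_length_cm" if length_fit.aic <= age_fit.aic else "age_months"
    thresholds = None
    boot = None
    if length_fit.converged and length_fit.slope != 0.0:
        thresholds = threshold_pair(length_fit)
        if n_boot > 0:
            boot = bootstrap_thresholds(length_fit, lengths, n_boot=n_boot, seed=seed)
    return PredictorComparison(
        length_fit=length_fit,
        age_fit=age_fit,
        aic_difference=float(aic_difference),
        preferred=preferred,
        thresholds=thresholds,
        bootstrap=boot,
    )
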