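"""Uncertainty intervals and two-period trend estimation.

Bootstrap percentile intervals resample the sampled units with replacement
and recompute the full estimator — including refitting its models — per
replicate. Analytic intervals use the standard with-replacement
linearization variance of the Hájek ratio mean (reducing to the usual
binomial-proportion SE for the naive estimator). The trend is the
difference of period means; its interval is either the percentile interval
of replicate differences (bootstrap or posterior draws) or the normal
approximation ±1.96 sqrt(var_1 + var_2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import (
    EstimateResult,
    UnitWeights,
    _counts_for,
    build_poststrata,
    doubly_robust_estimate,
    estimate_propensity_weights,
    naive_mean,
    poststratified_mean,
    stratified_subsample_mean,
    superpopulation_estimate,
    weighted_mean,
)
from .frame import PopulationFrame

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapDistribution",
    "TrendResult",
    "make_estimator",
    "bootstrap_percentile_interval",
    "analytic_interval",
    "trend_with_interval",
]

#: Fraction of failed bootstrap replicates tolerated before aborting.
MAX_FAILURE_RATE = 0.05


@dataclass
class BootstrapDistribution:
    method: str
    period: int
    estimates: np.ndarray
    seed: int | None
    n_failed: int = 0


@dataclass
class TrendResult:
    """Between-period change in mean occupancy with a 95% interval."""

    method: str
    point: float
    interval: tuple[float, float]
    interval_method: str


# ---------------------------------------------------------------------------
# estimator registry: uniform callables (frame, period, counts, rng) -> float
# ---------------------------------------------------------------------------

def make_estimator(name: str, **options) -> Callable:
    """Return a self-contained estimator callable for bootstrap use.

    Known names: naive, design, quasirandomization, poststratification,
    superpopulation, doubly_robust, subsampling. The callable signature is
    ``est(frame, period, counts=None, rng=None) -> float`` where ``counts``
    are per-unit sample multiplicities (a bootstrap resample).
    """
    covariates = options.get("covariates", ("elevation", "protected_prop"))
    predictors = options.get("predictors", ("elevation", "protected_prop"))
    model_kind = options.get("model_kind", "logistic")
    elevation_bins = options.get("elevation_bins", 10)
    subsample_size = options.get("size")

    def naive(frame, period, counts=None, rng=None):
        return naive_mean(frame, period, counts).point

    def design(frame, period, counts=None, rng=None):
        from .estimators import design_based_mean

        return design_based_mean(frame, period, counts).point

    def quasirandomization(frame, period, counts=None, rng=None):
        seed = int(rng.integers(2**31 - 1)) if rng is not None else None
        _, w = estimate_propensity_weights(
            frame, period, model_kind=model_kind, covariates=covariates,
            counts=counts, seed=seed,
        )
        return weighted_mean(frame, period, w, counts)

    def poststratification(frame, period, counts=None, rng=None):
        return poststratified_mean(
            frame, period, counts=counts, elevation_bins=elevation_bins
        ).point

    def superpopulation(frame, period, counts=None, rng=None):
        _, est = superpopulation_estimate(frame, period, predictors, counts)
        return est

    def doubly_robust(frame, period, counts=None, rng=None):
        seed = int(rng.integers(2**31 - 1)) if rng is not None else None
        pfit, _ = estimate_propensity_weights(
            frame, period, model_kind=model_kind, covariates=covariates,
            counts=counts, seed=seed,
        )
        sfit, _ = superpopulation_estimate(frame, period, predictors, counts)
        return doubly_robust_estimate(frame, period, pfit, sfit, counts)

    def subsampling(frame, period, counts=None, rng=None):
        seed = int(rng.integers(2**31 - 1)) if rng is not None else None
        strata = build_poststrata(frame, period, elevation_bins, counts=counts)
        mean, _ = stratified_subsample_mean(
            frame, period, strata, size=subsample_size, seed=seed
        )
        return mean

    registry = {
        "naive": naive,
        "design": design,
        "quasirandomization": quasirandomization,
        "poststratification": poststratification,
        "superpopulation": superpopulation,
        "doubly_robust": doubly_robust,
        "subsampling": subsampling,
    }
    try:
        fn = registry[name]
    except KeyError:
        raise ValueError(f"unknown estimator {name!r}; choose from {sorted(registry)}")
    fn.estimator_name = name
    return fn


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_percentile_interval(
    frame: PopulationFrame,
    period: int,
    estimator: Callable | str,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[BootstrapDistribution, tuple[float, float]]:
    """Percentile interval from B with-replacement resamples of the sample.

    Each replicate draws n units from the sampled units with replacement
    (represented as per-unit multiplicities, so the population frame is
    untouched) and recomputes the estimator from scratch. Replicates in
    which the estimator fails are dropped and counted; more than 5%
    failures aborts.
    """
    if isinstance(estimator, str):
        estimator = make_estimator(estimator)
    rng = np.random.default_rng(seed)
    R = frame.R(period)
    sampled_idx = np.flatnonzero(R)
    n = len(sampled_idx)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 sampled units")

    estimates = []
    n_failed = 0
    for b in range(B):
        draw = rng.choice(sampled_idx, size=n, replace=True)
        counts = np.bincount(draw, minlength=frame.N).astype(float)
        try:
            estimates.append(estimator(frame, period, counts, rng))
        except Exception as exc:  # noqa: BLE001 — replicate-level isolation
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
            if n_failed > MAX_FAILURE_RATE * B:
                raise RuntimeError(
                    f"more than {MAX_FAILURE_RATE:.0%} of bootstrap replicates failed"
                ) from exc
    est = np.asarray(estimates)
    alpha = 1 - level
    lo, hi = np.quantile(est, [alpha / 2, 1 - alpha / 2])
    name = getattr(estimator, "estimator_name", getattr(estimator, "__name__", "custom"))
    dist = BootstrapDistribution(
        method=name, period=period, estimates=est, seed=seed, n_failed=n_failed
    )
    return dist, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# analytic (linearization) intervals
# ---------------------------------------------------------------------------

def _ratio_mean_se(y: np.ndarray, w: np.ndarray) -> float:
    """With-replacement linearization SE of the Hájek mean sum(wy)/sum(w)."""
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 sampled units for an analytic SE")
    wsum = w.sum()
    ybar = np.dot(w, y) / wsum
    e = w * (y - ybar) / wsum
    return float(np.sqrt(n / (n - 1) * np.sum(e**2)))


def analytic_interval(
    frame: PopulationFrame,
    period: int,
    weights: UnitWeights | None = None,
    level: float = 0.95,
    counts: np.ndarray | None = None,
) -> EstimateResult:
    """Normal-approximation interval for a (possibly weighted) sample mean.

    With ``weights=None`` this is the naive estimator's binomial-proportion
    interval, SE = sqrt(p(1-p)/(n-1)); with weights it is the standard
    survey linearization SE of the weighted ratio mean, which reduces to
    the naive formula when all weights are equal.
    """
    m = _counts_for(frame, period, counts)
    sampled = m > 0
    y = frame.y(period).astype(float)[sampled]
    if weights is None:
        w = m[sampled]
        method = "naive"
    else:
        ids = frame.data["unit_id"].to_numpy()[sampled]
        w = pd.Series(weights.w, index=weights.unit_ids).loc[ids].to_numpy() * m[sampled]
        method = weights.method
    point = float(np.dot(w, y) / w.sum())
    se = _ratio_mean_se(y, w)
    z = norm.ppf(0.5 + level / 2)
    return EstimateResult(
        method=method,
        period=period,
        point=point,
        interval=(point - z * se, point + z * se),
        interval_method="normal",
        diagnostics={"se": se},
    )


# ---------------------------------------------------------------------------
# trend
# ---------------------------------------------------------------------------

def trend_with_interval(
    result1: EstimateResult,
    result2: EstimateResult,
    mode: str = "percentile",
    level: float = 0.95,
) -> TrendResult:
    """Trend = period-2 mean minus period-1 mean, with a 95% interval.

    ``mode="percentile"`` pairs the two periods' replicate distributions
    (bootstrap estimates or posterior draws, resampled independently) and
    takes percentiles of the differences. ``mode="normal"`` uses
    point ± z sqrt(var_1 + var_2) with variances recovered from the
    periods' normal intervals.
    """
    if result1.method != result2.method:
        raise ValueError(
            f"trend requires the same method in both periods; got "
            f"{result1.method!r} and {result2.method!r}"
        )
    point = result2.point - result1.point
    alpha = 1 - level
    if mode == "percentile":
        if result1.draws is None or result2.draws is None:
            raise ValueError("percentile trend interval needs replicate distributions")
        d1, d2 = np.asarray(result1.draws), np.asarray(result2.draws)
        k = min(len(d1), len(d2))
        diffs = d2[:k] - d1[:k]
        lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    elif mode == "normal":
        z = norm.ppf(0.5 + level / 2)
        ses = []
        for r in (result1, result2):
            if r.diagnostics.get("se") is not None:
                ses.append(r.diagnostics["se"])
            elif r.interval is not None:
                ses.append((r.interval[1] - r.interval[0]) / (2 * z))
            else:
                raise ValueError("normal trend interval needs per-period SEs")
        half = z * float(np.hypot(*ses))
        lo, hi = point - half, point + half
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TrendResult(
        method=result1.method,
        point=point,
        interval=(float(lo), float(hi)),
        interval_method=mode,
    )
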