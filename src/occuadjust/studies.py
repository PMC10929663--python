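"""Replicated simulation studies over synthetic landscapes.

These are the experiments the package's validation rests on, shared by the
analysis drivers, the test suite and the acceptance script:

* :func:`bias_study` — hold a finite population fixed, redraw the inclusion
  mechanism many times, and measure each estimator's bias against the known
  population mean (the adjusted estimators should beat the naive mean when
  the auxiliaries are informative and inclusion is MAR given them);
* :func:`unbiasedness_checks` — the design-based estimator with true
  inclusion probabilities, poststratification under stratum-driven
  inclusion, and the doubly robust estimator with exactly one correct
  component, each of which should be unbiased; plus the both-wrong negative
  control, which should not;
* :func:`coverage_study` — simulate many replicate worlds, build a 95%
  interval in each, and count how often it covers the truth; under a
  violation of the MAR assumption the adjusted estimators' coverage
  collapses, which is the headline caution about trusting nominal
  intervals from adjusted nonprobability samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    PropensityFit,
    SuperpopulationFit,
    design_based_mean,
    doubly_robust_estimate,
    naive_mean,
    poststratified_mean,
    superpopulation_estimate,
)
from .frame import PopulationFrame, SyntheticConfig, population_mean, simulate_frame
from .mrp import mrp_estimate
from .uncertainty import analytic_interval, bootstrap_percentile_interval, make_estimator

__all__ = [
    "bias_study",
    "unbiasedness_checks",
    "coverage_study",
    "resample_inclusion",
]


def resample_inclusion(
    frame: PopulationFrame,
    p_incl: np.ndarray,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """One fresh Bernoulli inclusion realization as a counts vector."""
    for _ in range(max_retries):
        R = (rng.random(frame.N) < p_incl).astype(float)
        if 0 < R.sum() < frame.N:
            return R
    raise RuntimeError("degenerate inclusion design in replication study")


def bias_study(
    frame: PopulationFrame,
    period: int,
    methods: tuple[str, ...] = (
        "naive",
        "quasirandomization",
        "poststratification",
        "superpopulation",
        "doubly_robust",
        "subsampling",
    ),
    n_replicates: int = 200,
    seed: int | None = None,
    mrp_replicates: int = 0,
    mrp_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Replicate the inclusion mechanism; measure each estimator's bias.

    The population (and hence the true mean) is fixed; only the sample
    inclusion R is redrawn from the frame's true inclusion probabilities.
    MRP is orders of magnitude slower than the rest, so it gets its own
    (smaller) replicate count; 0 skips it.

    Returns one row per method: mean error, |bias|, Monte-Carlo SE, and the
    replicate count.
    """
    p = frame.p_true(period)
    if p is None:
        raise ValueError("bias_study needs a synthetic frame with p_true")
    truth = population_mean(frame, period)
    rng = np.random.default_rng(seed)

    estimators = {m: make_estimator(m) for m in methods if m != "mrp"}
    errors: dict[str, list[float]] = {m: [] for m in methods}

    for _ in range(n_replicates):
        counts = resample_inclusion(frame, p, rng)
        for m, est in estimators.items():
            errors[m].append(est(frame, period, counts, rng) - truth)

    if "mrp" in methods and mrp_replicates > 0:
        kw = {"chains": 2, "iterations": 800, **(mrp_kwargs or {})}
        for _ in range(mrp_replicates):
            counts = resample_inclusion(frame, p, rng)
            res = mrp_estimate(
                frame, period, counts=counts,
                seed=int(rng.integers(2**31 - 1)), **kw,
            )
            errors["mrp"].append(res.point - truth)

    rows = []
    for m in methods:
        err = np.asarray(errors[m])
        if len(err) == 0:
            continue
        rows.append(
            {
                "method": m,
                "mean_error": err.mean(),
                "abs_bias": abs(err.mean()),
                "mc_se": err.std(ddof=1) / np.sqrt(len(err)),
                "n_replicates": len(err),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class UnbiasednessResult:
    label: str
    abs_bias: float
    mc_se: float
    n_replicates: int

    @property
    def within_3se(self) -> bool:
        return self.abs_bias < 3 * self.mc_se


def unbiasedness_checks(
    N: int = 5000,
    n_replicates: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimators that should (and one that should not) recover the truth.

    Four studies on one synthetic population, each over ``n_replicates``
    fresh inclusion draws:

    * ``design_true_p``      — Hájek with the true inclusion probabilities;
    * ``poststrat_stratum_inclusion`` — poststratification when inclusion
      probability is constant within each poststratum (MAR within strata);
    * ``dr_correct_propensity``  — doubly robust, true propensity, junk
      constant outcome model (population and outcome held fixed; only the
      inclusion draw is replicated);
    * ``dr_correct_outcome``     — doubly robust, junk propensity, the TRUE
      conditional occupancy probability as the outcome model; here the
      outcome is redrawn each replicate (a fixed realized outcome vector
      has residuals that correlate with any covariate-driven propensity, so
      "correct outcome model" is only meaningful under outcome redraws);
    * ``dr_both_wrong``          — the negative control: junk propensity
      and junk outcome model, whose bias should NOT vanish.
    """
    from scipy.special import expit

    from .frame import standardized_aux

    cfg = SyntheticConfig(N=N, seed=seed)
    frame = simulate_frame(cfg)
    period = 1
    truth = population_mean(frame, period)
    p = frame.p_true(period)
    rng = np.random.default_rng(seed + 1)

    # stratum-only inclusion probabilities for the poststratification check
    from .estimators import build_poststrata

    strata = build_poststrata(frame, period)
    stratum_p = rng.uniform(0.1, 0.8, size=strata.n_strata)
    p_stratum = stratum_p[strata.labels]

    X = np.column_stack([np.ones(frame.N), frame.aux()])
    design_z = np.column_stack([np.ones(frame.N), standardized_aux(frame)])
    prob_y = expit(design_z @ cfg.occupancy_coefs_by_period()[period])

    # junk models
    junk_yhat = np.full(frame.N, 0.9)
    junk_p = np.clip(0.9 - 0.8 * (frame.data["elevation"].to_numpy()
                                  > np.median(frame.data["elevation"])), 0.05, 1.0)

    def dr(fr, counts, p_hat, y_hat):
        sampled = counts > 0
        pfit = PropensityFit("study", p_hat, ())
        sfit = SuperpopulationFit(
            beta=np.zeros(1), y_hat=y_hat,
            residuals=(fr.y(period) - y_hat)[sampled],
            predictors=(), design=X, sampled=sampled, counts=counts,
        )
        return doubly_robust_estimate(fr, period, pfit, sfit, counts)

    # working frame whose outcome column is redrawn for the correct-outcome
    # study (inclusion depends on the auxiliaries only, so y and R redraws
    # are independent given x)
    redraw = PopulationFrame(frame.data.copy(), frame.periods)

    errs: dict[str, list[float]] = {
        "design_true_p": [],
        "poststrat_stratum_inclusion": [],
        "dr_correct_propensity": [],
        "dr_correct_outcome": [],
        "dr_both_wrong": [],
    }
    for _ in range(n_replicates):
        counts = resample_inclusion(frame, p, rng)
        errs["design_true_p"].append(
            design_based_mean(frame, period, counts).point - truth
        )
        errs["dr_correct_propensity"].append(dr(frame, counts, p, junk_yhat) - truth)
        errs["dr_both_wrong"].append(dr(frame, counts, junk_p, junk_yhat) - truth)

        y_new = (rng.random(frame.N) < prob_y).astype(np.int8)
        redraw.data[f"y_{period}"] = y_new
        counts_y = resample_inclusion(redraw, p, rng)
        errs["dr_correct_outcome"].append(
            dr(redraw, counts_y, junk_p, prob_y) - y_new.mean()
        )

        counts_s = resample_inclusion(frame, p_stratum, rng)
        errs["poststrat_stratum_inclusion"].append(
            poststratified_mean(frame, period, counts=counts_s).point - truth
        )

    rows = []
    for label, err in errs.items():
        err = np.asarray(err)
        rows.append(
            {
                "study": label,
                "abs_bias": abs(err.mean()),
                "mc_se": err.std(ddof=1) / np.sqrt(len(err)),
                "n_replicates": len(err),
            }
        )
    return pd.DataFrame(rows)


def coverage_study(
    base_config: SyntheticConfig,
    methods: tuple[str, ...] = ("poststratification", "superpopulation"),
    n_worlds: int = 200,
    B: int = 200,
    period: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Interval coverage of the true mean over independently simulated worlds.

    Each world draws a fresh population and sample from ``base_config``
    (reseeded), builds each method's 95% interval (analytic for
    poststratification and naive, percentile bootstrap otherwise), and
    checks whether it covers that world's true mean. With ``gamma_y != 0``
    in the config the MAR assumption fails and coverage falls below
    nominal.
    """
    import dataclasses as _dc

    rng = np.random.default_rng(seed)
    hits = {m: 0 for m in methods}
    for w in range(n_worlds):
        cfg = _dc.replace(base_config, seed=int(rng.integers(2**31 - 1)))
        frame = simulate_frame(cfg)
        truth = population_mean(frame, period)
        for m in methods:
            if m in ("naive", "poststratification"):
                if m == "naive":
                    res = analytic_interval(frame, period)
                else:
                    from .estimators import build_poststrata, poststratification_weights

                    uw = poststratification_weights(build_poststrata(frame, period))
                    res = analytic_interval(frame, period, weights=uw)
                lo, hi = res.interval
            else:
                est = make_estimator(m)
                _, (lo, hi) = bootstrap_percentile_interval(
                    frame, period, est, B=B, seed=int(rng.integers(2**31 - 1))
                )
            hits[m] += lo <= truth <= hi
    return pd.DataFrame(
        [
            {"method": m, "coverage": hits[m] / n_worlds, "n_worlds": n_worlds, "B": B}
            for m in methods
        ]
    )
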