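"""Estimators of a finite population's mean occupancy from a biased sample.

Every estimator targets the same quantity, the population mean

    ybar_N = (1/N) * sum_i y_i,

and most can be written as a Hájek ratio over the sampled units,

    ybar_w = sum_{i in s} w_i y_i / sum_{i in s} w_i,

so that an adjustment method is, operationally, a recipe for the weights w:

* naive          — w constant (no adjustment);
* design-based   — w = 1/p with known inclusion probabilities p;
* quasirandomization — w = 1/p_hat with p_hat from a binary model of the
  inclusion indicator on covariates fitted over the whole frame;
* poststratification — w = N_j/n_j within crossed auxiliary categories;
* superpopulation — a linear outcome model predicts y for nonsampled units;
  its estimate has an exact implied-weight representation;
* doubly robust  — propensity-weighted outcome-model residuals correct the
  superpopulation prediction; unbiased if either component is right;
* subsampling    — a stratified miniature of the population drawn from the
  sample, whose plain mean is the estimate.

All estimators accept an optional ``counts`` vector of per-unit sample
multiplicities (defaulting to the frame's inclusion indicator), which is how
the bootstrap re-enters each estimator without copying the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .frame import PopulationFrame

logger = logging.getLogger(__name__)

__all__ = [
    "UnitWeights",
    "PropensityFit",
    "StratumTable",
    "SuperpopulationFit",
    "EstimateResult",
    "naive_mean",
    "weighted_mean",
    "estimate_propensity_weights",
    "build_poststrata",
    "poststratification_weights",
    "superpopulation_estimate",
    "superpopulation_implied_weights",
    "doubly_robust_estimate",
    "stratified_subsample_mean",
]

DEFAULT_AUXILIARIES = ("elevation", "protected_prop")

#: Lower clip for estimated inclusion probabilities; reciprocals stay finite.
PROPENSITY_CLIP = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class UnitWeights:
    """Positive per-sampled-unit weights with method provenance.

    ``normalization`` records what the weight total targets: ``"N"`` for
    calibrated weights, ``"n"`` for constant naive weights, ``"arbitrary"``
    otherwise. Superpopulation implied weights may be negative.
    """

    unit_ids: np.ndarray
    w: np.ndarray
    method: str
    normalization: str = "arbitrary"

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.w = np.asarray(self.w, dtype=float)
        if len(self.unit_ids) != len(self.w):
            raise ValueError("unit_ids and w must have equal length")
        if self.method != "superpopulation" and np.any(self.w <= 0):
            raise ValueError(f"{self.method} weights must all be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "weight": self.w})


@dataclass
class PropensityFit:
    """Estimated (pseudo-)inclusion probabilities for every population unit."""

    model_kind: str
    p_hat: np.ndarray
    covariates: tuple[str, ...]
    n_clipped: int = 0
    model: object = None


@dataclass
class StratumTable:
    """Crossed auxiliary categories with population and sample counts.

    ``table`` has one row per stratum (``stratum``, ``Nj``, ``nj``);
    ``labels`` assigns every population unit to exactly one stratum (as an
    integer index into ``table``). Strata whose elevation bin ended up with
    population units but no sampled units are collapsed into a neighbouring
    elevation bin (standard survey practice), and the collapse is logged.
    """

    table: pd.DataFrame
    labels: np.ndarray
    period: int
    counts: np.ndarray
    unit_ids: np.ndarray | None = None

    @property
    def n_strata(self) -> int:
        return len(self.table)

    @property
    def N(self) -> int:
        return int(self.table["Nj"].sum())

    @property
    def n(self) -> int:
        return int(self.table["nj"].sum())


@dataclass
class SuperpopulationFit:
    """Least-squares outcome model fitted on the sampled units."""

    beta: np.ndarray
    y_hat: np.ndarray            # fitted value for every population unit
    residuals: np.ndarray        # y - y_hat on sampled units (count order)
    predictors: tuple[str, ...]
    design: np.ndarray           # full-population design matrix (with intercept)
    sampled: np.ndarray          # boolean mask over the frame
    counts: np.ndarray


@dataclass
class EstimateResult:
    """Method x period point estimate with an optional 95% interval."""

    method: str
    period: int
    point: float
    interval: tuple[float, float] | None = None
    interval_method: str = "none"
    draws: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _counts_for(frame: PopulationFrame, period: int, counts: np.ndarray | None) -> np.ndarray:
    if counts is None:
        return frame.R(period).astype(float)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (frame.N,):
        raise ValueError(f"counts must have one entry per population unit (shape {(frame.N,)})")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return counts


# ---------------------------------------------------------------------------
# basic estimators
# ---------------------------------------------------------------------------

def naive_mean(
    frame: PopulationFrame, period: int, counts: np.ndarray | None = None
) -> EstimateResult:
    """Unadjusted sample mean: every sampled unit gets weight 1/n."""
    m = _counts_for(frame, period, counts)
    n = m.sum()
    if n == 0:
        raise ValueError("empty sample: no units included in this period")
    point = float(np.dot(m, frame.y(period)) / n)
    return EstimateResult(method="naive", period=period, point=point)


def weighted_mean(
    frame: PopulationFrame,
    period: int,
    weights: UnitWeights,
    counts: np.ndarray | None = None,
) -> float:
    """Hájek ratio estimate sum(w y)/sum(w) over the sampled units.

    Invariant under any positive rescaling of the weights. The weights must
    cover exactly the units in the sample.
    """
    m = _counts_for(frame, period, counts)
    sampled = m > 0
    ids = frame.data["unit_id"].to_numpy()[sampled]
    order = pd.Series(np.arange(len(weights.unit_ids)), index=weights.unit_ids)
    if len(weights.unit_ids) != sampled.sum() or not np.isin(ids, weights.unit_ids).all():
        raise ValueError("weights must cover exactly the sampled units")
    w = weights.w[order.loc[ids].to_numpy()]
    mw = m[sampled] * w
    total = mw.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float(np.dot(mw, frame.y(period)[sampled]) / total)


def design_based_mean(
    frame: PopulationFrame, period: int, counts: np.ndarray | None = None
) -> EstimateResult:
    """Hájek estimator with the *true* inclusion probabilities (synthetic only)."""
    p = frame.p_true(period)
    if p is None:
        raise ValueError("design-based estimation needs true inclusion probabilities")
    m = _counts_for(frame, period, counts)
    sampled = m > 0
    w = UnitWeights(
        unit_ids=frame.data["unit_id"].to_numpy()[sampled],
        w=1.0 / p[sampled],
        method="design",
        normalization="N",
    )
    return EstimateResult(
        method="design", period=period, point=weighted_mean(frame, period, w, counts)
    )


# ---------------------------------------------------------------------------
# quasirandomization
# ---------------------------------------------------------------------------

def estimate_propensity_weights(
    frame: PopulationFrame,
    period: int,
    model_kind: str = "logistic",
    covariates: Sequence[str] = DEFAULT_AUXILIARIES,
    counts: np.ndarray | None = None,
    clip: float = PROPENSITY_CLIP,
    seed: int | None = None,
) -> tuple[PropensityFit, UnitWeights]:
    """Fit pseudo-inclusion probabilities and return their reciprocal weights.

    Inclusion status is known for every population unit, so this is a
    prediction problem: a binary model of the inclusion indicator on the
    covariates is fitted over the whole frame. Fitted probabilities are
    clipped to ``[clip, 1]`` before inversion.

    ``model_kind`` is ``"logistic"`` (default; essentially unpenalized) or
    ``"forest"`` (a random-forest classifier, whose out-of-bag-style
    probabilities can hit 0 and rely on the clip).
    """
    m = _counts_for(frame, period, counts)
    target = (m > 0).astype(int)
    if target.min() == target.max():
        raise ValueError("inclusion indicator is constant over the frame; nothing to model")
    X = frame.data[list(covariates)].to_numpy(dtype=float)
    sample_weight = np.where(target == 1, np.maximum(m, 1.0), 1.0)

    if model_kind == "logistic":
        model = LogisticRegression(C=1e6, max_iter=2000)
    elif model_kind == "forest":
        model = RandomForestClassifier(
            n_estimators=100, min_samples_leaf=20, random_state=seed, n_jobs=1
        )
    else:
        raise ValueError(f"unknown propensity model kind {model_kind!r}")
    model.fit(X, target, sample_weight=sample_weight)
    p_raw = model.predict_proba(X)[:, 1]
    n_clipped = int(np.sum(p_raw < clip))
    if n_clipped:
        logger.info("propensity: clipped %d probabilities below %g", n_clipped, clip)
    p_hat = np.clip(p_raw, clip, 1.0)

    fit = PropensityFit(
        model_kind=model_kind,
        p_hat=p_hat,
        covariates=tuple(covariates),
        n_clipped=n_clipped,
        model=model,
    )
    sampled = m > 0
    weights = UnitWeights(
        unit_ids=frame.data["unit_id"].to_numpy()[sampled],
        w=1.0 / p_hat[sampled],
        method="quasirandomization",
        normalization="N",
    )
    return fit, weights


# ---------------------------------------------------------------------------
# poststratification
# ---------------------------------------------------------------------------

def build_poststrata(
    frame: PopulationFrame,
    period: int,
    elevation_bins: int = 10,
    protected_rule: str = "0_vs_pos",
    counts: np.ndarray | None = None,
    collapse_empty: bool = True,
) -> StratumTable:
    """Cross discretized auxiliaries into poststrata with counts Nj, nj.

    Elevation is cut at its population deciles (left-open/right-closed,
    tied cut points collapsed); the protected-area proportion is
    dichotomized at 0 versus >0 (``protected_rule="0_vs_pos"``; ``"none"``
    skips the split). The default 10 x 2 crossing yields 20 poststrata.
    Population strata left without sampled units are collapsed into the
    nearest elevation bin within the same protected class.
    """
    m = _counts_for(frame, period, counts)
    elev = frame.data["elevation"].to_numpy(dtype=float)
    if len(np.unique(elev)) < elevation_bins:
        raise ValueError("elevation has fewer distinct values than requested bins")

    qs = np.quantile(elev, np.linspace(0, 1, elevation_bins + 1))
    inner = np.unique(qs[1:-1])
    if len(inner) < elevation_bins - 1:
        logger.warning(
            "tied elevation deciles: collapsing to %d bins", len(inner) + 1
        )
    # left-open/right-closed: unit goes to the first bin whose upper cut >= value
    elev_bin = np.searchsorted(inner, elev, side="left")
    if protected_rule == "0_vs_pos":
        prot_bin = (frame.data["protected_prop"].to_numpy(dtype=float) > 0).astype(int)
    elif protected_rule == "none":
        prot_bin = np.zeros(frame.N, dtype=int)
    else:
        raise ValueError(f"unknown protected_rule {protected_rule!r}")

    n_elev = len(inner) + 1
    cell = elev_bin * 2 + prot_bin  # stratum index before collapsing

    # collapse population cells with no sampled units into a neighbouring
    # elevation bin of the same protected class
    if collapse_empty:
        for _ in range(n_elev):
            Nj = np.bincount(cell, minlength=2 * n_elev)
            nj = np.bincount(cell, weights=m, minlength=2 * n_elev)
            bad = np.flatnonzero((Nj > 0) & (nj == 0))
            if len(bad) == 0:
                break
            j = bad[0]
            e, pcls = divmod(j, 2)
            neighbours = [
                (e + d) * 2 + pcls
                for d in (-1, 1)
                if 0 <= e + d < n_elev and nj[(e + d) * 2 + pcls] > 0
            ]
            if not neighbours:  # fall back to any sampled cell in the class
                same_class = [k for k in range(pcls, 2 * n_elev, 2) if nj[k] > 0]
                if not same_class:
                    raise ValueError(
                        f"protected class {pcls} contains no sampled units; cannot collapse"
                    )
                neighbours = [min(same_class, key=lambda k: abs(k // 2 - e))]
            tgt = max(neighbours, key=lambda k: nj[k])
            logger.info("collapsing empty poststratum %d into %d", j, tgt)
            cell[cell == j] = tgt

    keys, labels = np.unique(cell, return_inverse=True)
    Nj = np.bincount(labels)
    nj = np.bincount(labels, weights=m)
    elev_cat = keys // 2
    prot_cat = keys % 2
    table = pd.DataFrame(
        {
            "stratum": [f"elev{e}_prot{p}" for e, p in zip(elev_cat, prot_cat)],
            "elev_cat": elev_cat,
            "prot_cat": prot_cat,
            "Nj": Nj,
            "nj": nj,
        }
    )
    return StratumTable(
        table=table,
        labels=labels,
        period=period,
        counts=m,
        unit_ids=frame.data["unit_id"].to_numpy(),
    )


def poststratification_weights(strata: StratumTable) -> UnitWeights:
    """Weight N_j/n_j for every sampled unit in stratum j; totals N exactly."""
    nj = strata.table["nj"].to_numpy(dtype=float)
    Nj = strata.table["Nj"].to_numpy(dtype=float)
    if np.any((Nj > 0) & (nj == 0)):
        raise ValueError(
            "nonempty poststratum without sampled units; rebuild with collapse_empty=True"
        )
    m = strata.counts
    sampled = m > 0
    w = (Nj / np.where(nj > 0, nj, np.nan))[strata.labels[sampled]]
    ids = (
        strata.unit_ids[sampled]
        if strata.unit_ids is not None
        else np.flatnonzero(sampled)
    )
    return UnitWeights(
        unit_ids=ids,
        w=w,
        method="poststratification",
        normalization="N",
    )


def poststratified_mean(
    frame: PopulationFrame,
    period: int,
    strata: StratumTable | None = None,
    counts: np.ndarray | None = None,
    elevation_bins: int = 10,
) -> EstimateResult:
    """Poststratified Hájek estimate (weights N_j/n_j)."""
    if strata is None:
        strata = build_poststrata(frame, period, elevation_bins, counts=counts)
    uw = poststratification_weights(strata)
    point = weighted_mean(frame, period, uw, counts=strata.counts)
    return EstimateResult(method="poststratification", period=period, point=point)


# ---------------------------------------------------------------------------
# superpopulation modelling
# ---------------------------------------------------------------------------

def _design_matrix(frame: PopulationFrame, predictors: Sequence[str]) -> np.ndarray:
    if len(predictors) and isinstance(predictors[0], str):
        X = frame.data[list(predictors)].to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
    return np.column_stack([np.ones(frame.N), X])


def superpopulation_estimate(
    frame: PopulationFrame,
    period: int,
    predictors: Sequence[str] | np.ndarray = DEFAULT_AUXILIARIES,
    counts: np.ndarray | None = None,
) -> tuple[SuperpopulationFit, float]:
    """Linear outcome model on the sample; predictions fill in the rest.

    The model is fitted by least squares on the sampled units and the
    estimate is (sum of sampled y + sum of predicted y over nonsampled
    units) / N. A linear (not logistic) model is used deliberately: it
    admits an exact unit-weight representation
    (:func:`superpopulation_implied_weights`), so the estimator's effect on
    the sample's auxiliary distributions can be inspected. Predictions are
    not clipped to [0, 1] — clipping would break the weight identity — so
    the estimate can stray slightly outside the unit interval.

    ``predictors`` is a list of frame columns, or a ready-made (N, k) array
    of regressors (no intercept; one is added).
    """
    m = _counts_for(frame, period, counts)
    sampled = m > 0
    X = _design_matrix(frame, predictors)
    y = frame.y(period).astype(float)

    Xs = X[sampled] * np.sqrt(m[sampled])[:, None]
    ys = y[sampled] * np.sqrt(m[sampled])
    rank = np.linalg.matrix_rank(Xs)
    if rank < X.shape[1]:
        # name the offending columns via the QR pivot sizes
        _, Rqr = np.linalg.qr(Xs)
        diag = np.abs(np.diag(Rqr))
        bad = np.flatnonzero(diag < 1e-8 * diag.max())
        names = ["intercept"] + [
            predictors[i] if isinstance(predictors[0], str) else f"x{i}"
            for i in range(X.shape[1] - 1)
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient design on sampled units; collinear columns: "
            f"{[names[i] for i in bad]}"
        )
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    y_hat = X @ beta

    estimate = float((y[sampled].sum() + y_hat[~sampled].sum()) / frame.N)
    fit = SuperpopulationFit(
        beta=beta,
        y_hat=y_hat,
        residuals=(y - y_hat)[sampled],
        predictors=tuple(predictors) if isinstance(predictors[0], str) else ("array",),
        design=X,
        sampled=sampled,
        counts=m,
    )
    return fit, estimate


def superpopulation_implied_weights(
    fit: SuperpopulationFit, frame: PopulationFrame
) -> UnitWeights:
    """Exact unit weights reproducing the superpopulation estimate.

    For a least-squares fit with intercept on sampled units s,

        w_i = 1 + t_xbar' (X_s' X_s)^{-1} x_i,      t_xbar = sum_{i not in s} x_i,

    gives sum_{i in s} w_i y_i = N * ybar_sp and sum w_i = N (a calibration
    identity), so the Hájek form returns the model estimate exactly.
    Weights may be negative.
    """
    if not np.allclose(fit.counts[fit.sampled], 1.0):
        raise ValueError("implied weights are defined for the unweighted sample fit")
    X = fit.design
    s = fit.sampled
    Xs = X[s]
    XtX = Xs.T @ Xs
    try:
        t_proj = np.linalg.solve(XtX, X[~s].sum(axis=0))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular X_s'X_s; cannot form implied weights") from e
    w = 1.0 + Xs @ t_proj
    return UnitWeights(
        unit_ids=frame.data["unit_id"].to_numpy()[s],
        w=w,
        method="superpopulation",
        normalization="N",
    )


# ---------------------------------------------------------------------------
# doubly robust
# ---------------------------------------------------------------------------

def doubly_robust_estimate(
    frame: PopulationFrame,
    period: int,
    propensity: PropensityFit,
    superpop: SuperpopulationFit,
    counts: np.ndarray | None = None,
) -> float:
    """Propensity-corrected outcome-model estimate.

        ybar_dr = (1/N) sum_{i in s} r_i / p_hat_i + (1/N) sum_{i=1..N} yhat_i

    with r_i the outcome-model residuals on the sample. Unbiased when either
    the propensity model or the outcome model is correctly specified; when
    the outcome model is exact the first term vanishes and the estimate
    equals the model prediction term.
    """
    m = _counts_for(frame, period, counts)
    sampled = m > 0
    p = propensity.p_hat[sampled]
    if np.any(p == 0):
        raise ZeroDivisionError("estimated inclusion probability of 0 among sampled units")
    y = frame.y(period).astype(float)
    r = y[sampled] - superpop.y_hat[sampled]
    correction = float(np.sum(m[sampled] * r / p) / frame.N)
    model_term = float(superpop.y_hat.sum() / frame.N)
    return correction + model_term


# ---------------------------------------------------------------------------
# stratified subsampling
# ---------------------------------------------------------------------------

def _largest_remainder_allocation(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``shares`` summing exactly to ``total``."""
    raw = shares / shares.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def stratified_subsample_mean(
    frame: PopulationFrame,
    period: int,
    strata: StratumTable | None = None,
    size: int | None = None,
    seed: int | None = None,
    n_replicates: int = 1,
    counts: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean occupancy of a stratified with-replacement miniature of the population.

    From each poststratum j, round(size * N_j / N) sampled units are drawn
    with replacement (largest-remainder rounding, so draws total ``size``
    exactly; default size N/10). The subsample mean estimates the population
    mean; its expectation over draws equals the poststratified estimate.

    Returns ``(mean of replicate means, replicate means)``.
    """
    if strata is None:
        strata = build_poststrata(frame, period, counts=counts)
    if size is None:
        size = max(1, frame.N // 10)
    rng = np.random.default_rng(seed)
    m = strata.counts
    Nj = strata.table["Nj"].to_numpy(dtype=float)
    nj = strata.table["nj"].to_numpy(dtype=float)
    alloc = _largest_remainder_allocation(Nj, int(size))
    if np.any((alloc > 0) & (nj == 0)):
        raise ValueError("allocation to a stratum with no sampled units")

    y = frame.y(period).astype(float)
    reps = np.empty(n_replicates)
    # per-stratum sampled ys and draw probabilities (proportional to multiplicity)
    per_stratum = []
    for j in range(strata.n_strata):
        in_j = (strata.labels == j) & (m > 0)
        probs = m[in_j] / m[in_j].sum() if in_j.any() else None
        per_stratum.append((y[in_j], probs))
    for b in range(n_replicates):
        tot = 0.0
        for j, a in enumerate(alloc):
            if a == 0:
                continue
            yj, probs = per_stratum[j]
            tot += rng.choice(yj, size=a, replace=True, p=probs).sum()
        reps[b] = tot / size
    return float(reps.mean()), reps
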