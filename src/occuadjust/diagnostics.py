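"""Representativeness diagnostics for nonprobability samples.

The central quantity is the data defect correlation (ddc): the finite-
population Pearson correlation between the sample-inclusion indicator R and
the variable of interest y. Under simple random sampling the ddc is of
order N^(-1/2); an appreciable ddc signals an unrepresentative sample. The
ddc drives an exact decomposition of the naive sample mean's error,

    ybar_n - ybar_N = ddc * sqrt((N - n)/n) * sigma_y,

with sigma_y the population (1/N-convention) standard deviation — the
"data quantity" factor sqrt((N-n)/n) shows why a large biased sample can be
worse than a small random one. The partial ddc conditions both R and y on
the auxiliary variables by linear projection; it is near zero when the
missing-at-random-given-auxiliaries assumption holds.

Binned relative-frequency comparisons assess whether a weighting adjustment
moved the sample's auxiliary distribution toward the population's, scored
by mean absolute error (MAE) over 50 equal-width bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import UnitWeights, _counts_for
from .frame import PopulationFrame

__all__ = [
    "DdcReport",
    "BinnedComparison",
    "data_defect_correlation",
    "partial_ddc",
    "meng_error_decomposition",
    "binned_relative_frequency_comparison",
]


@dataclass
class DdcReport:
    """ddc diagnostics and the exact error decomposition for one period."""

    period: int
    ddc: float
    naive_error: float            # ybar_n - ybar_N
    data_quantity: float          # sqrt((N - n)/n)
    sigma_y: float                # population SD of y (1/N convention)
    identity_residual: float      # naive_error - ddc * data_quantity * sigma_y
    partial_ddc: float | None = None


@dataclass
class BinnedComparison:
    """Population vs sample vs weighted-sample distribution of one auxiliary."""

    auxiliary: str
    edges: np.ndarray
    population_freq: np.ndarray
    sample_freq: np.ndarray
    weighted_freq: np.ndarray
    mae_raw: float
    mae_weighted: float


def _pop_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with population (1/N) moments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def data_defect_correlation(frame: PopulationFrame, period: int) -> float:
    """corr(R, y) over all N population units."""
    return _pop_corr(frame.R(period), frame.y(period))


def partial_ddc(
    frame: PopulationFrame,
    period: int,
    auxiliaries: tuple[str, ...] = ("elevation", "protected_prop"),
) -> float:
    """ddc after linearly projecting the auxiliaries out of both R and y.

    Computed as the Pearson correlation of the residuals of least-squares
    projections of R and y on (1, auxiliaries) over all N units. Near zero
    when y is independent of inclusion given the auxiliaries (and the
    dependence is approximately linear in them).
    """
    X = np.column_stack([np.ones(frame.N), frame.aux(auxiliaries)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear auxiliaries; partial ddc undefined")
    R = frame.R(period).astype(float)
    y = frame.y(period).astype(float)
    coef, *_ = np.linalg.lstsq(X, np.column_stack([R, y]), rcond=None)
    resid = np.column_stack([R, y]) - X @ coef
    return _pop_corr(resid[:, 0], resid[:, 1])


def meng_error_decomposition(frame: PopulationFrame, period: int) -> DdcReport:
    """Exact decomposition of the naive estimator's error.

    Verifies ybar_n - ybar_N = ddc * sqrt((N-n)/n) * sigma_y and reports the
    (floating-point) residual of the identity alongside its three factors.
    """
    y = frame.y(period).astype(float)
    R = frame.R(period)
    N = frame.N
    n = int(R.sum())
    if n == 0 or n == N:
        raise ValueError("decomposition needs 1 <= n < N")
    ddc = data_defect_correlation(frame, period)
    sigma_y = float(y.std())
    dq = float(np.sqrt((N - n) / n))
    naive_error = float(y[R == 1].mean() - y.mean())
    residual = naive_error - ddc * dq * sigma_y
    return DdcReport(
        period=period,
        ddc=ddc,
        naive_error=naive_error,
        data_quantity=dq,
        sigma_y=sigma_y,
        identity_residual=residual,
    )


def binned_relative_frequency_comparison(
    frame: PopulationFrame,
    period: int,
    auxiliary: str,
    weights: UnitWeights | None = None,
    subsample_counts: np.ndarray | None = None,
    bins: int = 50,
    counts: np.ndarray | None = None,
) -> BinnedComparison:
    """Compare population, raw-sample and adjusted-sample distributions.

    The auxiliary's population range is split into ``bins`` equal-width bins
    (top bin right-closed so the maximum is counted). Relative frequencies
    are N_k/N for the population, n_k/n for the raw sample, and
    sum of weights in bin k over the total weight for the weighted sample.
    For the subsampling estimator — which has no unit weights — pass
    ``subsample_counts`` (per-unit draw counts); the adjusted distribution
    is then simply the subsample's. MAE over bins, raw and adjusted, is the
    summary: a smaller adjusted MAE means the adjustment brought the sample
    closer to the population.
    """
    x = frame.data[auxiliary].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError(f"auxiliary {auxiliary!r} is constant; zero-width bins")
    edges = np.linspace(lo, hi, bins + 1)

    m = _counts_for(frame, period, counts)
    sampled = m > 0

    pop_freq = np.histogram(x, bins=edges)[0] / frame.N
    samp_hist = np.histogram(x[sampled], bins=edges, weights=m[sampled])[0]
    samp_freq = samp_hist / m.sum()

    if (weights is None) == (subsample_counts is None):
        raise ValueError("provide exactly one of weights or subsample_counts")
    if weights is not None:
        ids = frame.data["unit_id"].to_numpy()[sampled]
        if sorted(ids) != sorted(weights.unit_ids):
            raise ValueError("weights must cover exactly the sampled units")
        import pandas as pd

        w = pd.Series(weights.w, index=weights.unit_ids).loc[ids].to_numpy()
        wm = w * m[sampled]
        w_hist = np.histogram(x[sampled], bins=edges, weights=wm)[0]
        weighted_freq = w_hist / wm.sum()
    else:
        sc = np.asarray(subsample_counts, dtype=float)
        if sc.shape != (frame.N,):
            raise ValueError("subsample_counts must have one entry per population unit")
        w_hist = np.histogram(x, bins=edges, weights=sc)[0]
        weighted_freq = w_hist / sc.sum()

    mae_raw = float(np.abs(samp_freq - pop_freq).mean())
    mae_weighted = float(np.abs(weighted_freq - pop_freq).mean())
    return BinnedComparison(
        auxiliary=auxiliary,
        edges=edges,
        population_freq=pop_freq,
        sample_freq=samp_freq,
        weighted_freq=weighted_freq,
        mae_raw=mae_raw,
        mae_weighted=mae_weighted,
    )
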