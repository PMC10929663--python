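"""End-to-end orchestration: frame in, estimates/diagnostics/trend out.

`run_analysis` applies the requested estimators to each period of a
population frame, attaches the interval each method calls for (analytic for
naive and poststratification, bootstrap percentile for quasirandomization /
superpopulation / doubly robust / subsampling, posterior credible for MRP),
computes representativeness diagnostics, and estimates the between-period
trend per method. Failures are isolated per method so one estimator cannot
sink a batch run. Everything is written as flat CSV plus a JSON manifest
recording the seed and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import (
    binned_relative_frequency_comparison,
    meng_error_decomposition,
    partial_ddc,
)
from .estimators import (
    EstimateResult,
    build_poststrata,
    estimate_propensity_weights,
    poststratification_weights,
    stratified_subsample_mean,
    superpopulation_estimate,
    superpopulation_implied_weights,
    weighted_mean,
)
from .frame import PopulationFrame, SyntheticConfig, population_mean, simulate_frame
from .mrp import mrp_estimate
from .uncertainty import (
    analytic_interval,
    bootstrap_percentile_interval,
    make_estimator,
    trend_with_interval,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "read_population_table",
    "run_analysis",
    "write_report",
]

KNOWN_METHODS = (
    "naive",
    "quasirandomization",
    "poststratification",
    "superpopulation",
    "doubly_robust",
    "subsampling",
    "mrp",
)

#: methods whose interval comes from the bootstrap
_BOOTSTRAP_METHODS = ("quasirandomization", "superpopulation", "doubly_robust", "subsampling")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    source: str | SyntheticConfig | None = None
    periods: tuple[int, ...] = (1, 2)
    methods: tuple[str, ...] = KNOWN_METHODS
    auxiliaries: tuple[str, ...] = ("elevation", "protected_prop")
    elevation_bins: int = 10
    propensity_model: str = "logistic"
    B: int = 1000
    mcmc_chains: int = 5
    mcmc_iterations: int = 2000
    subsample_size: int | None = None
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; known: {KNOWN_METHODS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.source, SyntheticConfig):
            d["source"] = self.source.to_dict()
        return d


@dataclass
class ResultsBundle:
    estimates: pd.DataFrame
    trends: pd.DataFrame
    diagnostics: pd.DataFrame
    binned: dict[tuple[int, str, str], object]
    weights: dict[tuple[int, str], pd.DataFrame]
    errors: dict[str, str]
    manifest: dict
    results: dict[tuple[str, int], EstimateResult] = field(default_factory=dict)


def read_population_table(
    path: str | Path,
    periods: Sequence[int] = (1, 2),
    column_map: dict[str, str] | None = None,
) -> PopulationFrame:
    """Read and validate a population frame from a flat delimited table.

    ``column_map`` renames arbitrary input columns onto the expected schema
    (``unit_id``, ``elevation``, ``protected_prop``, ``y_<p>``, ``R_<p>``),
    so any deposited layout can be adapted. Rows with missing auxiliaries
    are dropped with a logged count; non-binary y/R values are rejected
    with the offending column named.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    if df.empty:
        raise ValueError(f"{path}: empty population table")
    if column_map:
        df = df.rename(columns=column_map)
    required = ["unit_id", "elevation", "protected_prop"] + [
        f"{p}_{t}" for t in periods for p in ("y", "R")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_aux = df[["elevation", "protected_prop"]].isna().any(axis=1)
    if bad_aux.any():
        logger.warning("dropping %d rows with missing auxiliaries", int(bad_aux.sum()))
        df = df.loc[~bad_aux].reset_index(drop=True)
    for p in periods:
        for prefix in ("y", "R"):
            col = f"{prefix}_{p}"
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"column {col!r} contains values other than 0/1")
    return PopulationFrame(data=df, periods=tuple(periods))


def _estimate_one(
    frame: PopulationFrame, period: int, method: str, cfg: AnalysisConfig, seed: int
) -> tuple[EstimateResult, pd.DataFrame | None]:
    """Point estimate + the interval this method calls for; optional weights table."""
    weights_df = None
    if method == "naive":
        res = analytic_interval(frame, period)
    elif method == "poststratification":
        strata = build_poststrata(frame, period, cfg.elevation_bins)
        uw = poststratification_weights(strata)
        res = analytic_interval(frame, period, weights=uw)
        weights_df = uw.to_frame()
    elif method == "mrp":
        res = mrp_estimate(
            frame,
            period,
            chains=cfg.mcmc_chains,
            iterations=cfg.mcmc_iterations,
            seed=seed,
        )
    elif method in _BOOTSTRAP_METHODS:
        opts = {
            "covariates": cfg.auxiliaries,
            "predictors": cfg.auxiliaries,
            "model_kind": cfg.propensity_model,
            "elevation_bins": cfg.elevation_bins,
            "size": cfg.subsample_size,
        }
        est = make_estimator(method, **opts)
        point = est(frame, period, None, np.random.default_rng(seed))
        dist, interval = bootstrap_percentile_interval(
            frame, period, est, B=cfg.B, seed=seed
        )
        res = EstimateResult(
            method=method,
            period=period,
            point=point,
            interval=interval,
            interval_method="percentile-bootstrap",
            draws=dist.estimates,
            diagnostics={"n_failed": dist.n_failed},
        )
        if method == "quasirandomization":
            _, uw = estimate_propensity_weights(
                frame, period, cfg.propensity_model, cfg.auxiliaries, seed=seed
            )
            weights_df = uw.to_frame()
        elif method == "superpopulation":
            fit, _ = superpopulation_estimate(frame, period, cfg.auxiliaries)
            weights_df = superpopulation_implied_weights(fit, frame).to_frame()
    else:  # pragma: no cover — guarded by AnalysisConfig validation
        raise ValueError(f"unknown method {method!r}")
    return res, weights_df


def run_analysis(config: AnalysisConfig, frame: PopulationFrame | None = None) -> ResultsBundle:
    """Run every requested method on every period; diagnostics; trend."""
    if frame is None:
        if isinstance(config.source, SyntheticConfig):
            frame = simulate_frame(config.source)
        elif config.source is not None:
            frame = read_population_table(config.source, config.periods)
        else:
            raise ValueError("run_analysis needs a frame or a config.source")

    rng = np.random.default_rng(config.seed)
    results: dict[tuple[str, int], EstimateResult] = {}
    weights: dict[tuple[int, str], pd.DataFrame] = {}
    binned: dict[tuple[int, str, str], object] = {}
    errors: dict[str, str] = {}
    est_rows = []
    diag_rows = []

    synthetic = frame.p_true(config.periods[0]) is not None

    for period in config.periods:
        # representativeness diagnostics (undefined for a census sample:
        # R has no variance — recorded as an error, run continues)
        row = {
            "period": period,
            "n": frame.n(period),
            "N": frame.N,
            "sampling_fraction": frame.n(period) / frame.N,
        }
        try:
            rep = meng_error_decomposition(frame, period)
            rep.partial_ddc = partial_ddc(frame, period, config.auxiliaries)
            row.update(
                ddc=rep.ddc,
                partial_ddc=rep.partial_ddc,
                naive_error=rep.naive_error,
                sigma_y=rep.sigma_y,
                identity_residual=rep.identity_residual,
            )
        except ValueError as exc:
            errors[f"diagnostics_{period}"] = str(exc)
        if synthetic:
            row["true_mean"] = population_mean(frame, period)
        diag_rows.append(row)

        for method in config.methods:
            mseed = int(rng.integers(2**31 - 1))
            try:
                res, wdf = _estimate_one(frame, period, method, config, mseed)
            except Exception as exc:  # noqa: BLE001 — per-method isolation
                logger.warning("method %s failed in period %s: %s", method, period, exc)
                errors[f"{method}_{period}"] = str(exc)
                continue
            results[(method, period)] = res
            if wdf is not None:
                weights[(period, method)] = wdf
            est_rows.append(
                {
                    "method": method,
                    "period": period,
                    "point": res.point,
                    "lo": res.interval[0] if res.interval else np.nan,
                    "hi": res.interval[1] if res.interval else np.nan,
                    "interval_method": res.interval_method,
                }
            )

        # auxiliary-distribution comparisons for the weight-producing methods
        for period_method, wdf in list(weights.items()):
            if period_method[0] != period:
                continue
            uw_method = period_method[1]
            from .estimators import UnitWeights

            uw = UnitWeights(
                wdf["unit_id"].to_numpy(), wdf["weight"].to_numpy(), uw_method
            ) if (wdf["weight"] > 0).all() else None
            for aux in config.auxiliaries:
                try:
                    if uw is not None:
                        bc = binned_relative_frequency_comparison(
                            frame, period, aux, weights=uw
                        )
                        binned[(period, uw_method, aux)] = bc
                except Exception as exc:  # noqa: BLE001
                    errors[f"binned_{uw_method}_{period}_{aux}"] = str(exc)
        if "subsampling" in config.methods and (
            f"subsampling_{period}" not in errors
        ):
            # subsample distribution stands in for weights for this method
            strata = build_poststrata(frame, period, cfg_bins := config.elevation_bins)
            sub_seed = int(rng.integers(2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            size = config.subsample_size or max(1, frame.N // 10)
            draw_counts = np.zeros(frame.N)
            from .estimators import _largest_remainder_allocation

            alloc = _largest_remainder_allocation(
                strata.table["Nj"].to_numpy(dtype=float), size
            )
            for j, a in enumerate(alloc):
                in_j = np.flatnonzero((strata.labels == j) & (strata.counts > 0))
                if a and len(in_j):
                    chosen = sub_rng.choice(in_j, size=a, replace=True)
                    draw_counts += np.bincount(chosen, minlength=frame.N)
            for aux in config.auxiliaries:
                bc = binned_relative_frequency_comparison(
                    frame, period, aux, subsample_counts=draw_counts
                )
                binned[(period, "subsampling", aux)] = bc

    # trends
    trend_rows = []
    p1, p2 = config.periods[0], config.periods[-1]
    for method in config.methods:
        r1, r2 = results.get((method, p1)), results.get((method, p2))
        if r1 is None or r2 is None:
            continue
        mode = "percentile" if r1.draws is not None else "normal"
        try:
            tr = trend_with_interval(r1, r2, mode=mode)
        except Exception as exc:  # noqa: BLE001
            errors[f"trend_{method}"] = str(exc)
            continue
        trend_rows.append(
            {
                "method": method,
                "trend": tr.point,
                "lo": tr.interval[0],
                "hi": tr.interval[1],
                "interval_method": tr.interval_method,
            }
        )
    if synthetic:
        trend_rows.append(
            {
                "method": "truth",
                "trend": population_mean(frame, p2) - population_mean(frame, p1),
                "lo": np.nan,
                "hi": np.nan,
                "interval_method": "none",
            }
        )

    from . import __version__ as version

    manifest = {
        "seed": config.seed,
        "version": version,
        "config": config.to_dict(),
        "N": frame.N,
        "periods": list(config.periods),
        "errors": errors,
    }
    return ResultsBundle(
        estimates=pd.DataFrame(est_rows),
        trends=pd.DataFrame(trend_rows),
        diagnostics=pd.DataFrame(diag_rows),
        binned=binned,
        weights=weights,
        errors=errors,
        manifest=manifest,
        results=results,
    )


def write_report(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write estimates, trends, diagnostics, MAE and weights tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _write(bundle.estimates, "estimates.csv")
    _write(bundle.trends, "trends.csv")
    _write(bundle.diagnostics, "diagnostics.csv")

    mae_rows = [
        {
            "period": period,
            "method": method,
            "auxiliary": aux,
            "mae_raw": bc.mae_raw,
            "mae_weighted": bc.mae_weighted,
        }
        for (period, method, aux), bc in bundle.binned.items()
    ]
    _write(pd.DataFrame(mae_rows), "auxiliary_mae.csv")

    for (period, method), wdf in bundle.weights.items():
        _write(wdf, f"weights_{method}_period{period}.csv")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, default=str))
    written.append(manifest_path)
    return written
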