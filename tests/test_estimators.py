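"""Adjustment estimators: exact oracles, algebraic identities, Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from occuadjust import (
    SyntheticConfig,
    UnitWeights,
    build_poststrata,
    doubly_robust_estimate,
    estimate_propensity_weights,
    generate_population,
    naive_mean,
    population_mean,
    poststratification_weights,
    simulate_frame,
    stratified_subsample_mean,
    superpopulation_estimate,
    superpopulation_implied_weights,
    weighted_mean,
)
from occuadjust.estimators import (
    _largest_remainder_allocation,
    design_based_mean,
    poststratified_mean,
)
from occuadjust.frame import apply_inclusion_mechanism


def resample_inclusion(frame, p_incl, rng):
    """Fresh Bernoulli inclusion draw over a fixed population (counts vector)."""
    while True:
        R = (rng.random(frame.N) < p_incl).astype(float)
        if 0 < R.sum() < frame.N:
            return R


class TestNaiveAndWeighted:
    def test_naive_enumeration(self):
        assert naive_mean(make_frame([1, 0, 1, 1], [1, 1, 0, 0]), 1).point == 0.5
        assert naive_mean(make_frame([1, 1, 0, 1], [1, 1, 1, 1]), 1).point == 0.75

    def test_naive_empty_sample_errors(self):
        with pytest.raises(ValueError):
            naive_mean(make_frame([1, 0], [0, 0]), 1)

    def test_weighted_mean_inverse_probability_example(self):
        # sampled units with p = (0.5, 1.0) -> weights (2, 1) -> (1*2+0*1)/3
        frame = make_frame([1, 0, 1, 1], [1, 1, 0, 0])
        w = UnitWeights(["u0", "u1"], [2.0, 1.0], method="design")
        assert weighted_mean(frame, 1, w) == pytest.approx(2 / 3)

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None)
    def test_constant_weights_recover_naive(self, c):
        frame = make_frame([1, 0, 1, 1, 0], [1, 1, 1, 0, 1])
        w = UnitWeights([f"u{i}" for i in (0, 1, 2, 4)], np.full(4, c), "naive")
        assert weighted_mean(frame, 1, w) == pytest.approx(
            naive_mean(frame, 1).point, abs=1e-12
        )

    def test_hajek_rescaling_invariance(self, small_frame):
        R = small_frame.R(1)
        ids = small_frame.data["unit_id"].to_numpy()[R == 1]
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 5.0, size=int(R.sum()))
        a = weighted_mean(small_frame, 1, UnitWeights(ids, w, "design"))
        b = weighted_mean(small_frame, 1, UnitWeights(ids, 7.0 * w, "design"))
        assert a == pytest.approx(b, abs=1e-14)

    def test_weight_mismatch_errors(self, small_frame):
        with pytest.raises(ValueError, match="exactly the sampled units"):
            weighted_mean(small_frame, 1, UnitWeights(["u0"], [1.0], "design"))


class TestPropensity:
    def test_true_probabilities_give_unbiased_design_estimate(self):
        # design-based unbiasedness over 500 replicate inclusion draws
        cfg = SyntheticConfig(N=5000, seed=21)
        frame = simulate_frame(cfg)
        truth = population_mean(frame, 1)
        p = frame.p_true(1)
        rng = np.random.default_rng(77)
        ests = []
        for _ in range(500):
            counts = resample_inclusion(frame, p, rng)
            ests.append(design_based_mean(frame, 1, counts).point)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - truth) < 3 * mc_se

    def test_intercept_only_model_recovers_naive(self, small_frame):
        # constant covariate -> fitted p = n/N everywhere -> constant weights
        from occuadjust.frame import PopulationFrame

        frame = PopulationFrame(small_frame.data.copy(), small_frame.periods)
        frame.data["const"] = 1.0
        fit, w = estimate_propensity_weights(frame, 1, covariates=["const"])
        np.testing.assert_allclose(fit.p_hat, frame.n(1) / frame.N, atol=1e-3)
        assert weighted_mean(frame, 1, w) == pytest.approx(
            naive_mean(frame, 1).point, abs=1e-9
        )

    def test_adjustment_beats_naive_under_informative_auxiliaries(self):
        # qualitative bias-ordering oracle at modest replicate count
        rng = np.random.default_rng(5)
        naive_err, adj_err = [], []
        cfg = SyntheticConfig(N=3000, seed=9)
        frame = simulate_frame(cfg)
        truth = population_mean(frame, 1)
        p = frame.p_true(1)
        for _ in range(60):
            counts = resample_inclusion(frame, p, rng)
            naive_err.append(naive_mean(frame, 1, counts).point - truth)
            _, w = estimate_propensity_weights(frame, 1, counts=counts)
            adj_err.append(weighted_mean(frame, 1, w, counts) - truth)
        assert abs(np.mean(adj_err)) < abs(np.mean(naive_err))

    def test_constant_inclusion_errors(self):
        frame = make_frame([1, 0, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            estimate_propensity_weights(frame, 1)

    def test_forest_probabilities_are_clipped(self, small_frame):
        fit, w = estimate_propensity_weights(small_frame, 1, model_kind="forest", seed=0)
        assert np.all(fit.p_hat >= 1e-6) and np.all(fit.p_hat <= 1)
        assert np.all(w.w > 0)


class TestPoststratification:
    def test_default_crossing_yields_twenty_strata(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        assert strata.n_strata == 20

    def test_counts_partition_population_and_sample(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        assert strata.N == default_frame.N
        assert strata.n == default_frame.n(1)
        # every unit in exactly one stratum
        assert len(strata.labels) == default_frame.N

    def test_weights_calibrate_to_stratum_counts(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        uw = poststratification_weights(strata)
        assert uw.w.sum() == pytest.approx(default_frame.N, abs=1e-8)
        sampled = strata.counts > 0
        for j in range(strata.n_strata):
            mask = strata.labels[sampled] == j
            Nj = strata.table["Nj"].iloc[j]
            assert uw.w[mask].sum() == pytest.approx(Nj, abs=1e-9)

    def test_two_strata_cell_mean_example(self):
        # (N1=100, n1=10, ybar1=0.8), (N2=100, n2=90, ybar2=0.2) -> 0.5
        y = np.r_[np.repeat([1, 0], [80, 20]), np.repeat([1, 0], [20, 80])]
        R = np.zeros(200)
        R[:8] = 1          # 8 occupied sampled in stratum 1
        R[80:82] = 1       # 2 unoccupied sampled in stratum 1
        R[100:118] = 1     # 18 occupied sampled in stratum 2
        R[120:192] = 1     # 72 unoccupied sampled in stratum 2
        elevation = np.r_[np.zeros(100), np.ones(100)]
        frame = make_frame(y, R, elevation=elevation)
        strata = build_poststrata(frame, 1, elevation_bins=2)
        assert strata.n_strata == 2
        est = poststratified_mean(frame, 1, strata)
        # cell means: 0.8 and 0.2, equal population shares
        assert est.point == pytest.approx(0.5)

    def test_single_stratum_equals_naive(self, small_frame):
        strata = build_poststrata(small_frame, 1, elevation_bins=1, protected_rule="none")
        assert strata.n_strata == 1
        assert strata.table["Nj"].iloc[0] == small_frame.N
        assert strata.table["nj"].iloc[0] == small_frame.n(1)
        est = poststratified_mean(small_frame, 1, strata)
        assert est.point == pytest.approx(naive_mean(small_frame, 1).point, abs=1e-12)

    def test_unbiased_under_stratum_only_inclusion(self):
        # inclusion depends only on the stratum labels -> MAR within strata
        cfg = SyntheticConfig(N=5000, seed=31)
        frame = generate_population(cfg)
        strata = build_poststrata(
            apply_inclusion_mechanism(frame, cfg), 1
        )
        rng = np.random.default_rng(13)
        stratum_p = rng.uniform(0.05, 0.9, size=strata.n_strata)
        p_incl = stratum_p[strata.labels]
        truth = population_mean(frame, 1)
        ests = []
        for _ in range(500):
            counts = resample_inclusion(frame, p_incl, rng)
            ests.append(poststratified_mean(frame, 1, counts=counts).point)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - truth) < 3 * mc_se

    def test_empty_sampled_stratum_collapses(self):
        # put all high-elevation samples out of the sample: bin must collapse
        rng = np.random.default_rng(3)
        elevation = np.sort(rng.gamma(2, 100, size=400))
        y = rng.integers(0, 2, size=400)
        R = np.zeros(400)
        R[:200] = rng.random(200) < 0.5  # only low elevations sampled
        frame = make_frame(y, R.astype(int), elevation=elevation)
        strata = build_poststrata(frame, 1)
        nj = strata.table["nj"].to_numpy()
        Nj = strata.table["Nj"].to_numpy()
        assert not np.any((Nj > 0) & (nj == 0))
        assert strata.N == 400


class TestSuperpopulation:
    def test_intercept_only_equals_naive(self, small_frame):
        X = np.empty((small_frame.N, 0))
        fit, est = superpopulation_estimate(small_frame, 1, predictors=X)
        assert est == pytest.approx(naive_mean(small_frame, 1).point, abs=1e-12)

    def test_saturated_strata_indicators_equal_poststratification(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        # intercept + (k-1) indicators = saturated cell-means model
        K = strata.n_strata
        dummies = (strata.labels[:, None] == np.arange(1, K)).astype(float)
        fit, est = superpopulation_estimate(default_frame, 1, predictors=dummies)
        ps = poststratified_mean(default_frame, 1, strata)
        assert est == pytest.approx(ps.point, abs=1e-10)

    def test_exact_linear_outcome_recovers_truth(self):
        # y exactly linear in the predictor over the whole frame
        elevation = np.linspace(0, 1, 50)
        y = (elevation > 0.6).astype(int)
        frame = make_frame(y, (np.arange(50) % 2 == 0).astype(int),
                           elevation=elevation)
        X = y[:, None].astype(float)  # trivially exact regressor
        fit, est = superpopulation_estimate(frame, 1, predictors=X)
        assert est == pytest.approx(population_mean(frame, 1), abs=1e-12)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_rank_deficient_design_names_columns(self, small_frame):
        small_frame.data["elev_copy"] = small_frame.data["elevation"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            superpopulation_estimate(
                small_frame, 1, predictors=["elevation", "elev_copy"]
            )
        small_frame.data.drop(columns="elev_copy", inplace=True)

    def test_residuals_sum_to_zero_with_intercept(self, default_frame):
        fit, _ = superpopulation_estimate(default_frame, 1)
        assert fit.residuals.sum() == pytest.approx(0, abs=1e-8)


class TestImpliedWeights:
    def test_weighted_form_reproduces_model_estimate(self, default_frame):
        fit, est = superpopulation_estimate(default_frame, 1)
        uw = superpopulation_implied_weights(fit, default_frame)
        wm = weighted_mean(default_frame, 1, uw)
        assert wm == pytest.approx(est, abs=1e-10)

    def test_weights_sum_to_population_size(self, default_frame):
        fit, _ = superpopulation_estimate(default_frame, 1)
        uw = superpopulation_implied_weights(fit, default_frame)
        assert uw.w.sum() == pytest.approx(default_frame.N, abs=1e-8)

    def test_intercept_only_weights_all_equal(self, small_frame):
        X = np.empty((small_frame.N, 0))
        fit, _ = superpopulation_estimate(small_frame, 1, predictors=X)
        uw = superpopulation_implied_weights(fit, small_frame)
        assert np.allclose(uw.w, uw.w[0], atol=1e-12)


class TestDoublyRobust:
    def test_exact_outcome_model_collapses_to_superpopulation(self):
        elevation = np.linspace(0, 1, 60)
        y = (elevation > 0.5).astype(int)
        R = (np.arange(60) % 2 == 0).astype(int)
        frame = make_frame(y, R, elevation=elevation)
        X = y[:, None].astype(float)
        sfit, sp = superpopulation_estimate(frame, 1, predictors=X)
        pfit, _ = estimate_propensity_weights(frame, 1, covariates=["elevation"])
        dr = doubly_robust_estimate(frame, 1, pfit, sfit)
        assert dr == pytest.approx(sp, abs=1e-10)

    def test_correct_propensity_fixes_wrong_outcome_model(self):
        # double robustness: true p with a junk outcome model stays unbiased
        from occuadjust.estimators import PropensityFit, SuperpopulationFit

        cfg = SyntheticConfig(N=5000, seed=41)
        frame = simulate_frame(cfg)
        truth = population_mean(frame, 1)
        p = frame.p_true(1)
        pfit = PropensityFit("oracle", p, ("p_true",))
        rng = np.random.default_rng(19)
        # deliberately wrong outcome model: constant 0.9 prediction
        y_hat = np.full(frame.N, 0.9)
        ests = []
        for _ in range(500):
            counts = resample_inclusion(frame, p, rng)
            sfit = SuperpopulationFit(
                beta=np.array([0.9]), y_hat=y_hat,
                residuals=(frame.y(1) - y_hat)[counts > 0],
                predictors=("wrong",), design=np.ones((frame.N, 1)),
                sampled=counts > 0, counts=counts,
            )
            ests.append(doubly_robust_estimate(frame, 1, pfit, sfit, counts))
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - truth) < 3 * mc_se

    def test_zero_propensity_raises(self):
        from occuadjust.estimators import PropensityFit, SuperpopulationFit

        frame = make_frame([1, 0, 1, 0], [1, 1, 0, 0])
        pfit = PropensityFit("oracle", np.array([0.0, 0.5, 0.5, 0.5]), ())
        sfit = SuperpopulationFit(
            beta=np.zeros(1), y_hat=np.zeros(4), residuals=np.zeros(2),
            predictors=(), design=np.ones((4, 1)),
            sampled=np.array([True, True, False, False]),
            counts=np.array([1.0, 1, 0, 0]),
        )
        with pytest.raises(ZeroDivisionError):
            doubly_robust_estimate(frame, 1, pfit, sfit)


class TestSubsampling:
    def test_largest_remainder_totals_exactly(self):
        shares = np.array([3.0, 3.0, 3.0, 1.0])
        alloc = _largest_remainder_allocation(shares, 10)
        assert alloc.sum() == 10
        assert np.all(alloc >= 1)

    def test_allocation_matches_population_shares(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        size = default_frame.N // 10
        Nj = strata.table["Nj"].to_numpy(dtype=float)
        alloc = _largest_remainder_allocation(Nj, size)
        assert alloc.sum() == size
        np.testing.assert_allclose(alloc, size * Nj / Nj.sum(), atol=1.0)

    def test_expectation_equals_poststratified_estimate(self, default_frame):
        # law of total expectation over >=1000 seeded replicates
        strata = build_poststrata(default_frame, 1)
        mean, reps = stratified_subsample_mean(
            default_frame, 1, strata, seed=6, n_replicates=1000
        )
        ps = poststratified_mean(default_frame, 1, strata).point
        mc_se = reps.std() / np.sqrt(len(reps))
        assert abs(mean - ps) < 3 * mc_se

    def test_single_stratum_expectation_is_naive(self, small_frame):
        strata = build_poststrata(small_frame, 1, elevation_bins=1, protected_rule="none")
        mean, reps = stratified_subsample_mean(
            small_frame, 1, strata, seed=2, n_replicates=2000
        )
        mc_se = reps.std() / np.sqrt(len(reps))
        assert abs(mean - naive_mean(small_frame, 1).point) < 3 * mc_se
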