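"""ddc, partial ddc, the exact error decomposition, and binned MAE comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from occuadjust import (
    SyntheticConfig,
    binned_relative_frequency_comparison,
    build_poststrata,
    data_defect_correlation,
    estimate_propensity_weights,
    meng_error_decomposition,
    partial_ddc,
    poststratification_weights,
    simulate_frame,
)


class TestDdc:
    def test_hand_enumerated_value(self):
        # cov = -0.125, sd_R = 0.5, sd_y = 0.43301 -> ddc = -0.57735
        frame = make_frame([1, 0, 1, 1], [1, 1, 0, 0])
        assert data_defect_correlation(frame, 1) == pytest.approx(-0.57735, abs=1e-5)

    def test_perfect_preferential_sampling(self):
        frame = make_frame([1, 0, 1, 1], [1, 0, 1, 1])
        assert data_defect_correlation(frame, 1) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            data_defect_correlation(make_frame([1, 1, 1], [1, 0, 1]), 1)

    def test_antisymmetric_under_outcome_flip(self, small_frame):
        ddc = data_defect_correlation(small_frame, 1)
        flipped = make_frame(
            1 - small_frame.y(1),
            small_frame.R(1),
            elevation=small_frame.data["elevation"].to_numpy(),
        )
        assert data_defect_correlation(flipped, 1) == pytest.approx(-ddc, abs=1e-12)

    def test_invariant_to_unit_relabelling(self, small_frame):
        perm = np.random.default_rng(4).permutation(small_frame.N)
        shuffled = make_frame(
            small_frame.y(1)[perm],
            small_frame.R(1)[perm],
            elevation=small_frame.data["elevation"].to_numpy()[perm],
        )
        assert data_defect_correlation(shuffled, 1) == pytest.approx(
            data_defect_correlation(small_frame, 1), abs=1e-12
        )


class TestPartialDdc:
    def test_uninformative_auxiliaries_leave_ddc_unchanged(self):
        # auxiliaries uncorrelated with both R and y: projection changes nothing
        rng = np.random.default_rng(8)
        N = 2000
        y = rng.integers(0, 2, N)
        R = rng.integers(0, 2, N)
        # residualize the auxiliary against (1, R, y) so it is exactly orthogonal
        raw = rng.normal(size=N)
        M = np.column_stack([np.ones(N), R, y])
        elev = raw - M @ np.linalg.lstsq(M, raw, rcond=None)[0]
        frame = make_frame(y, R, elevation=elev)
        assert partial_ddc(frame, 1, ("elevation",)) == pytest.approx(
            data_defect_correlation(frame, 1), abs=1e-9
        )

    def test_strong_negative_gamma_gives_negative_partial_ddc(self):
        vals = [
            partial_ddc(
                simulate_frame(SyntheticConfig(N=4000, gamma_y=-2.0, seed=s)), 1
            )
            for s in range(5)
        ]
        assert max(vals) < 0

    def test_collinear_auxiliaries_error(self, small_frame):
        from occuadjust.frame import PopulationFrame

        frame = PopulationFrame(small_frame.data.copy(), small_frame.periods)
        frame.data["elev2"] = frame.data["elevation"]
        with pytest.raises(np.linalg.LinAlgError):
            partial_ddc(frame, 1, ("elevation", "elev2"))


class TestErrorDecomposition:
    def test_hand_enumerated_identity(self):
        frame = make_frame([1, 0, 1, 1], [1, 1, 0, 0])
        rep = meng_error_decomposition(frame, 1)
        assert rep.naive_error == pytest.approx(-0.25)
        assert rep.data_quantity == pytest.approx(1.0)
        assert rep.sigma_y == pytest.approx(0.43301, abs=1e-5)
        assert abs(rep.identity_residual) < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_identity_holds_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 400))
        y = rng.integers(0, 2, N)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        R = rng.integers(0, 2, N)
        if R.sum() == 0:
            R[0] = 1
        if R.sum() == N:
            R[-1] = 0
        frame = make_frame(y, R)
        rep = meng_error_decomposition(frame, 1)
        assert abs(rep.identity_residual) < 1e-12

    def test_census_limit_error_vanishes(self):
        frame = make_frame([1, 0, 1, 1, 0], [1, 1, 1, 1, 0])
        rep = meng_error_decomposition(frame, 1)
        # only one unit missing: tiny error, identity still exact
        assert abs(rep.identity_residual) < 1e-12
        with pytest.raises(ValueError):
            meng_error_decomposition(make_frame([1, 0], [1, 1]), 1)


class TestBinnedComparison:
    def test_frequency_vectors_are_distributions(self, default_frame):
        _, uw = estimate_propensity_weights(default_frame, 1)
        bc = binned_relative_frequency_comparison(
            default_frame, 1, "elevation", weights=uw
        )
        for freq in (bc.population_freq, bc.sample_freq, bc.weighted_freq):
            assert np.all(freq >= 0)
            assert freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(bc.population_freq) == 50

    def test_full_population_sample_has_zero_raw_mae(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        y[0] = 1 - y[0] if y.min() == y.max() else y[0]
        frame = make_frame(y, np.ones(100, dtype=int), elevation=rng.normal(size=100))
        from occuadjust.estimators import UnitWeights

        uw = UnitWeights(frame.data["unit_id"].to_numpy(), np.ones(100), "naive")
        bc = binned_relative_frequency_comparison(frame, 1, "elevation", weights=uw)
        assert bc.mae_raw == 0
        assert bc.mae_weighted == 0

    def test_poststratification_calibrates_at_stratum_resolution(self, default_frame):
        # auxiliary = the protected dichotomy itself, binned at 0 vs >0:
        # calibration forces exact agreement of the weighted frequencies
        strata = build_poststrata(default_frame, 1)
        uw = poststratification_weights(strata)
        from occuadjust.frame import PopulationFrame

        frame = PopulationFrame(default_frame.data.copy(), default_frame.periods)
        frame.data["prot_flag"] = (frame.data["protected_prop"] > 0).astype(float)
        bc = binned_relative_frequency_comparison(frame, 1, "prot_flag", weights=uw, bins=2)
        assert bc.mae_weighted == pytest.approx(0, abs=1e-12)

    def test_weighting_improves_auxiliary_match(self, default_frame):
        _, uw = estimate_propensity_weights(default_frame, 1)
        bc = binned_relative_frequency_comparison(
            default_frame, 1, "elevation", weights=uw
        )
        assert bc.mae_weighted < bc.mae_raw

    def test_constant_auxiliary_errors(self):
        frame = make_frame([1, 0, 1], [1, 1, 0], elevation=np.ones(3))
        from occuadjust.estimators import UnitWeights

        uw = UnitWeights(["u0", "u1"], [1.0, 1.0], "naive")
        with pytest.raises(ValueError, match="constant"):
            binned_relative_frequency_comparison(frame, 1, "elevation", weights=uw)

    def test_subsample_distribution_mode(self, default_frame):
        strata = build_poststrata(default_frame, 1)
        rng = np.random.default_rng(0)
        counts = np.zeros(default_frame.N)
        sampled = np.flatnonzero(default_frame.R(1))
        counts[rng.choice(sampled, 500)] += 1
        bc = binned_relative_frequency_comparison(
            default_frame, 1, "elevation", subsample_counts=counts
        )
        assert bc.weighted_freq.sum() == pytest.approx(1.0, abs=1e-9)
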