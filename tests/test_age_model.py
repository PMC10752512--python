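"""Sampling of group estimates and spline disaggregation to single ages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import band_users_oracle, natural_spline_oracle
from youthads import (AgeBand, AgeGroupEstimate, AgeProfile, ParameterSet,
                      PopulationTable, RunConfig, ValidationError,
                      build_age_profile, sample_group_estimates,
                      spline_interpolate, users_by_age)
from youthads.age_model import Z95, band_knots, ensure_child_minutes


def _bands(*specs):
    return [AgeGroupEstimate(AgeBand(lo, hi), est, m)
            for lo, hi, est, m in specs]


class TestSampling:
    def test_zero_margin_returns_point_estimate_exactly(self, rng):
        bands = _bands((8, 12, 0.37, 0.0), (13, 17, 0.62, 0.0))
        np.testing.assert_array_equal(
            sample_group_estimates(bands, rng), [0.37, 0.62])

    def test_truncation_keeps_draws_in_legal_range(self):
        bands = _bands((8, 12, 0.01, 0.05), (13, 17, 0.99, 0.05))
        draws = np.array([sample_group_estimates(bands, s) for s in range(500)])
        assert np.all((draws >= 0) & (draws <= 1))
        minutes = _bands((0, 17, 0.5, 2.0))
        mdraws = np.array([sample_group_estimates(minutes, s, kind="minutes")
                           for s in range(500)])
        assert np.all(mdraws >= 0)

    @pytest.mark.parametrize("margin", [0.073, 0.052])
    def test_empirical_sd_matches_margin_over_z(self, margin):
        """10,000 draws from estimate 0.5: SD must be margin95/1.96
        within 5% (adult-survey sampling errors)."""
        bands = _bands((18, 29, 0.5, margin))
        rng = np.random.default_rng(7)
        draws = np.array([sample_group_estimates(bands, rng)[0]
                          for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(margin / Z95, rel=0.05)

    def test_deterministic_under_fixed_seed(self):
        bands = _bands((8, 12, 0.4, 0.03), (13, 17, 0.6, 0.03))
        a = sample_group_estimates(bands, 123)
        b = sample_group_estimates(bands, 123)
        np.testing.assert_array_equal(a, b)


class TestSpline:
    def test_two_knots_interpolate_linearly(self):
        assert spline_interpolate([10, 20], [0.2, 0.6], [15])[0] == \
            pytest.approx(0.4, abs=1e-12)

    def test_exact_at_knots(self):
        x = np.array([8.0, 15.0, 24.0, 40.0, 60.0])
        y = np.array([0.1, 0.8, 0.5, 0.3, 0.2])
        np.testing.assert_allclose(spline_interpolate(x, y, x), y, atol=1e-10)

    def test_boundary_second_derivative_is_zero(self):
        x = [8.0, 15.0, 24.0, 40.0]
        y = [0.2, 0.7, 0.6, 0.1]
        h = 1e-4
        for edge, inward in ((x[0], +1), (x[-1], -1)):
            pts = spline_interpolate(
                x, y, [edge, edge + inward * h, edge + 2 * inward * h])
            second = (pts[2] - 2 * pts[1] + pts[0]) / h ** 2
            assert abs(second) < 1e-4

    def test_matches_tridiagonal_oracle_on_fixed_knots(self):
        x = np.array([8.0, 15.0, 24.0, 40.0])
        y = np.array([0.15, 0.72, 0.55, 0.20])
        grid = np.linspace(8, 40, 101)
        np.testing.assert_allclose(spline_interpolate(x, y, grid),
                                   natural_spline_oracle(x, y, grid),
                                   atol=1e-8)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=3, max_value=9), st.integers(0, 2**31 - 1))
    def test_matches_tridiagonal_oracle_on_random_knots(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 10.0, n).cumsum()  # strictly increasing gaps
        y = rng.uniform(0, 1, n)
        grid = np.linspace(x[0], x[-1], 57)
        np.testing.assert_allclose(spline_interpolate(x, y, grid),
                                   natural_spline_oracle(x, y, grid),
                                   atol=1e-8)

    def test_linear_beyond_boundary_knots(self):
        x = [10.0, 15.0, 25.0, 40.0]
        y = [0.3, 0.6, 0.5, 0.2]
        below = spline_interpolate(x, y, [4.0, 6.0, 8.0])
        assert np.diff(below, 2)[0] == pytest.approx(0.0, abs=1e-10)
        above = spline_interpolate(x, y, [50.0, 60.0, 70.0])
        assert np.diff(above, 2)[0] == pytest.approx(0.0, abs=1e-10)

    def test_rejects_degenerate_knot_sets(self):
        with pytest.raises(ValidationError):
            spline_interpolate([10.0], [0.5], [5])
        with pytest.raises(ValidationError):
            spline_interpolate([10, 10, 20], [0.1, 0.2, 0.3], [15])
        with pytest.raises(ValidationError):
            spline_interpolate([20, 10], [0.1, 0.2], [15])

    def test_vectorized_sets_match_per_set_evaluation(self, rng):
        x = np.array([10.0, 15.0, 25.0, 40.0, 60.0])
        Y = rng.uniform(0, 1, (5, 7))
        grid = np.linspace(0, 84, 85)
        allsets = spline_interpolate(x, Y, grid)
        for j in range(7):
            np.testing.assert_allclose(
                allsets[:, j], spline_interpolate(x, Y[:, j], grid), atol=1e-12)


class TestBuildProfile:
    CFG = RunConfig(seed=0, n_candidates=10, n_keep=5)
    PREV = _bands((8, 12, 0.3, 0.03), (13, 17, 0.5, 0.03),
                  (18, 29, 0.4, 0.07), (30, 49, 0.3, 0.05))
    MINS = _bands((0, 17, 40.0, 5.0), (18, 49, 25.0, 5.0))

    def _profile(self, pdraws, mdraws=None):
        ps = ParameterSet("x", np.asarray(pdraws, float),
                          np.asarray(mdraws if mdraws is not None
                                     else [40.0, 25.0], float))
        return build_age_profile(ps, self.PREV, self.MINS, self.CFG)

    def test_zero_draws_give_zero_prevalence_everywhere(self):
        profile = self._profile([0, 0, 0, 0])
        assert np.all(profile.p == 0.0)

    def test_constant_draws_give_constant_profile(self):
        profile = self._profile([0.3, 0.3, 0.3, 0.3])
        np.testing.assert_allclose(profile.p, 0.3, atol=1e-10)

    def test_overshooting_spline_is_clamped_to_one(self):
        """Steep adjacent knots force the raw natural spline above 1
        between knots; the profile must report exactly 1.0 there while
        matching the unclamped oracle elsewhere."""
        draws = np.array([0.05, 1.0, 1.0, 0.05])
        knots = band_knots(self.PREV, self.CFG.age_max)
        ages = np.arange(self.CFG.age_max + 1, dtype=float)
        raw = spline_interpolate(knots, draws, ages)
        assert raw.max() > 1.0  # the fixture does overshoot
        profile = self._profile(draws)
        over = raw > 1.0
        assert np.all(profile.p[over] == 1.0)
        inside = (raw >= 0) & (raw <= 1)
        np.testing.assert_allclose(profile.p[inside], raw[inside], atol=1e-12)

    def test_ages_below_layout_take_clamped_linear_extrapolation(self):
        profile = self._profile([0.3, 0.5, 0.4, 0.3])
        knots = band_knots(self.PREV, self.CFG.age_max)
        raw = spline_interpolate(knots, np.array([0.3, 0.5, 0.4, 0.3]),
                                 np.arange(0, 10, dtype=float))
        np.testing.assert_allclose(profile.p[:10], np.clip(raw, 0, 1),
                                   atol=1e-12)

    def test_single_minutes_band_gives_constant_minutes(self):
        ps = ParameterSet("x", np.array([0.3, 0.4, 0.4, 0.3]), np.array([12.0]))
        profile = build_age_profile(ps, self.PREV,
                                    _bands((0, 49, 12.0, 0.0)), self.CFG)
        assert np.all(profile.m == 12.0)

    def test_child_minutes_fallback_inserted_for_adult_only_layout(self):
        adult_only = _bands((18, 49, 25.0, 5.0), (50, 84, 20.0, 5.0))
        padded = ensure_child_minutes(adult_only, self.CFG)
        assert padded[0].band == AgeBand(0, 17)
        assert padded[0].estimate == 5.0 and padded[0].margin95 == 0.0
        covered = ensure_child_minutes(self.MINS, self.CFG)
        assert covered == tuple(self.MINS)

    def test_draw_band_mismatch_rejected(self):
        ps = ParameterSet("x", np.array([0.3, 0.4]), np.array([40.0, 25.0]))
        with pytest.raises(ValidationError):
            build_age_profile(ps, self.PREV, self.MINS, self.CFG)

    def test_illegal_draws_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ParameterSet("x", np.array([1.2]), np.array([10.0]))
        with pytest.raises(ValidationError):
            ParameterSet("x", np.array([0.5]), np.array([-1.0]))


class TestUsersByAge:
    def test_products_and_brute_force_band_sum(self, rng):
        pop = PopulationTable(np.arange(85), np.full(85, 1000.0))
        p = rng.uniform(0, 1, 85)
        profile = AgeProfile("x", p, np.full(85, 10.0))
        users = users_by_age(profile, pop)
        np.testing.assert_allclose(users, 1000.0 * p)
        assert users[5:18].sum() == pytest.approx(
            band_users_oracle(p, pop.counts, 5, 17), rel=1e-12)

    def test_constant_half_prevalence(self):
        pop = PopulationTable(np.arange(85), np.full(85, 1000.0))
        profile = AgeProfile("x", np.full(85, 0.5), np.full(85, 10.0))
        assert np.all(users_by_age(profile, pop) == 500.0)

    def test_zero_prevalence_gives_zero_users(self):
        pop = PopulationTable(np.arange(85), np.full(85, 1000.0))
        profile = AgeProfile("x", np.zeros(85), np.full(85, 10.0))
        assert np.all(users_by_age(profile, pop) == 0.0)

    def test_length_mismatch_rejected(self):
        pop = PopulationTable(np.arange(80), np.full(80, 1000.0))
        profile = AgeProfile("x", np.zeros(85), np.zeros(85))
        with pytest.raises(ValidationError):
            users_by_age(profile, pop)
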