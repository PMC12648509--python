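"""Season-matrix assembly, PLS fitting, VIP scoring and window delineation."""

import numpy as np
import pandas as pd
import pytest

from chillreq.agroclimatic_models import daily_chill
from chillreq.io_phenology import BloomRecord
from chillreq.pls_delineation import (
    SampleSizeError,
    SeasonMatrix,
    WindowUndefinedError,
    build_season_matrix,
    day_results,
    delineate_chill_window,
    fit_pls,
)
from chillreq.weather import make_hourly_temps

from conftest import ORCHARD_LATITUDE
from oracles import nipals_pls_coefficients


@pytest.fixture(scope="module")
def small_daily(request):
    weather = request.getfixturevalue("small_weather")
    return daily_chill(make_hourly_temps(weather, ORCHARD_LATITUDE))


def _records(genotype, years, pheno=70):
    return [BloomRecord(genotype, y, pheno + (y % 5)) for y in years]


def _generic_matrix(X, y, day_offset=-60):
    """Wrap an arbitrary matrix as a chill-only SeasonMatrix."""
    days = list(range(day_offset, day_offset + X.shape[1]))
    return SeasonMatrix(
        genotype="1_1",
        chill=pd.DataFrame(X, columns=days),
        heat=None,
        y=pd.Series(np.asarray(y, float), name="pheno"),
    )


class TestBuildSeasonMatrix:
    def test_november_to_april_window_has_181_columns(self, small_daily):
        matrix = build_season_matrix(small_daily, _records("1_1", range(2012, 2018)))
        assert matrix.chill.shape == (6, 181)
        assert matrix.day_index[0] == -60  # Nov 1
        assert matrix.day_index[-1] == 120  # Apr 30
        assert matrix.heat.shape == (6, 181)

    def test_season_without_weather_coverage_is_dropped(self, small_daily):
        records = _records("1_1", range(2012, 2018)) + [BloomRecord("1_1", 2011, 70)]
        matrix = build_season_matrix(small_daily, records)
        assert matrix.chill.shape[0] == 6
        assert matrix.dropped_seasons == [2011]

    def test_too_few_seasons_is_an_error(self, small_daily):
        with pytest.raises(SampleSizeError):
            build_season_matrix(small_daily, _records("1_1", [2012, 2013, 2014]))

    def test_heat_block_optional(self, small_daily):
        matrix = build_season_matrix(
            small_daily, _records("1_1", range(2012, 2018)), heat_block=False
        )
        assert matrix.heat is None


class TestFitPLS:
    def test_recovers_negative_association_sign(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 12))
        z3 = (X[:, 3] - X[:, 3].mean()) / X[:, 3].std(ddof=1)
        matrix = _generic_matrix(X, -2.0 * z3 + 70.0)
        fit = fit_pls(matrix, n_components=2)
        assert fit.coefficients[3] < 0

    def test_saturated_fit_reproduces_response(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 10))
        y = rng.normal(70, 5, size=6)
        fit = fit_pls(_generic_matrix(X, y), n_components=5)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-6)

    def test_coefficients_match_independent_nipals_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(6, 10))
            y = rng.normal(70, 5, size=6)
            matrix = _generic_matrix(X, y)
            fit = fit_pls(matrix, n_components=2)
            std = X.std(axis=0, ddof=1)
            Z = (X - X.mean(axis=0)) / std
            oracle = nipals_pls_coefficients(Z, y, 2) / std
            np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)

    def test_constant_columns_excluded_with_zero_vip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 6))
        X[:, 2] = 5.0
        fit = fit_pls(_generic_matrix(X, rng.normal(70, 5, 8)), n_components=2)
        assert not fit.included[2]
        assert fit.vip[2] == 0.0
        assert fit.coefficients[2] == 0.0

    def test_too_few_rows_for_components(self):
        X = np.random.default_rng(4).normal(size=(3, 5))
        with pytest.raises(SampleSizeError):
            fit_pls(_generic_matrix(X, [70, 71, 72]), n_components=3)


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(5)
        for n_comp in (1, 2, 3):
            X = rng.normal(size=(10, 15))
            y = rng.normal(70, 5, 10)
            fit = fit_pls(_generic_matrix(X, y), n_components=n_comp)
            assert np.mean(fit.vip[fit.included] ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_single_relevant_predictor_has_maximal_vip(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        y = 3.0 * X[:, 4] + rng.normal(0, 0.05, 20)
        fit = fit_pls(_generic_matrix(X, y), n_components=2)
        assert fit.vip.argmax() == 4

    def test_one_component_vip_proportional_to_weights(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 6))
        fit = fit_pls(_generic_matrix(X, rng.normal(70, 5, 8)), n_components=1)
        w = np.abs(fit.x_weights[:, 0])
        expected = w / np.linalg.norm(w) * np.sqrt(fit.included.sum())
        np.testing.assert_allclose(fit.vip[fit.included], expected, atol=1e-10)


def _day_table(qualifying, span=(-60, 120), vip_hi=1.2, vip_lo=0.3):
    days = list(range(span[0], span[1] + 1))
    qualifying = set(qualifying)
    return pd.DataFrame(
        {
            "Block": "chill",
            "Day": days,
            "VIP": [vip_hi if d in qualifying else vip_lo for d in days],
            "Coef": [-1.0 if d in qualifying else 1.0 for d in days],
        }
    )


class TestDelineation:
    def test_uncapped_window_spans_qualifying_days(self):
        window = delineate_chill_window(
            _day_table(range(-50, 21)), median_bloom=70, genotype="1_1"
        )
        assert (window.start, window.end, window.capped) == (-50, 20, False)

    def test_median_bloom_cap_shortens_window(self):
        window = delineate_chill_window(
            _day_table(range(50, 81)), median_bloom=70, genotype="1_1"
        )
        assert (window.end, window.capped) == (69, True)

    def test_fractional_median_caps_at_floor_minus_one(self):
        window = delineate_chill_window(
            _day_table(range(-30, 75)), median_bloom=71.5, genotype="1_1"
        )
        assert window.end == 70

    def test_window_end_always_before_median_bloom(self):
        for median in (40.0, 55.5, 70.0):
            window = delineate_chill_window(
                _day_table(range(-40, 110)), median_bloom=median
            )
            assert window.end < median

    def test_all_vip_below_threshold_is_undefined(self):
        table = _day_table(range(-50, 21), vip_hi=0.79)
        with pytest.raises(WindowUndefinedError):
            delineate_chill_window(table, median_bloom=70, genotype="1_9")

    def test_threshold_exactly_met_qualifies(self):
        window = delineate_chill_window(
            _day_table(range(-50, 21), vip_hi=0.8), median_bloom=70
        )
        assert window.start == -50

    def test_isolated_spurious_days_do_not_extend_window(self):
        table = _day_table(list(range(-50, 0)) + [40, 41])
        window = delineate_chill_window(table, median_bloom=70)
        assert window.end == -1
        permissive = delineate_chill_window(table, median_bloom=70, min_run=1)
        assert permissive.end == 41

    def test_heat_block_days_never_qualify(self):
        chill = _day_table(range(-50, 1))
        heat = chill.copy()
        heat["Block"] = "heat"
        heat["Day"] += 60  # strongly "qualifying" heat days later in the season
        window = delineate_chill_window(pd.concat([chill, heat]), median_bloom=70)
        assert window.end == 0

    def test_raising_threshold_never_widens_window(self):
        rng = np.random.default_rng(8)
        days = list(range(-60, 121))
        table = pd.DataFrame(
            {
                "Block": "chill",
                "Day": days,
                "VIP": rng.uniform(0, 2, len(days)),
                "Coef": rng.normal(0, 1, len(days)),
            }
        )
        prev_width = None
        for threshold in (0.2, 0.5, 0.8, 1.1, 1.4):
            try:
                w = delineate_chill_window(
                    table, median_bloom=70, vip_threshold=threshold, min_run=1
                )
                width = w.end - w.start
            except WindowUndefinedError:
                width = -1
            if prev_width is not None:
                assert width <= prev_width
            prev_width = width


class TestDayResults:
    def test_table_covers_both_blocks(self, small_daily):
        matrix = build_season_matrix(small_daily, _records("1_1", range(2012, 2018)))
        results = day_results(fit_pls(matrix))
        assert set(results["Block"]) == {"chill", "heat"}
        assert len(results) == 2 * 181
        assert (results["VIP"] >= 0).all()
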