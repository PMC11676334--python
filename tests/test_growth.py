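"""Growth-rate math, response grids, optimum detection, lipid productivity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from algatrait.growth import (
    ConditionGrid,
    GrowthError,
    GrowthObservation,
    GrowthSeries,
    build_condition_grid,
    classify_growth,
    find_optimum,
    fold_change,
    lipid_productivity,
    read_growth_csv,
    read_plate_csv,
    specific_growth_rate,
)


def _series(values, condition="c", kind="density"):
    return GrowthSeries(
        condition,
        tuple(GrowthObservation(float(t), float(v), kind)
              for t, v in enumerate(values)),
    )


class TestSpecificGrowthRate:
    def test_no_change_is_zero(self):
        assert specific_growth_rate(0.3, 0.3, 0.0, 2.0) == 0.0

    def test_doubling_in_three_days(self):
        assert specific_growth_rate(0.1, 0.2, 0.0, 3.0) == pytest.approx(
            math.log(2) / 3, abs=1e-4
        )

    def test_constructed_inverse(self):
        assert specific_growth_rate(0.05, 0.05 * math.e**1.5, 0, 3) == (
            pytest.approx(0.5)
        )

    def test_hours_expressed_as_days(self):
        # a 72 h screen passed as 3 days yields per-day rates
        mu = specific_growth_rate(0.05, 0.1, 0.0, 72.0 / 24.0)
        assert mu == pytest.approx(math.log(2) / 3)

    @given(
        a1=st.floats(1e-3, 1e6), a2=st.floats(1e-3, 1e6),
        span=st.floats(0.1, 30),
    )
    def test_antisymmetric_under_value_swap(self, a1, a2, span):
        fwd = specific_growth_rate(a1, a2, 0.0, span)
        rev = specific_growth_rate(a2, a1, 0.0, span)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    @pytest.mark.parametrize(
        "args", [(0, 1, 0, 1), (1, 0, 0, 1), (1, 2, 3, 3), (1, 2, 3, 2)]
    )
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(GrowthError):
            specific_growth_rate(*args)


class TestFoldChangeAndClassification:
    def test_published_fivefold_increase(self):
        # initial 7.08e3 cells/mL, day-14 density 3.54e4
        series = GrowthSeries(
            "0.5M",
            (
                GrowthObservation(0, 7.08e3),
                GrowthObservation(7, 2.4e4),
                GrowthObservation(14, 3.54e4),
            ),
        )
        assert fold_change(series, 14) == pytest.approx(5.0)

    def test_constant_series_fold_one(self):
        assert fold_change(_series([2, 2, 2]), 2) == 1.0

    def test_uses_latest_observation_at_or_before(self):
        series = _series([1, 3, 9])
        assert fold_change(series, 1.5) == 3.0

    @given(st.lists(st.floats(0.1, 1e5), min_size=2, max_size=12))
    def test_fold_change_matches_direct_ratio(self, values):
        series = _series(values)
        t_final = series.observations[-1].time
        assert fold_change(series, t_final) == pytest.approx(
            values[-1] / values[0]
        )

    def test_zero_initial_rejected(self):
        with pytest.raises(GrowthError):
            fold_change(_series([0, 1]), 1)

    def test_fivefold_series_is_growth(self):
        assert classify_growth(_series([1, 2, 5])) == "growth"

    def test_flat_series_is_no_growth(self):
        assert classify_growth(_series([1, 1, 1]), 1.2) == "no_growth"

    def test_threshold_is_inclusive(self):
        assert classify_growth(_series([1.0, 1.2]), 1.2) == "growth"


class TestConditionGrid:
    def test_equal_ods_give_zero_grid(self):
        plate = [(10, 50, 0.1, 0.1), (10, 100, 0.1, 0.1),
                 (20, 50, 0.1, 0.1), (20, 100, 0.1, 0.1)]
        grid = build_condition_grid(plate, 3.0)
        assert (grid.mu == 0).all()

    def test_duplicate_cells_rejected(self):
        with pytest.raises(GrowthError, match="duplicate"):
            build_condition_grid(
                [(10, 50, 0.1, 0.2), (10, 50, 0.1, 0.3)], 3.0
            )

    def test_missing_cells_are_nan(self):
        grid = build_condition_grid(
            [(10, 50, 0.1, 0.2), (20, 100, 0.1, 0.2)], 3.0
        )
        assert np.isnan(grid.mu).sum() == 2

    @given(seed=st.integers(0, 10_000))
    def test_inversion_recovers_known_surface(self, seed):
        rng = np.random.default_rng(seed)
        temps = np.sort(rng.choice(np.arange(5, 41), size=5, replace=False))
        pfds = np.sort(rng.choice(np.arange(10, 351), size=6, replace=False))
        mu_true = rng.uniform(-0.2, 1.5, size=(5, 6))
        duration = float(rng.uniform(0.5, 5))
        plate = [
            (float(t), float(i), 0.05, 0.05 * math.exp(mu_true[a, b] * duration))
            for a, t in enumerate(temps)
            for b, i in enumerate(pfds)
        ]
        grid = build_condition_grid(plate, duration)
        assert np.allclose(grid.mu, mu_true, atol=1e-12)

    def test_grid_csv_export_round_trips(self, tmp_path):
        grid = build_condition_grid(
            [(10, 50, 0.1, 0.2), (10, 100, 0.1, 0.15),
             (20, 50, 0.1, 0.4), (20, 100, 0.1, 0.1)], 3.0
        )
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path, index_col="temperature_c")
        assert np.allclose(back.to_numpy(), grid.mu)


class TestFindOptimum:
    def test_single_cell_grid(self):
        grid = ConditionGrid((21.0,), (88.0,), np.array([[0.4]]))
        opt = find_optimum(grid)
        assert (opt.temperature, opt.pfd, opt.mu_max) == (21.0, 88.0, 0.4)

    def test_peak_at_published_optimum(self):
        temps = (15.0, 18.0, 21.0, 24.0, 27.0)
        pfds = (44.0, 66.0, 88.0, 120.0, 160.0)
        mu = np.fromfunction(
            lambda i, j: 0.5
            - 0.01 * (i - 2) ** 2
            - 0.01 * (j - 2) ** 2,
            (5, 5),
        )
        opt = find_optimum(ConditionGrid(temps, pfds, mu))
        assert (opt.temperature, opt.pfd) == (21.0, 88.0)
        assert opt.plateau_mask[2, 2]

    def test_tie_breaks_toward_lower_temperature_then_pfd(self):
        mu = np.array([[0.1, 0.5], [0.5, 0.2]])
        opt = find_optimum(ConditionGrid((10.0, 20.0), (50.0, 100.0), mu))
        assert (opt.temperature, opt.pfd) == (10.0, 100.0)
        mu2 = np.array([[0.5, 0.5], [0.1, 0.2]])
        opt2 = find_optimum(ConditionGrid((10.0, 20.0), (50.0, 100.0), mu2))
        assert (opt2.temperature, opt2.pfd) == (10.0, 50.0)

    def test_plateau_ranges_cover_near_optimal_cells(self):
        mu = np.array([[0.95, 1.0, 0.96], [0.5, 0.6, 0.5]])
        opt = find_optimum(
            ConditionGrid((18.0, 30.0), (44.0, 88.0, 132.0), mu), 0.9
        )
        assert opt.temperature_range == (18.0, 18.0)
        assert opt.pfd_range == (44.0, 132.0)

    def test_all_nan_grid_rejected(self):
        grid = ConditionGrid((10.0,), (50.0,), np.array([[np.nan]]))
        with pytest.raises(GrowthError):
            find_optimum(grid)


class TestLipidProductivity:
    @pytest.mark.parametrize(
        "cl, t, expected",
        [(0.0, 5.0, 0.0), (1.0, 10.0, 0.1), (0.43, 21.0, 0.0205)],
    )
    def test_values(self, cl, t, expected):
        assert lipid_productivity(cl, t) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(GrowthError):
            lipid_productivity(1.0, 0.0)


def test_csv_readers(tmp_path):
    growth = tmp_path / "growth.csv"
    growth.write_text(
        "condition,time_d,value,measure_kind\n"
        "0.5M,0,7080,density\n0.5M,14,35400,density\n"
        "0M,0,7000,density\n0M,14,6900,density\n"
    )
    series = read_growth_csv(growth)
    assert [s.condition for s in series] == ["0.5M", "0M"]
    assert classify_growth(series[0]) == "growth"
    assert classify_growth(series[1]) == "no_growth"

    plate = tmp_path / "plate.csv"
    plate.write_text(
        "temperature_c,pfd,od_start,od_end\n"
        "10,50,0.1,0.2\n10,100,0.1,0.3\n"
    )
    records = read_plate_csv(plate)
    assert records == [(10.0, 50.0, 0.1, 0.2), (10.0, 100.0, 0.1, 0.3)]
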