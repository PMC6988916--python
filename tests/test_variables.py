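"""Variable construction, exclusion screening and transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestspat import SampleId
from forestspat.variables import (build_sample_frame, compute_cereal_yield,
                                  compute_variables, exclusion_filter,
                                  invert_response, linearize_response,
                                  transform_and_standardize)

from conftest import make_unit

SID = SampleId("ZAM", "micro")


class TestComputeVariables:
    def test_ratio_definitions(self):
        df = compute_variables([make_unit()])
        row = df.iloc[0]
        assert row["FC"] == 0.5            # 50 / 100
        assert row["PVA"] == 0.5           # 100 / 200
        assert row["PP_FA"] == 20.0        # 1000 / 50 forest ha
        assert row["RD"] == 2.0            # 4 km / 2 km^2
        assert row["FL"] == 0.6            # 120 / 200
        assert row["CSI"] == 40.0

    def test_ppfa_per_total_area_mode(self):
        df = compute_variables([make_unit()], ppfa_mode="per_total_area")
        assert df["PP_FA"].iloc[0] == 5.0  # 1000 / 200 ha

    def test_road_density_unit_conversion(self):
        # 4 km of road in 400 ha = 4 km^2 -> 1 km/km^2
        df = compute_variables([make_unit(A_TOT=400.0, R_TOT=4.0)])
        assert df["RD"].iloc[0] == 1.0

    def test_zero_potential_forest_flags_not_raises(self):
        df = compute_variables([make_unit(FA=0.0, FA_pot=0.0)])
        assert np.isnan(df["FC"].iloc[0])

    def test_cy_column_dropped_when_fully_absent(self):
        assert "CY" not in compute_variables([make_unit()]).columns
        assert "CY" in compute_variables([make_unit(CY=1e6)]).columns


class TestCerealYield:
    def test_constant_series_times_factor(self):
        maize = {y: 2.0 for y in range(2000, 2016)}
        assert compute_cereal_yield(maize, None, (3.58e6, 2.8e6), 2015) == \
            pytest.approx(2.0 * 3.58e6)

    def test_max_rule_prefers_more_caloric_crop(self):
        maize = {y: 2.0 for y in range(2006, 2016)}
        rice = {y: 3.0 for y in range(2006, 2016)}
        out = compute_cereal_yield(maize, rice, (1.0e6, 1.0e6), 2015)
        assert out == pytest.approx(3.0e6)

    def test_matches_direct_mean_loop(self, rng):
        years = list(range(2006, 2016))
        maize = dict(zip(years, rng.uniform(1, 5, 10)))
        factor = 3.58e6
        expected = sum(maize.values()) / 10 * factor
        assert compute_cereal_yield(maize, None, (factor, 1.0), 2015) == \
            pytest.approx(expected, rel=1e-12)

    def test_window_is_trailing_ten_years(self):
        maize = {1990: 100.0, 2010: 2.0}  # the 1990 value must not leak in
        assert compute_cereal_yield(maize, None, (1.0, 1.0), 2015) == 2.0

    def test_empty_window_returns_absent(self):
        assert compute_cereal_yield({1990: 2.0}, None, (1.0, 1.0), 2015) is None
        assert compute_cereal_yield(None, None, (1.0, 1.0), 2015) is None


class TestExclusionFilter:
    def table(self, **overrides):
        units = [
            make_unit(unit_id="ok"),
            make_unit(unit_id="bare", FA=0.0),            # FC nil
            make_unit(unit_id="full", FA=100.0),          # FC extreme
            make_unit(unit_id="nocsi", CSI=0.0),          # CSI nil
            make_unit(unit_id="noroad", R_TOT=0.0),       # RD nil
        ]
        return compute_variables(units)

    def test_reasons_reported_per_unit(self):
        kept, report = exclusion_filter(self.table())
        assert list(kept.index) == ["ok"]
        reasons = dict(zip(report.unit_id, report.reason))
        assert reasons["bare"] == "FC nil"
        assert reasons["full"] == "FC extreme"
        assert "CSI nil" in reasons["nocsi"]
        assert "RD nil" in reasons["noroad"]

    def test_all_valid_keeps_everything(self):
        table = compute_variables(
            [make_unit(unit_id=f"u{i}", FA=30.0 + i) for i in range(10)])
        kept, report = exclusion_filter(table)
        assert len(kept) == 10 and report.empty

    def test_zero_flatness_does_not_exclude(self):
        table = compute_variables([make_unit(unit_id="flat0", FL_TOT=0.0),
                                   make_unit(unit_id="other")])
        kept, _ = exclusion_filter(table)
        assert "flat0" in kept.index

    def test_idempotent_and_order_independent(self, rng):
        table = self.table()
        kept1, _ = exclusion_filter(table)
        kept2, rep2 = exclusion_filter(kept1)
        assert kept1.equals(kept2) and rep2.empty
        shuffled = table.iloc[rng.permutation(len(table))]
        kept3, _ = exclusion_filter(shuffled)
        assert sorted(kept3.index) == sorted(kept1.index)

    def test_everything_excluded_raises(self):
        table = compute_variables([make_unit(FA=0.0)])
        with pytest.raises(ValueError):
            exclusion_filter(table)


class TestLinearization:
    def test_known_points(self):
        out = linearize_response(np.array([0.5, 0.25, 0.75]))
        assert out[0] == pytest.approx(0.0, abs=1e-15)
        assert out[1] == pytest.approx(np.log(3.0))
        assert out[2] == pytest.approx(-np.log(3.0))  # antisymmetric about 1/2

    def test_strictly_decreasing_in_fc(self):
        fc = np.linspace(0.01, 0.99, 99)
        assert np.all(np.diff(linearize_response(fc)) < 0)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1 - 1e-9),
                    min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, fcs):
        fc = np.array(fcs)
        assert np.allclose(invert_response(linearize_response(fc)), fc,
                           atol=1e-12)

    def test_boundary_values_raise(self):
        for bad in ([0.0, 0.5], [0.5, 1.0], [np.nan]):
            with pytest.raises(ValueError):
                linearize_response(np.array(bad))


class TestStandardization:
    def frame(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        units = [make_unit(unit_id=f"u{i}",
                           A_TOT=rng.uniform(300, 600),
                           FA=rng.uniform(20, 80),
                           FA_pot=rng.uniform(90, 250),
                           P_TOT=rng.uniform(200, 5000),
                           R_TOT=rng.uniform(1, 10),
                           FL_TOT=rng.uniform(50, 280),
                           CSI=rng.uniform(10, 90))
                 for i in range(n)]
        table = compute_variables(units)
        return transform_and_standardize(table, SID)

    def test_columns_have_mean_zero_sd_one(self):
        frame = self.frame()
        assert np.allclose(frame.X_std.mean(), 0.0, atol=1e-10)
        assert np.allclose(frame.X_std.std(ddof=1), 1.0, atol=1e-10)

    def test_log_transform_is_recorded(self):
        frame = self.frame()
        assert np.allclose(frame.X_log, np.log(frame.X_raw))
        assert np.allclose(
            frame.X_std, (frame.X_log - frame.mu) / frame.sigma)

    def test_sd_uses_sample_denominator(self):
        frame = self.frame()
        assert np.allclose(frame.sigma, frame.X_log.std(ddof=1))

    def test_standardization_is_idempotent(self):
        frame = self.frame()
        again = (frame.X_std - frame.X_std.mean()) / frame.X_std.std(ddof=1)
        assert np.allclose(again, frame.X_std, atol=1e-12)

    def test_correlations_invariant_under_standardization(self):
        frame = self.frame()
        assert np.allclose(frame.X_log.corr(), frame.X_std.corr(), atol=1e-12)

    def test_constant_column_raises_with_name(self):
        units = [make_unit(unit_id=f"u{i}", FA=30.0 + i) for i in range(10)]
        table = compute_variables(units)
        with pytest.raises(ValueError, match="CSI"):
            transform_and_standardize(table, SID)

    def test_partial_cy_column_is_dropped(self):
        rng = np.random.default_rng(3)
        units = [make_unit(unit_id=f"u{i}", FA=rng.uniform(20, 80),
                           A_TOT=rng.uniform(300, 600),
                           FA_pot=rng.uniform(90, 250),
                           P_TOT=rng.uniform(100, 900),
                           R_TOT=rng.uniform(1, 9),
                           FL_TOT=rng.uniform(50, 280),
                           CSI=rng.uniform(10, 90),
                           CY=None if i == 0 else 5e6 + i)
                 for i in range(10)]
        frame = transform_and_standardize(compute_variables(units), SID)
        assert "CY" not in frame.X_std.columns

    def test_zero_flatness_blocks_log_with_message(self):
        units = [make_unit(unit_id="z", FL_TOT=0.0), make_unit(unit_id="b")]
        table = compute_variables(units)
        kept, _ = exclusion_filter(table)
        with pytest.raises(ValueError, match="FL"):
            transform_and_standardize(kept, SID)


def test_build_sample_frame_round_trips_response(small_sample, sample_id):
    units, truth = small_sample
    frame, report = build_sample_frame(units, sample_id)
    assert report.empty
    assert np.allclose(frame.FC_star, truth["FC_star"], atol=1e-12)
    assert np.allclose(invert_response(frame.FC_star), frame.FC, atol=1e-12)
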