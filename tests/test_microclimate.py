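"""Daily/annual summaries, buffering offsets and slopes, group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_meta, make_series
from thermobuffer import microclimate as mc


class TestDailySummaries:
    def test_constant_day(self):
        d = mc.daily_summaries(make_series([20.0] * 24), min_hours=20)
        assert len(d) == 1
        row = d.iloc[0]
        assert row.t_max == row.t_mean == row.t_min == 20.0
        assert row.diurnal_range == 0.0
        assert bool(row.complete)

    def test_four_reading_arithmetic(self):
        d = mc.daily_summaries(make_series([18.0, 22.0, 26.0, 22.0]),
                               min_hours=4)
        row = d.iloc[0]
        assert (row.t_max, row.t_min, row.t_mean, row.diurnal_range) == \
            (26.0, 18.0, 22.0, 8.0)

    def test_incomplete_day_flagged(self):
        d = mc.daily_summaries(make_series([20.0] * 10), min_hours=20)
        assert not bool(d.iloc[0].complete)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 45), min_size=3, max_size=48))
    def test_ordering_invariant(self, temps):
        d = mc.daily_summaries(make_series(temps), min_hours=1)
        assert ((d.t_min <= d.t_mean + 1e-9) & (d.t_mean <= d.t_max + 1e-9)).all()
        assert (d.diurnal_range >= 0).all()


class TestAnnualSummary:
    def _dailies(self, tmax):
        n = len(tmax)
        return pd.DataFrame({
            "logger_id": "L1",
            "date": pd.date_range("2017-02-01", periods=n, freq="D"),
            "t_max": tmax, "t_mean": np.asarray(tmax) - 5.0,
            "t_min": np.asarray(tmax) - 10.0,
            "diurnal_range": 10.0, "n_hours": 24, "complete": True,
        })

    def test_exceedance_is_strict(self):
        out = mc.annual_summary(self._dailies([38.0, 39.0, 39.5, 40.0, 41.0]),
                                thresholds=(39.0,))
        assert out["days_above_39"] == 3

    def test_constant_range(self):
        out = mc.annual_summary(self._dailies([30.0] * 10), thresholds=())
        assert out["mean_diurnal_range"] == 10.0

    def test_all_days_incomplete_is_error(self):
        d = self._dailies([30.0] * 5).assign(complete=False)
        with pytest.raises(ValueError):
            mc.annual_summary(d)

    def test_translation_leaves_range_and_seasonality(self):
        base = self._dailies(20.0 + 3 * np.sin(np.arange(120)))
        shifted = base.assign(t_max=base.t_max + 5, t_mean=base.t_mean + 5,
                              t_min=base.t_min + 5)
        a, b = mc.annual_summary(base), mc.annual_summary(shifted)
        assert b["mean_diurnal_range"] == pytest.approx(a["mean_diurnal_range"])
        assert b["seasonality"] == pytest.approx(a["seasonality"])


class TestSeasonality:
    def test_equal_months_zero(self):
        assert mc.seasonality([22.0] * 12) == 0.0

    def test_two_month_sd_oracle(self):
        assert mc.seasonality([10.0, 20.0]) == pytest.approx(7.0711, abs=1e-4)

    def test_matches_direct_sd(self, rng):
        m = 20 + 2 * np.sin(np.linspace(0, 2 * np.pi, 12))
        assert mc.seasonality(m) == pytest.approx(float(np.std(m, ddof=1)))

    def test_single_month_rejected(self):
        with pytest.raises(ValueError):
            mc.seasonality([20.0])


def _paired_dailies(sub_max, und_max, n=30):
    def mk(lid, tmax):
        return pd.DataFrame({
            "logger_id": lid,
            "date": pd.date_range("2017-02-01", periods=n, freq="D"),
            "t_max": tmax, "t_mean": tmax - 5.0, "t_min": tmax - 10.0,
            "diurnal_range": 10.0, "n_hours": 24, "complete": True,
        })
    metas = {
        "S": make_meta("S", stratum="subcanopy", site_id="s1"),
        "U": make_meta("U", stratum="understorey", site_id="s1", height_m=1.2),
    }
    return {"S": mk("S", sub_max), "U": mk("U", und_max)}, metas


class TestStratumOffsets:
    def test_identical_series_zero_offset(self):
        dailies, metas = _paired_dailies(30.0, 30.0)
        out = mc.stratum_offsets(dailies, metas)
        assert np.allclose(out["offset_c"], 0.0)

    def test_constant_difference(self):
        dailies, metas = _paired_dailies(30.0, 28.0)
        out = mc.stratum_offsets(dailies, metas)
        got = out.set_index("statistic")["offset_c"]
        assert got["daily_max"] == pytest.approx(2.0)

    def test_antisymmetric_under_stratum_swap(self, rng):
        a = 30.0 + rng.normal(0, 1, 30)
        b = 28.0 + rng.normal(0, 1, 30)
        d1, m1 = _paired_dailies(a, b)
        d2, m2 = _paired_dailies(b, a)
        o1 = mc.stratum_offsets(d1, m1).set_index("statistic")["offset_c"]
        o2 = mc.stratum_offsets(d2, m2).set_index("statistic")["offset_c"]
        for stat in ("daily_max", "daily_mean", "daily_min"):
            assert o1[stat] == pytest.approx(-o2[stat])


class TestBufferingSlope:
    def test_identity_coupling(self):
        df = pd.DataFrame({"t_sub": [20.0, 22, 25, 27], "t_und": [20.0, 22, 25, 27]})
        fit = mc.buffering_slope(df)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_linear_relation(self):
        x = np.linspace(18, 30, 50)
        fit = mc.buffering_slope(pd.DataFrame({"t_sub": x, "t_und": 5 + 0.68 * x}))
        assert fit.slope == pytest.approx(0.68, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"t_sub": [20.0, 20.0], "t_und": [18.0, 19.0]})
        with pytest.raises(ValueError):
            mc.buffering_slope(df)

    def test_alignment_drops_unshared_hours(self):
        sub = make_series([20.0, 21, 22], logger_id="S")
        und = make_series([19.0, 20], logger_id="U")
        aligned = mc.align_strata_hours(sub, und)
        assert len(aligned) == 2


class TestLapseRate:
    def test_two_point_oracle(self):
        annual = pd.DataFrame({"logger_id": ["a", "b"],
                               "mean_daily_mean": [25.0, 20.0]})
        metas = {"a": make_meta("a", elevation_masl=500.0),
                 "b": make_meta("b", elevation_masl=1500.0, area="west-high")}
        out = mc.lapse_rate(annual, metas)
        assert out["slope_c_per_m"] == pytest.approx(-0.005)
        assert out["slope_c_per_10m"] == pytest.approx(-0.05)

    def test_flat_temperatures(self):
        annual = pd.DataFrame({"logger_id": list("abc"),
                               "mean_daily_mean": [20.0] * 3})
        metas = {k: make_meta(k, elevation_masl=e)
                 for k, e in zip("abc", (400.0, 900.0, 1400.0))}
        assert mc.lapse_rate(annual, metas)["slope_c_per_m"] == pytest.approx(0.0)

    def test_equal_elevations_rejected(self):
        annual = pd.DataFrame({"logger_id": ["a", "b"],
                               "mean_daily_mean": [25.0, 20.0]})
        metas = {k: make_meta(k, elevation_masl=500.0) for k in "ab"}
        with pytest.raises(ValueError):
            mc.lapse_rate(annual, metas)


class TestGroupComparison:
    def test_pooled_t_oracle(self):
        out = mc.group_comparison({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        row = out.iloc[0]
        assert row.t == pytest.approx(-3.674, abs=1e-3)
        assert row.df == 4

    def test_identical_groups(self):
        out = mc.group_comparison({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert out.iloc[0].t == pytest.approx(0.0)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_tukey_no_false_positives_on_equal_means(self, rng):
        flags = 0
        reps = 150
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0, 1, 10) for i in range(4)}
            out = mc.group_comparison(groups, design="pairwise-all")
            flags += (out["p"] < 0.05).any()
        # familywise error should be ~alpha; allow generous slack
        assert flags / reps <= 0.07

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            mc.group_comparison({"a": [1.0, 1.0], "b": [2.0, 2.0]})
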