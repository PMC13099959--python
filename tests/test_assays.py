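"""Single-strain assay formulas and the buffering analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfcomp import (
    GrowthCurve,
    MatingCounts,
    ReporterMeasurement,
    aggregate_fields,
    classify_rescue,
    expected_double,
    lag_time,
    mating_rate,
    miller_units,
    ph_profile,
    rescue_panel,
)
from mfcomp.assays import lag_time_table, mating_rate_table, miller_units_table


class TestMatingRate:
    @pytest.mark.parametrize(
        "V,Z,A,S,expected",
        [
            (100, 0, 0, 0, 0.0),  # all vegetative
            (0, 10, 0, 0, 100.0),  # all zygotes
            (0, 0, 7, 0, 100.0),  # all asci
            (80, 5, 5, 20, 3000 / 110),  # (2*5+2*5+0.5*20)*100 / (80+30)
            (50, 10, 5, 8, (2 * 10 + 2 * 5 + 0.5 * 8) * 100 / (50 + 34)),
            (10, 0, 0, 4, 200 / 12),
        ],
    )
    def test_printed_formula(self, V, Z, A, S, expected):
        assert mating_rate(MatingCounts(V, Z, A, S)) == pytest.approx(expected, rel=1e-12)

    def test_unscorable_field(self):
        with pytest.raises(ValueError, match="unscorable"):
            mating_rate(MatingCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatingCounts(-1, 0, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 500), st.integers(0, 100), st.integers(0, 100), st.integers(0, 200))
    def test_bounded_in_0_100(self, V, Z, A, S):
        if V + Z + A + S == 0:
            return
        assert 0.0 <= mating_rate(MatingCounts(V, Z, A, S)) <= 100.0

    def test_monotone_in_counts(self):
        base = mating_rate(MatingCounts(50, 5, 5, 10))
        assert mating_rate(MatingCounts(50, 6, 5, 10)) > base
        assert mating_rate(MatingCounts(50, 5, 6, 10)) > base
        assert mating_rate(MatingCounts(50, 5, 5, 11)) > base
        assert mating_rate(MatingCounts(51, 5, 5, 10)) < base


class TestAggregateFields:
    def test_identical_fields(self):
        agg = aggregate_fields({1: [40.0] * 9})
        assert agg.replicate_means[1] == 40.0
        assert agg.mean == 40.0 and agg.sd is None

    def test_field_mean(self):
        agg = aggregate_fields({1: [10.0, 20.0, 30.0]})
        assert agg.replicate_means[1] == pytest.approx(20.0)

    def test_two_level_aggregation_not_pooled(self):
        # replicate means are averaged, fields are never pooled across reps
        agg = aggregate_fields({1: [0.0, 100.0], 2: [50.0]})
        assert agg.mean == pytest.approx(50.0)
        assert agg.sd == pytest.approx(0.0)

    def test_empty_replicate_is_an_error(self):
        with pytest.raises(ValueError, match="no fields"):
            aggregate_fields({1: []})


class TestMillerUnits:
    @pytest.mark.parametrize(
        "od420,od600,vol,t,expected",
        [
            (0.0, 5.0, 0.2, 30, 0.0),
            (0.5, 5.0, 0.2, 30, 500 / 30),
            (1.0, 1.0, 1.0, 1.0, 1000.0),
            (0.25, 2.0, 0.1, 15, 250 / 3),
            (0.8, 4.0, 0.5, 20, 800 / 40),
        ],
    )
    def test_printed_formula(self, od420, od600, vol, t, expected):
        mu = miller_units(ReporterMeasurement(od420, od600, vol, t))
        assert mu == pytest.approx(expected, rel=1e-12)

    def test_scaling_properties(self):
        base = ReporterMeasurement(0.5, 5.0, 0.2, 30)
        mu = miller_units(base)
        assert miller_units(ReporterMeasurement(1.0, 5.0, 0.2, 30)) == pytest.approx(2 * mu)
        assert miller_units(ReporterMeasurement(0.5, 5.0, 0.2, 60)) == pytest.approx(mu / 2)
        assert miller_units(ReporterMeasurement(0.5, 10.0, 0.2, 30)) == pytest.approx(mu / 2)
        assert miller_units(ReporterMeasurement(0.5, 5.0, 0.4, 30)) == pytest.approx(mu / 2)

    def test_invalid_measurement_rejected(self):
        with pytest.raises(ValueError):
            ReporterMeasurement(0.5, 0.0, 0.2, 30)
        with pytest.raises(ValueError):
            ReporterMeasurement(0.5, 5.0, -0.2, 30)


class TestLagTime:
    def test_starts_above_threshold(self):
        assert lag_time(GrowthCurve([0, 10], [0.6, 0.7])) == 0.0

    def test_linear_interpolation(self):
        assert lag_time(GrowthCurve([0, 10], [0.4, 0.6])) == pytest.approx(5.0)

    def test_never_reached(self):
        assert lag_time(GrowthCurve([0, 10, 20], [0.1, 0.2, 0.3])) is None

    def test_monotone_under_pointwise_dominance(self):
        t = np.arange(0, 200, 10.0)
        slow = 0.7 / (1 + np.exp(-(t - 100) / 20))
        fast = slow * 1.3
        assert lag_time(GrowthCurve(t, fast)) <= lag_time(GrowthCurve(t, slow))

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurve([0, 0], [0.1, 0.2])
        with pytest.raises(ValueError):
            GrowthCurve([0], [0.1])


class TestPhProfile:
    def test_flat_profile_tie_breaks_to_lowest_ph(self):
        prof = ph_profile({4.0: [30.0], 5.5: [30.0], 7.0: [30.0]})
        assert prof.optimum_pH == 4.0

    def test_peaked_profile(self):
        rates = {ph: [5.0, 6.0] for ph in np.arange(4.0, 9.5, 0.5)}
        rates[8.0] = [48.0, 52.0]  # alkaline-activated peak
        prof = ph_profile(rates)
        assert prof.optimum_pH == 8.0
        assert prof.table.loc[8.0, "mean"] == pytest.approx(50.0)

    def test_single_replicate_sd_absent(self):
        prof = ph_profile({4.0: [10.0], 7.0: [20.0]})
        assert np.isnan(prof.table["sd"]).all()

    def test_needs_two_ph_levels(self):
        with pytest.raises(ValueError):
            ph_profile({5.5: [10.0]})


class TestBuffering:
    def test_neutral_partner(self):
        assert expected_double(60.0, 40.0, 60.0) == pytest.approx(40.0)

    def test_direct_value(self):
        assert expected_double(30.0, 40.0, 60.0) == pytest.approx(20.0)

    def test_dead_single_gives_zero(self):
        assert expected_double(0.0, 40.0, 60.0) == 0.0

    def test_wt_zero_is_an_error(self):
        with pytest.raises(ValueError):
            expected_double(30.0, 40.0, 0.0)

    @pytest.mark.parametrize(
        "single,double,expected",
        [
            (0.2, 5.0, "rescued"),  # near-zero single restored to a few percent
            (0.2, 0.5, "not_rescued"),
            (20.0, 25.0, "not_rescued"),  # single not near-zero
            (0.9, 3.0, "rescued"),  # boundary: double exactly at the minimum
            (1.0, 9.0, "not_rescued"),  # single exactly at the floor
        ],
    )
    def test_rescue_rule(self, single, double, expected):
        assert classify_rescue(single, double) == expected

    def test_rescue_monotonicity(self):
        assert classify_rescue(0.5, 4.0) == "rescued"
        assert classify_rescue(0.5, 2.9) == "not_rescued"  # lower double cannot rescue more
        assert classify_rescue(1.5, 4.0) == "not_rescued"  # higher single cannot rescue more

    def test_rescue_panel(self):
        singles = {"V5D": 0.1, "V5H": 0.3, "Y7E": 15.0}
        doubles = {"V5D": 6.0, "V5H": 0.4, "Y7E": 18.0}
        panel = rescue_panel(singles, doubles, wt_rate=60.0)
        assert panel.loc["V5D", "call"] == "rescued"
        assert panel.loc["V5H", "call"] == "not_rescued"
        assert panel.loc["Y7E", "call"] == "not_rescued"

    def test_rescue_panel_mismatched_variants(self):
        with pytest.raises(ValueError):
            rescue_panel({"V5D": 0.1}, {"Y7E": 5.0}, wt_rate=60.0)


class TestTableInterfaces:
    def test_mating_rate_table_two_level(self):
        rows = []
        for rep in (1, 2, 3):
            for fld in range(1, 4):
                rows.append(("WT", "MEA", rep, fld, 50, 10, 5, 4))
        df = pd.DataFrame(rows, columns=["genotype", "condition", "replicate", "field", "V", "Z", "A", "S"])
        out = mating_rate_table(df)
        expected = mating_rate(MatingCounts(50, 10, 5, 4))
        assert out.loc[0, "mean"] == pytest.approx(expected)
        assert out.loc[0, "n_replicates"] == 3

    def test_miller_units_table(self):
        df = pd.DataFrame(
            [("WT", 10.0, 5.5, r, 0.5, 5.0, 0.2, 30.0) for r in (1, 2, 3)],
            columns=["genotype", "peptide_conc_uM", "pH", "replicate", "od420", "od600", "volume_ml", "time_min"],
        )
        out = miller_units_table(df)
        assert out.loc[0, "mean"] == pytest.approx(500 / 30)

    def test_lag_time_table(self):
        df = pd.DataFrame(
            [("WT", 1, 0.0, 0.4), ("WT", 1, 10.0, 0.6), ("T2Q", 1, 0.0, 0.1), ("T2Q", 1, 10.0, 0.2)],
            columns=["genotype", "replicate", "time_min", "od600"],
        )
        out = lag_time_table(df).set_index("genotype")
        assert out.loc["WT", "lag_min"] == pytest.approx(5.0)
        assert np.isnan(out.loc["T2Q", "lag_min"])
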