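"""Dependency ratios: closed-form values, equivalences, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import demodep as d


def frame_from_weights(u15=0.0, working=0.0, old=0.0, active_working=None,
                       period=2015):
    """Toy frame with the given weighted person counts in three age blocks."""
    rows = []
    if u15:
        rows.append({"age_group": "5-9", "sex": "female", "education": "none",
                     "activity": "not_applicable", "weight": u15})
    if working:
        active_w = working if active_working is None else active_working
        inactive_w = working - active_w
        if active_w:
            rows.append({"age_group": "40-44", "sex": "male",
                         "education": "upper_secondary", "activity": "active",
                         "weight": active_w})
        if inactive_w:
            rows.append({"age_group": "40-44", "sex": "female",
                         "education": "upper_secondary", "activity": "inactive",
                         "weight": inactive_w})
    if old:
        rows.append({"age_group": "70-74", "sex": "male",
                     "education": "primary", "activity": "inactive", "weight": old})
    return d.PopulationFrame(pd.DataFrame(rows), period)


UNIT = d.ProductivityWeights(
    weights={lvl: 1.0 for lvl in d.DEFAULT_LADDER.levels}
)


class TestAdr:
    def test_thirty_eight_dependents_per_hundred_workers(self):
        frame = frame_from_weights(u15=20, working=100, old=18)
        assert d.adr(frame) == pytest.approx(0.38)

    def test_all_working_age_gives_zero(self):
        assert d.adr(frame_from_weights(working=50)) == 0.0

    def test_hand_arithmetic(self):
        frame = frame_from_weights(u15=30, working=60, old=12)
        assert d.adr(frame) == pytest.approx(0.70)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            d.adr(frame_from_weights(u15=10, old=5))


class TestLfdr:
    def test_everyone_active_gives_zero(self):
        assert d.lfdr(frame_from_weights(working=80)) == 0.0

    def test_children_count_as_inactive(self):
        frame = frame_from_weights(u15=30, working=120, active_working=100, old=0)
        # inactive = 30 children + 20 inactive adults
        assert d.lfdr(frame) == pytest.approx(0.5)

    def test_zero_active_raises(self):
        with pytest.raises(ZeroDivisionError):
            d.lfdr(frame_from_weights(working=10, active_working=0))


class TestPwlfdr:
    def test_reference_only_frame_gives_one(self):
        frame = frame_from_weights(working=200, active_working=100)
        assert d.pwlfdr(frame, UNIT) == pytest.approx(1.0)

    def test_hand_computed_with_published_weight_endpoints(self):
        # 60 inactives; 50 active at W=0.36 and 50 at W=2.03
        rows = [
            {"age_group": "40-44", "sex": "female", "education": "upper_secondary",
             "activity": "inactive", "weight": 60.0},
            {"age_group": "40-44", "sex": "male", "education": "no_education",
             "activity": "active", "weight": 50.0},
            {"age_group": "40-44", "sex": "male", "education": "postsecondary",
             "activity": "active", "weight": 50.0},
        ]
        frame = d.PopulationFrame(pd.DataFrame(rows), 2015)
        weights = d.ProductivityWeights(
            weights={"no_education": 0.36, "primary": 0.6, "lower_secondary": 0.8,
                     "upper_secondary": 1.0, "postsecondary": 2.03}
        )
        expected = 60.0 / (0.36 * 50 + 2.03 * 50)
        assert d.pwlfdr(frame, weights) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5020920502092050, abs=1e-12)

    def test_doubling_weights_halves_the_ratio(self):
        frame = frame_from_weights(u15=40, working=150, active_working=90, old=25)
        base = d.ProductivityWeights(
            weights={"no_education": 0.4, "primary": 0.6, "lower_secondary": 0.8,
                     "upper_secondary": 1.0, "postsecondary": 2.0}
        )
        doubled = d.ProductivityWeights(
            weights={k: 2 * v for k, v in base.weights.items()},
            reference="__none__",
        )
        assert d.pwlfdr(frame, doubled) == pytest.approx(
            d.pwlfdr(frame, base) / 2, rel=1e-12
        )

    def test_missing_weight_raises(self):
        frame = frame_from_weights(working=100, active_working=60)
        with pytest.raises(KeyError):
            d.pwlfdr(frame, d.ProductivityWeights(weights={"primary": 0.5}))

    @given(
        inactive=st.floats(1, 1e4), a1=st.floats(1, 1e4), a2=st.floats(1, 1e4),
        scale=st.floats(0.01, 100),
    )
    def test_unit_weight_equivalence_and_scale_invariance(self, inactive, a1, a2, scale):
        rows = [
            {"age_group": "10-14", "sex": "male", "education": "none",
             "activity": "not_applicable", "weight": inactive},
            {"age_group": "30-34", "sex": "male", "education": "primary",
             "activity": "active", "weight": a1},
            {"age_group": "50-54", "sex": "female", "education": "postsecondary",
             "activity": "active", "weight": a2},
        ]
        frame = d.PopulationFrame(pd.DataFrame(rows), 2015)
        assert d.pwlfdr(frame, UNIT) == pytest.approx(d.lfdr(frame), rel=1e-12)
        scaled_rows = [dict(r, weight=r["weight"] * scale) for r in rows]
        scaled = d.PopulationFrame(pd.DataFrame(scaled_rows), 2015)
        assert d.lfdr(scaled) == pytest.approx(d.lfdr(frame), rel=1e-9)
        assert d.adr(scaled) == pytest.approx(d.adr(frame), rel=1e-9)
        assert d.pwlfdr(scaled, UNIT) == pytest.approx(d.pwlfdr(frame, UNIT), rel=1e-9)


class TestNormalizeSeries:
    def test_constant_series_normalizes_to_one(self):
        s = pd.DataFrame({"adr": [0.4, 0.4], "lfdr": [1.1, 1.1], "pwlfdr": [0.9, 0.9]},
                         index=[2015, 2020])
        out = d.normalize_series(s, 2015)
        assert (out.to_numpy() == 1.0).all()

    def test_base_maps_to_one_and_ratios_scale(self):
        s = pd.DataFrame({"adr": [0.4, 0.6]}, index=[2015, 2040])
        out = d.normalize_series(s, 2015)
        assert out.loc[2015, "adr"] == 1.0
        assert out.loc[2040, "adr"] == pytest.approx(1.5)

    def test_normalization_preserves_scenario_ordering(self):
        low = pd.DataFrame({"adr": [0.5, 0.7, 1.2]}, index=[2015, 2020, 2025])
        high = pd.DataFrame({"adr": [0.5, 0.8, 1.1]}, index=[2015, 2020, 2025])
        nl, nh = d.normalize_series(low, 2015), d.normalize_series(high, 2015)
        assert ((nl["adr"] < nh["adr"]) == (low["adr"] < high["adr"])).all()

    def test_zero_base_raises(self):
        s = pd.DataFrame({"adr": [0.0, 0.5]}, index=[2015, 2020])
        with pytest.raises(ZeroDivisionError):
            d.normalize_series(s, 2015)


class TestPyramidAndActiveCounts:
    def test_partition_reproduces_total(self, estimates):
        cfg = d.ScenarioConfig(tfr=1.0, sampling_fraction=0.02)
        frame = d.build_base_population(estimates, cfg)
        table = d.pyramid_summary(frame)
        assert table["weight"].sum() == pytest.approx(frame.weighted_total)

    def test_collapse_map_matches_low_medium_high(self, ladder):
        mapping = d.tier_map(ladder)
        assert mapping["lower_secondary"] == "low"
        assert mapping["no_education"] == "low"
        assert mapping["upper_secondary"] == "medium"
        assert mapping["postsecondary"] == "high"

    def test_empty_frame_gives_empty_table(self):
        frame = d.PopulationFrame(
            pd.DataFrame(columns=["age_group", "sex", "education", "activity", "weight"]),
            2015,
        )
        assert len(d.pyramid_summary(frame)) == 0

    def test_active_counts_match_lfdr_denominator(self, estimates, schedules, fitted_lfp, productivity_weights):
        cfg = d.ScenarioConfig(tfr=1.7, horizon=2025, sampling_fraction=0.02, seed=4)
        base = d.build_base_population(estimates, cfg)
        traj = d.run_projection(base, schedules, fitted_lfp, cfg)
        counts = d.active_counts_by_education(traj)
        for frame, _ in traj:
            total_active = counts.loc[counts["period"] == frame.period, "active_weight"].sum()
            inactive = frame.weighted_total - total_active
            assert inactive / total_active == pytest.approx(d.lfdr(frame), rel=1e-9)

    def test_education_expansion_grows_postsecondary_workforce(self):
        """Constructed cohort-replacement trajectory: total actives shrink,
        postsecondary actives never do."""
        frames = []
        for i, (total, post) in enumerate([(1000, 100), (900, 180), (800, 260)]):
            rows = [
                {"age_group": "40-44", "sex": "male", "education": "postsecondary",
                 "activity": "active", "weight": post},
                {"age_group": "40-44", "sex": "male", "education": "primary",
                 "activity": "active", "weight": total - post},
                {"age_group": "70-74", "sex": "male", "education": "primary",
                 "activity": "inactive", "weight": 500},
            ]
            frames.append(d.PopulationFrame(pd.DataFrame(rows), 2015 + 5 * i))
        counts = d.active_counts_by_education(frames)
        high = counts[counts["tier"] == "high"].sort_values("period")["active_weight"]
        totals = counts.groupby("period")["active_weight"].sum()
        assert (high.diff().dropna() >= 0).all()
        assert (totals.diff().dropna() < 0).all()

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            d.active_counts_by_education([])
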