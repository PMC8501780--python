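"""Projection engine: event semantics, Monte Carlo envelopes, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import demodep as d
from demodep.engine import age_increment
from demodep.types import RateSchedules


def cfg(**kw):
    kw.setdefault("tfr", 1.0)
    kw.setdefault("seed", 11)
    return d.ScenarioConfig(**kw)


def bulk_frame(n, age_group="40-44", sex="male", education="upper_secondary",
               weight=1.0, period=2015, activity=None):
    df = pd.DataFrame(
        {
            "age_group": [age_group] * n,
            "sex": [sex] * n,
            "education": [education] * n,
            "weight": [weight] * n,
        }
    )
    if activity:
        df["activity"] = activity
    return d.PopulationFrame(df, period)


def flat_schedules(period=2015, survival=1.0, emigration=0.0,
                   entry=None, advance=None, nb_survival=1.0):
    """Minimal single-period schedule tables with uniform rates."""
    ladder = d.DEFAULT_LADDER
    surv, emig = [], []
    for code, lab in enumerate(d.AGE_LABELS):
        for sex in ("male", "female"):
            emig.append((period, lab, sex, emigration))
            if code <= 2:
                surv.append((period, lab, sex, "none", survival))
            else:
                for lvl in ladder.levels:
                    surv.append((period, lab, sex, lvl, survival))
    tr = []
    if entry:
        for sex in ("male", "female"):
            for lvl, p in entry.items():
                tr.append((period, "15-19", sex, "none", lvl, p))
    if advance:
        for age_lab, from_lvl, to_lvl, p in advance:
            for sex in ("male", "female"):
                tr.append((period, age_lab, sex, from_lvl, to_lvl, p))
    shape = np.array([0.05, 0.35, 0.30, 0.17, 0.09, 0.03, 0.01])
    shape = shape / (5 * shape.sum())
    fert = [(period, d.AGE_LABELS[3 + i], s) for i, s in enumerate(shape)]
    nb = [(period, "male", nb_survival), (period, "female", nb_survival)]
    return RateSchedules(
        survival=pd.DataFrame(surv, columns=["period", "age_group", "sex", "education", "ratio"]),
        education_transitions=pd.DataFrame(
            tr, columns=["period", "age_group", "sex", "from_level", "to_level", "prob"]
        ),
        fertility=pd.DataFrame(fert, columns=["period", "age_group", "shape"]),
        emigration=pd.DataFrame(emig, columns=["period", "age_group", "sex", "rate"]),
        immigration=pd.DataFrame(
            columns=["period", "age_group", "sex", "education", "count"]
        ),
        newborn_survival=pd.DataFrame(nb, columns=["period", "sex", "ratio"]),
    )


class TestMortality:
    def test_ratio_one_keeps_everyone(self):
        frame = bulk_frame(1_000)
        out, deaths = d.step_mortality(frame, flat_schedules(survival=1.0), seed=1)
        assert out.n_cases == 1_000 and deaths == 0.0

    def test_ratio_zero_removes_everyone(self):
        frame = bulk_frame(1_000, weight=2.0)
        out, deaths = d.step_mortality(frame, flat_schedules(survival=1e-12), seed=1)
        assert out.n_cases == 0
        assert deaths == pytest.approx(2_000.0)

    def test_binomial_envelope_at_100k(self):
        frame = bulk_frame(100_000)
        out, _ = d.step_mortality(frame, flat_schedules(survival=0.8), seed=1)
        sd = np.sqrt(100_000 * 0.8 * 0.2)
        assert abs(out.n_cases - 80_000) <= 3 * sd

    def test_missing_stratum_is_reported(self):
        frame = bulk_frame(10)
        sched = flat_schedules()
        sched.survival = sched.survival[sched.survival["age_group"] != "40-44"]
        with pytest.raises(ValueError, match="survival.*40-44"):
            d.step_mortality(frame, sched, seed=1)


class TestEducation:
    def test_identity_transitions_change_nothing(self):
        frame = bulk_frame(500, age_group="20-24", education="primary")
        out = d.step_education(frame, flat_schedules(), seed=1)
        pd.testing.assert_frame_equal(out.data, frame.data)

    def test_certain_transition_advances_everyone(self):
        frame = bulk_frame(500, age_group="20-24", education="primary")
        sched = flat_schedules(advance=[("20-24", "primary", "lower_secondary", 1.0)])
        out = d.step_education(frame, sched, seed=1)
        assert (out.data["education"] == "lower_secondary").all()

    def test_half_probability_binomial_envelope(self):
        frame = bulk_frame(40_000, age_group="20-24", education="primary")
        sched = flat_schedules(advance=[("20-24", "primary", "lower_secondary", 0.5)])
        out = d.step_education(frame, sched, seed=1)
        moved = int((out.data["education"] == "lower_secondary").sum())
        assert abs(moved - 20_000) <= 3 * np.sqrt(40_000 * 0.25)

    def test_entry_distribution_assigns_all_new_adults(self):
        frame = bulk_frame(2_000, age_group="15-19", education="none",
                           activity="not_applicable")
        sched = flat_schedules(entry={"lower_secondary": 0.3, "upper_secondary": 0.7})
        out = d.step_education(frame, sched, seed=1)
        counts = out.data["education"].value_counts()
        assert counts.get("none", 0) == 0
        share = counts["upper_secondary"] / 2_000
        assert abs(share - 0.7) <= 3 * np.sqrt(0.21 / 2_000)

    def test_downward_transition_rejected(self):
        frame = bulk_frame(10, age_group="20-24", education="upper_secondary")
        sched = flat_schedules(advance=[("20-24", "upper_secondary", "primary", 0.5)])
        with pytest.raises(ValueError, match="up the ladder"):
            d.step_education(frame, sched, seed=1)

    def test_outgoing_probability_above_one_rejected(self):
        frame = bulk_frame(10, age_group="20-24", education="primary")
        sched = flat_schedules(
            advance=[("20-24", "primary", "lower_secondary", 0.7),
                     ("20-24", "primary", "upper_secondary", 0.6)]
        )
        with pytest.raises(ValueError, match="sum"):
            d.step_education(frame, sched, seed=1)


class TestEmigration:
    def test_zero_rates_change_nothing(self):
        frame = bulk_frame(1_000)
        out, gone = d.step_emigration(frame, flat_schedules(emigration=0.0), seed=1)
        assert out.n_cases == 1_000 and gone == 0.0

    def test_rate_one_empties_the_cell(self):
        frame = bulk_frame(1_000)
        sched = flat_schedules()
        mask = (sched.emigration["age_group"] == "40-44") & (sched.emigration["sex"] == "male")
        sched.emigration.loc[mask, "rate"] = 1.0
        out, gone = d.step_emigration(frame, sched, seed=1)
        assert out.n_cases == 0 and gone == pytest.approx(1_000.0)

    def test_small_rate_binomial_envelope(self):
        frame = bulk_frame(50_000)
        out, _ = d.step_emigration(frame, flat_schedules(emigration=0.02), seed=1)
        removed = 50_000 - out.n_cases
        assert abs(removed - 1_000) <= 3 * np.sqrt(50_000 * 0.02 * 0.98)


class TestFertility:
    def test_zero_tfr_no_births(self):
        frame = bulk_frame(5_000, age_group="25-29", sex="female")
        out, tally = d.step_fertility(frame, flat_schedules(), cfg(tfr=0.0), seed=1)
        assert out.n_cases == 5_000 and tally["births_total"] == 0.0

    def test_newborn_inherits_mother_weight(self):
        frame = bulk_frame(200, age_group="25-29", sex="female", weight=7.25)
        out, tally = d.step_fertility(frame, flat_schedules(), cfg(tfr=1.7), seed=1)
        newborns = out.data[out.data["origin"] == "birth"]
        assert len(newborns) > 0
        assert np.allclose(newborns["weight"], 7.25)
        assert (newborns["age"] == 0).all()
        assert (newborns["activity"] == "not_applicable").all()

    def test_weighted_births_match_expectation_oracle(self):
        """Realized births vs the deterministic sum of 5*ASFR over women."""
        frames = []
        for i, band in enumerate(d.AGE_LABELS[3:10]):
            frames.append(bulk_frame(15_000, age_group=band, sex="female").data)
        frame = d.PopulationFrame(pd.concat(frames, ignore_index=True), 2015)
        sched = flat_schedules()
        shape = sched.fertility.set_index("age_group")["shape"]
        tfr = 1.7
        expected = sum(15_000 * 5 * tfr * shape[band] for band in d.AGE_LABELS[3:10])
        out, tally = d.step_fertility(frame, sched, cfg(tfr=tfr), seed=1)
        sd = np.sqrt(sum(15_000 * 5 * tfr * shape[band] for band in d.AGE_LABELS[3:10]))
        assert abs(tally["births_total"] - expected) <= 3 * sd

    def test_newborn_survival_thins_births(self):
        frame = bulk_frame(20_000, age_group="25-29", sex="female")
        out, tally = d.step_fertility(
            frame, flat_schedules(nb_survival=0.5), cfg(tfr=1.7), seed=1
        )
        assert tally["births"] < tally["births_total"]
        ratio = tally["births"] / tally["births_total"]
        assert abs(ratio - 0.5) < 0.05


class TestLaborForce:
    def test_certain_participation(self):
        frame = bulk_frame(1_000, age_group="40-44")
        params = d.LfpLogitParams(coef={"male": {"intercept": 40.0}, "female": {}})
        out = d.step_labor_force(frame, params, seed=1)
        assert (out.data["activity"] == "active").all()

    def test_binomial_envelope_at_30k(self):
        p = 0.6
        b0 = float(np.log(p / (1 - p)))
        frame = bulk_frame(30_000, age_group="40-44")
        params = d.LfpLogitParams(coef={"male": {"intercept": b0}, "female": {}})
        out = d.step_labor_force(frame, params, seed=1)
        active = int((out.data["activity"] == "active").sum())
        assert abs(active - 18_000) <= 3 * np.sqrt(30_000 * p * (1 - p))

    def test_children_remain_not_applicable_and_old_inactive(self):
        df = pd.concat(
            [
                bulk_frame(100, age_group="5-9", education="none").data,
                bulk_frame(100, age_group="80-84").data,
            ],
            ignore_index=True,
        )
        frame = d.PopulationFrame(df, 2015)
        params = d.LfpLogitParams(coef={"male": {"intercept": 40.0}, "female": {}})
        out = d.step_labor_force(frame, params, seed=1)
        assert (out.data.loc[out.data["age"] == 1, "activity"] == "not_applicable").all()
        assert (out.data.loc[out.data["age"] == 16, "activity"] == "inactive").all()

    def test_composition_shift_raises_aggregate_participation(self, fitted_lfp):
        """With constant parameters, aggregate participation moves only
        through composition: shifting mass toward high-participation strata
        raises the aggregate rate."""
        low = bulk_frame(20_000, age_group="40-44", sex="male", education="no_education")
        high = bulk_frame(20_000, age_group="40-44", sex="male", education="postsecondary")

        def agg_rate(frame):
            out = d.step_labor_force(frame, fitted_lfp, seed=5)
            return (out.data["activity"] == "active").mean()

        assert agg_rate(high) > agg_rate(low)


class TestRunProjection:
    def test_horizon_equal_start_gives_assigned_base(self, estimates, schedules, fitted_lfp):
        c = cfg(tfr=0.8, start=2015, horizon=2015, sampling_fraction=0.02)
        base = d.build_base_population(estimates, c)
        traj = d.run_projection(base, schedules, fitted_lfp, c)
        assert len(traj) == 1
        frame = traj[0][0]
        adults = frame.data["age"] > 2
        assert set(frame.data.loc[adults, "activity"].unique()) <= {"active", "inactive"}

    def test_frozen_world_conserves_population(self, fitted_lfp):
        base = bulk_frame(5_000, age_group="40-44", weight=3.0)
        # a zero-probability transition row keeps the schedule formally complete
        sched = flat_schedules(advance=[("20-24", "primary", "lower_secondary", 0.0)])
        c = cfg(tfr=0.0, start=2015, horizon=2020)
        traj = d.run_projection(base, sched, fitted_lfp, c)
        assert len(traj) == 2
        final = traj[-1][0]
        assert final.weighted_total == pytest.approx(15_000.0)
        assert (final.data["age"] == 9).all()  # aged one band

    def test_accounting_identity_every_period(self, estimates, schedules, fitted_lfp):
        c = cfg(tfr=1.7, start=2015, horizon=2035, sampling_fraction=0.05)
        base = d.build_base_population(estimates, c)
        traj = d.run_projection(base, schedules, fitted_lfp, c)
        for (prev, _), (cur, tally) in zip(traj, traj[1:]):
            lhs = cur.weighted_total
            rhs = (
                prev.weighted_total - tally.deaths - tally.emigrants
                + tally.immigrants + tally.births
            )
            assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-6)

    def test_coverage_gap_reported_before_simulation(self, estimates, fitted_lfp, schedules):
        c = cfg(tfr=1.7, start=2015, horizon=2090, sampling_fraction=0.02)
        base = d.build_base_population(estimates, c)
        with pytest.raises(ValueError, match="coverage"):
            d.run_projection(base, schedules, fitted_lfp, c)

    def test_same_seed_reproduces_run(self, estimates, schedules, fitted_lfp):
        c = cfg(tfr=0.8, start=2015, horizon=2030, sampling_fraction=0.02, seed=9)
        base = d.build_base_population(estimates, c)
        t1 = d.run_projection(base, schedules, fitted_lfp, c)
        t2 = d.run_projection(base, schedules, fitted_lfp, c)
        for (f1, _), (f2, _) in zip(t1, t2):
            pd.testing.assert_frame_equal(f1.data, f2.data)

    def test_common_random_numbers_align_preexisting_cohorts(
        self, estimates, schedules, fitted_lfp
    ):
        """Scenarios sharing a seed keep everyone born before the start
        identical; only fertility-born cohorts differ."""
        c = cfg(tfr=0.8, start=2015, horizon=2030, sampling_fraction=0.04, seed=2)
        base = d.build_base_population(estimates, c)
        low = d.run_projection(base, schedules, fitted_lfp, c)[-1][0]
        high = d.run_projection(base, schedules, fitted_lfp, c.with_tfr(1.7))[-1][0]

        def adults(frame):  # 15+ in 2030 were alive in 2015
            df = frame.data
            return (
                df[df["age"] >= 3]
                .groupby(["age", "sex", "education", "activity"], observed=True)["weight"]
                .sum()
            )

        pd.testing.assert_series_equal(adults(low), adults(high))
        assert low.weighted_total < high.weighted_total

    def test_single_run_dispersion_is_small(self, estimates, schedules, fitted_lfp):
        """Between-seed noise of the aggregate indicators stays well below a
        percent at moderate case counts, so one run is representative."""
        finals = []
        for seed in range(4):
            c = cfg(tfr=1.7, start=2015, horizon=2045, sampling_fraction=0.05, seed=seed)
            base = d.build_base_population(estimates, c)
            traj = d.run_projection(base, schedules, fitted_lfp, c)
            finals.append(d.lfdr(traj[-1][0]))
        finals = np.array(finals)
        assert finals.std() / finals.mean() < 0.02


class TestAgeIncrement:
    def test_top_band_absorbs(self):
        frame = bulk_frame(10, age_group="100+")
        assert (age_increment(frame).data["age"] == 20).all()
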