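"""Generator contracts: life tables, cohorts with ground truth, census."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from lifehorizon import (ExcessHazard, SyntheticScenario, build_cohort,
                         generate_census, generate_cohort, generate_life_table,
                         null_scenario)
from lifehorizon.lifetable import LifeTable

from conftest import WASHOUT, WINDOW


class TestLifeTable:
    def test_constant_shape_fills_every_cell(self):
        lt = generate_life_table(2002, 2004, max_age=90,
                                 hazard_shape={"kind": "constant", "q": 0.5})
        for sex in ("M", "F"):
            assert np.all(lt.q[sex][:, :-1] == 0.5)
            assert np.all(lt.q[sex][:, -1] == 1.0)

    def test_gompertz_q_strictly_increasing_in_age(self, life_table):
        for sex in ("M", "F"):
            assert np.all(np.diff(life_table.q[sex], axis=1) > 0)

    def test_same_parameters_give_byte_identical_tables(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_life_table(2002, 2015).write_csv(a)
        generate_life_table(2002, 2015).write_csv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_csv_round_trip(self, life_table, tmp_path):
        p = tmp_path / "lt.csv"
        life_table.write_csv(p)
        back = LifeTable.read_csv(p)
        for sex in ("M", "F"):
            np.testing.assert_allclose(back.q[sex], life_table.q[sex])

    def test_carry_forward_reuses_last_year(self):
        lt = generate_life_table(2002, 2005,
                                 hazard_shape={"kind": "gompertz",
                                               "annual_improvement": 0.0})
        a = lt.monthly_death_prob_path("F", 60, 2004, 240)
        b = lt.monthly_death_prob_path("F", 60, 2030, 240)
        np.testing.assert_allclose(a, b)

    @pytest.mark.parametrize("shape", [
        {"kind": "constant", "q": 1.5},
        {"kind": "gompertz", "a": -1.0},
        {"kind": "gompertz", "b": 0.0},
        {"kind": "gompertz", "annual_improvement": 1.5},
        {"kind": "weird"},
    ])
    def test_invalid_hazard_shapes_rejected(self, shape):
        with pytest.raises(ValueError):
            generate_life_table(2002, 2015, hazard_shape=shape)

    def test_table_must_cover_old_age(self):
        with pytest.raises(ValueError):
            generate_life_table(2002, 2015, max_age=80)


class TestScenarioValidation:
    def test_subtype_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticScenario(subtype_weights={"SAH": 0.5, "ICH": 0.2,
                                               "NIH": 0.1, "CI": 0.1})

    @pytest.mark.parametrize("field,value", [
        ("sex_ratio", 1.2), ("washout_noise_rate", -0.1),
        ("nonhosp_rate", 2.0), ("no_imaging_rate", -1.0),
    ])
    def test_proportions_bounded(self, field, value):
        with pytest.raises(ValueError):
            SyntheticScenario(**{field: value})

    def test_additive_excess_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ExcessHazard(mode="additive", values=(-0.01,))

    def test_age_distribution_must_be_adult(self):
        with pytest.raises(ValueError):
            SyntheticScenario(age_distribution={10: 1.0})


class TestCohortGeneration:
    def test_identical_seed_gives_identical_claims(self, life_table):
        sc = null_scenario(seed=42, n_patients=200)
        a, _ = generate_cohort(sc, life_table)
        b, _ = generate_cohort(sc, life_table)
        pd.testing.assert_frame_equal(a, b)

    def test_index_events_conserved(self, life_table):
        sc = SyntheticScenario(seed=3, n_patients=150, washout_noise_rate=0.3,
                               nonhosp_rate=0.3, no_imaging_rate=0.3)
        claims, truth = generate_cohort(sc, life_table)
        assert len(truth.patients) == 150
        index_lines = claims[(claims["primary_dx"].str.match("I6[0-3]$"))
                             & (claims["date"] >= "2006-01-01")]
        assert index_lines["patient_id"].nunique() == 150

    def test_full_washout_noise_empties_the_cohort(self, life_table):
        sc = SyntheticScenario(seed=5, n_patients=60, washout_noise_rate=1.0)
        claims, _ = generate_cohort(sc, life_table)
        patients, ledger = build_cohort(claims, WINDOW, WASHOUT)
        assert len(patients) == 0
        assert ledger["washout_stroke_record"] == 60

    def test_null_scenario_truth_has_zero_eyll(self, life_table):
        _, truth = generate_cohort(null_scenario(seed=1, n_patients=100), life_table)
        assert truth.eyll == 0.0
        np.testing.assert_array_equal(truth.survival.surv, truth.reference.surv)

    def test_true_le_integrates_true_curve(self, life_table):
        _, truth = generate_cohort(null_scenario(seed=2, n_patients=100), life_table)
        assert abs(truth.le - truth.survival.restricted_mean(
            truth.survival.horizon)) < 1e-6

    def test_empirical_deaths_converge_to_true_curve(self, life_table):
        """KS distance between sampled death months and the analytic lifetime
        distribution shrinks as the cohort grows."""
        dists = []
        for n in (100, 1_000, 10_000):
            sc = null_scenario(seed=7, n_patients=n)
            _, truth = generate_cohort(sc, life_table)
            s = truth.survival
            cdf = lambda t, s=s: 1.0 - np.interp(t, s.months, s.surv)
            dists.append(kstest(truth.patients["true_death_month"], cdf).statistic)
        assert dists[0] > dists[2]
        assert dists[1] > dists[2]

    def test_stronger_excess_hazard_shortens_true_le(self, life_table):
        les = []
        for mult in (1.0, 2.0, 4.0):
            sc = SyntheticScenario(seed=9, n_patients=50,
                                   excess_hazard=ExcessHazard.constant(mult))
            _, truth = generate_cohort(sc, life_table)
            les.append(truth.le)
        assert les[0] > les[1] > les[2]


class TestCensus:
    def test_first_band_width_is_seven(self, life_table):
        census = generate_census(life_table, 1000, [(2006, 2007)])
        first = census[(census["age_group"] == "18-24") & (census["sex"] == "M")]
        assert float(first["population"].iloc[0]) == 7000.0

    def test_constant_population_identical_across_periods(self, life_table):
        census = generate_census(life_table, 1000, [(2006, 2007), (2008, 2009)])
        by_period = census.groupby("period")["population"].sum()
        assert by_period.nunique() == 1

    def test_shrinking_population_strictly_decreases(self, life_table):
        census = generate_census(life_table, 1000,
                                 [(2006, 2007), (2008, 2009), (2010, 2011)],
                                 annual_growth=-0.02)
        totals = census.groupby("period")["population"].sum().sort_index()
        assert np.all(np.diff(totals.to_numpy()) < 0)

    def test_empty_periods_rejected(self, life_table):
        with pytest.raises(ValueError):
            generate_census(life_table, 1000, [])
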