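"""Inclusion/exclusion cascade, comorbidity flags, SSI scoring, cost binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifehorizon import (CohortConfig, SSIConfig, build_cohort, compute_ssi,
                         flag_comorbidities, flag_outpatient_comparators,
                         generate_cohort, monthly_costs, null_scenario)
from lifehorizon.cohort import EXCLUSION_ORDER

from conftest import WASHOUT, WINDOW, claim_line


class TestCascade:
    def test_toy_cascade_each_rule_removes_one(self, toy_claims):
        patients, ledger = build_cohort(toy_claims, WINDOW, WASHOUT)
        assert ledger["input_patients"] == 6
        assert [ledger[k] for k in EXCLUSION_ORDER] == [1, 1, 1, 1, 1]
        assert ledger["retained"] == 1
        assert patients["patient_id"].tolist() == ["F"]
        assert patients["subtype"].tolist() == ["NIH"]

    def test_ledger_conserves_patient_count(self, life_table):
        from lifehorizon import SyntheticScenario
        sc = SyntheticScenario(seed=11, n_patients=300, washout_noise_rate=0.2,
                               nonhosp_rate=0.2, no_imaging_rate=0.2)
        claims, _ = generate_cohort(sc, life_table)
        _, ledger = build_cohort(claims, WINDOW, WASHOUT)
        assert (ledger["retained"] + sum(ledger[k] for k in EXCLUSION_ORDER)
                == ledger["input_patients"])

    def test_empty_claims_give_empty_cohort(self, toy_claims):
        patients, ledger = build_cohort(toy_claims.iloc[:0], WINDOW, WASHOUT)
        assert len(patients) == 0
        assert all(ledger[k] == 0 for k in EXCLUSION_ORDER)

    def test_clean_synthetic_cohort_fully_retained(self, life_table):
        sc = null_scenario(seed=4, n_patients=120)
        claims, _ = generate_cohort(sc, life_table)
        patients, ledger = build_cohort(claims, WINDOW, WASHOUT)
        assert ledger["retained"] == 120 == len(patients)

    def test_rebuilding_from_retained_claims_is_idempotent(self, life_table):
        sc = null_scenario(seed=6, n_patients=100)
        claims, _ = generate_cohort(sc, life_table)
        first, _ = build_cohort(claims, WINDOW, WASHOUT)
        again, ledger = build_cohort(
            claims[claims["patient_id"].isin(first["patient_id"])],
            WINDOW, WASHOUT)
        pd.testing.assert_frame_equal(first.reset_index(drop=True),
                                      again.reset_index(drop=True))

    def test_subtypes_partition_the_cohort(self, life_table):
        sc = null_scenario(seed=8, n_patients=200)
        claims, _ = generate_cohort(sc, life_table)
        patients, _ = build_cohort(claims, WINDOW, WASHOUT)
        assert patients["subtype"].isin(["SAH", "ICH", "NIH", "CI"]).all()
        assert patients["subtype"].notna().all()
        assert patients.groupby("subtype", observed=True).size().sum() == len(patients)

    def test_malformed_codes_skipped_and_counted(self, toy_claims):
        bad = pd.DataFrame([claim_line("Z", "2007-01-01", dx="???")])
        _, ledger = build_cohort(pd.concat([toy_claims, bad]), WINDOW, WASHOUT)
        assert ledger["skipped_malformed_lines"] == 1
        assert ledger["input_patients"] == 6

    def test_washout_must_precede_window(self, toy_claims):
        with pytest.raises(ValueError, match="precede"):
            build_cohort(toy_claims, WINDOW, ("2002-01-01", "2007-12-31"))


class TestOutpatientComparators:
    def _claims(self, visits, pid="X"):
        return pd.DataFrame([
            claim_line(pid, d, setting="outpatient", dx="I63", procs="")
            for d in visits])

    def test_three_distinct_dates_qualify(self):
        c = self._claims(["2007-01-01", "2007-02-01", "2007-03-01"])
        assert flag_outpatient_comparators(c, {"X"}) == {"X"}

    def test_two_visits_do_not_qualify(self):
        c = self._claims(["2007-01-01", "2007-02-01"])
        assert flag_outpatient_comparators(c, {"X"}) == set()

    def test_same_day_lines_count_as_one_visit(self):
        c = self._claims(["2007-01-01", "2007-01-01", "2007-01-01"])
        assert flag_outpatient_comparators(c, {"X"}) == set()


class TestComorbidities:
    def _cohort(self):
        return pd.DataFrame({
            "patient_id": ["A", "B", "C"],
            "index_date": pd.to_datetime(["2007-06-01"] * 3),
        })

    def test_record_day_before_index_flags_true(self):
        claims = pd.DataFrame([claim_line("A", "2007-05-31", dx="I10", procs="")])
        out = flag_comorbidities(claims, self._cohort(), "2002-01-01")
        assert bool(out.loc[out["patient_id"] == "A", "hypertension"].iloc[0])

    def test_record_on_index_date_flags_false(self):
        claims = pd.DataFrame([claim_line("A", "2007-06-01", dx="I10", procs="")])
        out = flag_comorbidities(claims, self._cohort(), "2002-01-01")
        assert not out["hypertension"].any()

    def test_disjoint_conditions_each_one_third(self):
        claims = pd.DataFrame([
            claim_line("A", "2006-01-01", dx="I10", procs=""),
            claim_line("B", "2006-01-01", dx="E11", procs=""),
            claim_line("C", "2006-01-01", dx="I48", procs=""),
        ])
        out = flag_comorbidities(claims, self._cohort(), "2002-01-01")
        for cond in ("hypertension", "diabetes", "AF"):
            assert out[cond].mean() == pytest.approx(1 / 3)

    def test_missing_condition_in_code_map_rejected(self):
        cfg = CohortConfig(comorbidity_codes={"AF": ("I48",)})
        with pytest.raises(ValueError, match="missing conditions"):
            flag_comorbidities(pd.DataFrame([claim_line("A", "2006-01-01")]),
                               self._cohort(), "2002-01-01", cfg)


class TestSSI:
    def test_all_zero_indicators_give_clipped_intercept(self):
        ind = pd.DataFrame({"patient_id": ["A"], "ICU": [False]})
        cfg = SSIConfig(intercept=2.0)     # below the floor of 4.1
        assert compute_ssi(ind, cfg).iloc[0] == 4.1

    def test_single_term_sum(self):
        ind = pd.DataFrame({"patient_id": ["A"], "ICU": [True]})
        cfg = SSIConfig(intercept=4.1, coefficients={"ICU": 2.0})
        assert compute_ssi(ind, cfg).iloc[0] == pytest.approx(6.1)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=5, max_size=5),
           st.lists(st.floats(0, 4), min_size=5, max_size=5))
    def test_matches_brute_force_dot_product(self, flags, coefs):
        names = [f"x{i}" for i in range(5)]
        cfg = SSIConfig(intercept=4.1, coefficients=dict(zip(names, coefs)),
                        score_min=0.0, score_max=1e9)
        ind = pd.DataFrame([dict(zip(names, flags), patient_id="A")])
        expected = 4.1 + sum(c * f for c, f in zip(coefs, flags))
        assert compute_ssi(ind, cfg).iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_unknown_indicator_ignored(self):
        ind = pd.DataFrame({"patient_id": ["A"], "ICU": [True], "XX": [True]})
        cfg = SSIConfig(coefficients={"ICU": 1.0}, score_min=0, score_max=99)
        assert compute_ssi(ind, cfg).iloc[0] == pytest.approx(5.1)


class TestMonthlyCosts:
    def test_lines_binned_by_month_since_index(self):
        patients = pd.DataFrame({"patient_id": ["A"],
                                 "index_date": pd.to_datetime(["2007-01-01"])})
        claims = pd.DataFrame([
            claim_line("A", "2007-01-05", insurer=100.0, copay=10.0, procs=""),
            claim_line("A", "2007-02-03", insurer=50.0, copay=5.0, procs=""),
            claim_line("A", "2006-12-20", insurer=999.0, copay=99.0, procs=""),
        ])
        out = monthly_costs(claims, patients)
        assert out["month"].tolist() == [0, 1]
        assert out["insurer"].tolist() == [100.0, 50.0]
        assert out["copay"].tolist() == [10.0, 5.0]

    def test_negative_costs_rejected(self):
        patients = pd.DataFrame({"patient_id": ["A"],
                                 "index_date": pd.to_datetime(["2007-01-01"])})
        claims = pd.DataFrame([claim_line("A", "2007-01-05", insurer=-1.0)])
        with pytest.raises(ValueError, match="negative"):
            monthly_costs(claims, patients)
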