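"""Cost profiles, rolling-over cost extrapolation, discounted lifetime costs."""

import numpy as np
import pandas as pd
import pytest

from lifehorizon import (CostProfile, DiscountSpec, SurvivalCurve,
                         convert_currency, extrapolate_costs, lifetime_cost,
                         monthly_mean_costs)


def profile(total, copay_share=0.0, n=None):
    total = np.asarray(total, dtype=float)
    return CostProfile(
        months=np.arange(total.size),
        mean_cost={"insurer": total * (1 - copay_share),
                   "copay": total * copay_share},
        n_contributing=np.full(total.size, n or 10))


def rectangle_curve(alive_months, horizon):
    surv = np.zeros(horizon + 1)
    surv[:alive_months] = 1.0
    return SurvivalCurve(months=np.arange(horizon + 1), surv=surv,
                         provenance="extrapolated")


class TestMonthlyMeans:
    def _patients(self, fups):
        return pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(fups))],
                             "followup_months": fups})

    def test_mean_over_patients_under_observation(self):
        long = pd.DataFrame({"patient_id": ["P0", "P1"], "month": [0, 0],
                             "insurer": [100.0, 300.0], "copay": [0.0, 0.0]})
        prof = monthly_mean_costs(self._patients([1, 1]), long)
        assert prof.mean_cost["insurer"][0] == pytest.approx(200.0)

    def test_censored_patient_leaves_later_months(self):
        long = pd.DataFrame({"patient_id": ["P0", "P0", "P1"],
                             "month": [0, 5, 0],
                             "insurer": [100.0, 999.0, 40.0],
                             "copay": [0.0, 0.0, 0.0]})
        prof = monthly_mean_costs(self._patients([5, 10]), long)
        # P0 (censored at 5) cannot contribute at month 5
        assert prof.n_contributing[5] == 1
        assert prof.mean_cost["insurer"][5] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_average(self, seed):
        rng = np.random.default_rng(seed)
        n, horizon = 12, 18
        fups = rng.integers(1, horizon + 1, size=n)
        rows = []
        for i in range(n):
            for m in range(fups[i]):
                if rng.random() < 0.7:
                    rows.append({"patient_id": f"P{i}", "month": m,
                                 "insurer": rng.uniform(0, 500),
                                 "copay": rng.uniform(0, 100)})
        long = pd.DataFrame(rows)
        prof = monthly_mean_costs(self._patients(fups), long)
        for m in prof.months:
            under = [i for i in range(n) if fups[i] > m]
            for stream in ("insurer", "copay"):
                paid = long[(long["month"] == m)
                            & long["patient_id"].isin([f"P{i}" for i in under])]
                expected = paid[stream].sum() / len(under)
                assert prof.mean_cost[stream][m] == pytest.approx(expected, abs=1e-9)


class TestCostExtrapolation:
    def test_constant_costs_continue_flat(self):
        prof = extrapolate_costs(profile(np.full(60, 250.0)),
                                 rectangle_curve(100, 120))
        np.testing.assert_allclose(prof.mean_cost["insurer"][60:], 250.0, rtol=1e-9)
        assert set(prof.provenance[60:]) == {"extrapolated"}

    def test_exponential_rise_continues_log_linear_trend(self):
        m = np.arange(60)
        total = np.expm1(2.0 + 0.01 * m)
        prof = extrapolate_costs(profile(total), rectangle_curve(100, 120))
        expected = np.expm1(2.0 + 0.01 * np.arange(61, 121))
        np.testing.assert_allclose(prof.mean_cost["insurer"][61:], expected, rtol=1e-6)

    def test_zero_costs_stay_zero(self):
        prof = extrapolate_costs(profile(np.zeros(60)), rectangle_curve(100, 120))
        np.testing.assert_array_equal(prof.mean_cost["insurer"], 0.0)

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_costs(profile(np.ones(60)), rectangle_curve(100, 120),
                              window=1)


class TestLifetimeCost:
    def test_rectangular_undiscounted_sum(self):
        lc = lifetime_cost(profile(np.full(121, 100.0)), rectangle_curve(12, 120),
                           DiscountSpec(0.0))
        assert lc["total"] == pytest.approx(1200.0)

    def test_discounted_sum_matches_scalar_loop(self):
        lc = lifetime_cost(profile(np.full(121, 100.0)), rectangle_curve(12, 120),
                           DiscountSpec(0.05))
        expected = sum(100.0 * 1.05 ** (-m / 12) for m in range(12))
        assert lc["total"] == pytest.approx(expected, abs=1e-9)

    def test_discounting_is_monotone_in_rate(self):
        rng = np.random.default_rng(5)
        total = rng.uniform(0, 400, size=121)
        surv = np.minimum.accumulate(rng.uniform(0.3, 1.0, size=121))
        surv[0] = 1.0
        lifetime = SurvivalCurve(months=np.arange(121), surv=surv,
                                 provenance="extrapolated")
        values = [lifetime_cost(profile(total), lifetime, DiscountSpec(r))["total"]
                  for r in (0.0, 0.03, 0.05)]
        assert values[0] >= values[1] >= values[2]

    def test_streams_add_exactly(self):
        prof = profile(np.full(121, 90.0), copay_share=0.18)
        lc = lifetime_cost(prof, rectangle_curve(40, 120), DiscountSpec(0.03))
        assert lc["total"] == lc["insurer"] + lc["copay"]
        assert lc["copay_share"] == pytest.approx(0.18)

    def test_bounded_by_max_cost_times_survival_mass(self):
        rng = np.random.default_rng(6)
        total = rng.uniform(0, 400, size=121)
        lifetime = rectangle_curve(80, 120)
        lc = lifetime_cost(profile(total), lifetime, DiscountSpec(0.0))
        assert lc["total"] <= total.max() * lifetime.surv.sum() + 1e-9

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="extrapolate"):
            lifetime_cost(profile(np.ones(60)), rectangle_curve(80, 120))

    def test_negative_discount_rate_rejected(self):
        with pytest.raises(ValueError):
            DiscountSpec(-0.01)


class TestCurrency:
    def test_exchange_rate_identity(self):
        assert convert_currency(1131.2) == pytest.approx(1.0)

    def test_zero_maps_to_zero(self):
        assert convert_currency(0.0) == 0.0

    def test_scalar_division(self):
        assert convert_currency(2_262_400.0) == pytest.approx(2000.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(1.0, 0.0)
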