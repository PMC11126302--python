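"""Log-linear regression, window selection and the derived rate estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import closed_form_ols

from asvgrowth.growth import (
    ACCEPTED,
    INSUFFICIENT,
    NONPOSITIVE,
    NONSIGNIFICANT,
    RegressionFit,
    accepted_frame,
    bulk_rate,
    estimate_asv_rates,
    estimate_motu_rates,
    fit_log_linear,
    motu_rate,
    records_to_frame,
    select_window,
)
from asvgrowth.pseudoabundance import pseudoabundance_table


def _fit(slope, p, n=9):
    return RegressionFit(slope=slope, intercept=0.0, p_value=p, r_squared=0.9, n_points=n)


class TestFitLogLinear:
    def test_exact_exponential(self):
        fit = fit_log_linear([0, 1, 2], np.exp([0.0, 2.0, 4.0]))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_series_has_zero_slope(self):
        fit = fit_log_linear([0, 1, 2], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert not (fit.p_value < 0.05)  # NaN p never counts as significant

    def test_insufficient_points(self):
        assert fit_log_linear([0, 1], [1.0, 2.0]) is None
        assert fit_log_linear([1, 1, 1], [1.0, 2.0, 3.0]) is None

    def test_zero_pseudoabundance_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            fit_log_linear([0, 1, 2], [1.0, 0.0, 2.0])

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            x = rng.uniform(0, 3, size=n)
            while np.unique(x).size < 2:
                x = rng.uniform(0, 3, size=n)
            y = np.exp(rng.normal(0, 1, size=n))
            fit = fit_log_linear(x, y)
            slope, intercept, p = closed_form_ols(x, np.log(y))
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-8)


class TestSelectWindow:
    def test_highest_significant_slope_wins(self):
        status, window, fit = select_window(_fit(3.0, 0.01), _fit(2.0, 0.001))
        assert (status, window, fit.slope) == (ACCEPTED, "t0t2t3", 3.0)

    def test_nonsignificant_pair_discarded(self):
        status, _, _ = select_window(_fit(1.0, 0.2), _fit(0.8, 0.2))
        assert status == NONSIGNIFICANT

    def test_single_candidate(self):
        status, window, fit = select_window(None, _fit(2.5, 0.01))
        assert (status, window, fit.slope) == (ACCEPTED, "t0t2t3t4", 2.5)

    def test_significant_negative_slope(self):
        status, _, _ = select_window(_fit(-1.0, 0.001), _fit(-0.5, 0.3))
        assert status == NONPOSITIVE

    def test_both_absent(self):
        assert select_window(None, None)[0] == INSUFFICIENT

    def test_slope_tie_broken_by_p(self):
        status, window, _ = select_window(_fit(2.0, 0.001), _fit(2.0, 0.01))
        assert (status, window) == (ACCEPTED, "t0t2t3")
        status, window, _ = select_window(_fit(2.0, 0.01), _fit(2.0, 0.01))
        assert (status, window) == (ACCEPTED, "t0t2t3t4")  # full tie -> longer window


class TestEstimateAsvRates:
    def test_noise_free_recovery(self, exact_sim):
        """Every grower's rate is recovered near machine precision."""
        ptab = pseudoabundance_table(exact_sim.experiment)
        df = accepted_frame(estimate_asv_rates(ptab))
        truth = exact_sim.truth.mu_frame()
        merged = df.merge(truth, on=["asv_id", "season", "treatment"])
        growers = exact_sim.truth.asv_type == "grower"
        assert len(merged) == int(growers.sum())
        np.testing.assert_allclose(
            merged["slope_per_day"], merged["mu_true"], atol=1e-9
        )

    def test_absent_asv_is_insufficient(self, exact_sim):
        exp = exact_sim.experiment
        counts = exp.counts.copy()
        counts.loc["ASV_0001"] = 0.0
        exp2 = type(exp)(
            counts=counts, samples=exp.samples, totals=exp.totals, taxonomy=exp.taxonomy
        ).validate()
        recs = records_to_frame(estimate_asv_rates(pseudoabundance_table(exp2)))
        row = recs[recs["asv_id"] == "ASV_0001"].iloc[0]
        assert row["status"] == INSUFFICIENT

    def test_one_record_per_asv_and_condition(self, noisy_sim):
        recs = records_to_frame(
            estimate_asv_rates(pseudoabundance_table(noisy_sim.experiment))
        )
        n_cond = noisy_sim.experiment.samples[["season", "treatment"]].drop_duplicates()
        assert len(recs) == len(noisy_sim.experiment.asv_ids) * len(n_cond)
        assert not recs.duplicated(["asv_id", "season", "treatment"]).any()


class TestBulkRate:
    def test_doubling_totals(self, toy_experiment):
        totals = pd.Series(
            1.0e6 * 2.0 ** np.array([0, 1, 2, 3]), index=toy_experiment.sample_ids
        )
        rec = bulk_rate(totals, toy_experiment.samples, "winter", "CL")
        assert rec.status == ACCEPTED
        assert rec.slope_per_day == pytest.approx(math.log(2), abs=1e-9)
        assert rec.asv_id == "__bulk__"

    def test_constant_totals_discarded(self, toy_experiment):
        totals = pd.Series(1.0e6, index=toy_experiment.sample_ids)
        rec = bulk_rate(totals, toy_experiment.samples, "winter", "CL")
        assert rec.status != ACCEPTED

    def test_bulk_not_above_max_asv_rate(self, exact_sim):
        """Totals aggregate all taxa, so bulk growth <= fastest member."""
        exp = exact_sim.experiment
        df = accepted_frame(estimate_asv_rates(pseudoabundance_table(exp)))
        rec = bulk_rate(exp.totals, exp.samples, "winter", "CL")
        assert rec.slope_per_day <= df["slope_per_day"].max() + 1e-9


class TestMotuRate:
    @pytest.mark.parametrize(
        "fold,hours,expected",
        [
            (1.0, 96.0, 0.0),
            (math.e, 24.0, 1.0),
            (8.0, 48.0, math.log(8) / 48 * 24),
        ],
    )
    def test_closed_form(self, fold, hours, expected):
        rate = motu_rate([10.0], [10.0 * fold], 1.0e6, 1.0e6, hours)
        assert rate == pytest.approx(expected, abs=1e-12)

    def test_zero_endpoint_is_nan(self):
        assert math.isnan(motu_rate([0.0], [5.0], 1e6, 1e6, 72.0))

    def test_equals_two_point_regression(self):
        """Endpoint means duplicated as regression points give the same slope."""
        rel0, rel4 = [2.0, 3.0, 4.0], [9.0, 11.0, 10.0]
        t0tot, t4tot = 1.0e6, 3.0e6
        rate = motu_rate(rel0, rel4, t0tot, t4tot, 72.0)
        a0 = np.mean(rel0) * t0tot / 100
        a4 = np.mean(rel4) * t4tot / 100
        fit = fit_log_linear([0, 0, 3, 3], [a0, a0, a4, a4])
        assert rate == pytest.approx(fit.slope, abs=1e-10)

    def test_table_estimation(self, noisy_sim):
        exp = noisy_sim.experiment
        df = estimate_motu_rates(noisy_sim.motu, exp.samples, exp.totals)
        assert set(df.columns) == {"motu_id", "season", "treatment", "rate_per_day"}
        n_cond = exp.samples[["season", "treatment"]].drop_duplicates()
        assert len(df) == len(noisy_sim.motu) * len(n_cond)
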