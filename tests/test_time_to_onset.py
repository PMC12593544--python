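"""Onset intervals and Weibull hazard modeling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import weibull_min

from faersig.cohort import ReportCase, build_cohort
from faersig.faers_io import parse_faers_date
from faersig.synthetic import generate_frames
from faersig.time_to_onset import (
    WeibullFit,
    classify_failure,
    compute_onsets,
    fit_weibull,
    onset_summary,
)
from tests.conftest import small_config


def case(pid, event, seqs=("1",)):
    return ReportCase(
        primaryid=pid,
        caseid=pid,
        fda_dt=parse_faers_date("20240601"),
        event_dt=parse_faers_date(event),
        sex="male",
        age_years=None,
        weight_kg=None,
        country=None,
        reporter="missing",
        outcome="missing",
        report_year=2024,
        pts=frozenset({"Nausea"}),
        ps_drug_seqs=frozenset(seqs),
    )


def ther(rows):
    return pd.DataFrame(rows, columns=["primaryid", "dsg_drug_seq", "start_dt"]).astype(str)


class TestComputeOnsets:
    def test_calendar_arithmetic(self):
        recs, _ = compute_onsets([case("1", "20240119")], ther([["1", "1", "20240101"]]))
        assert recs[0].onset_days == 18

    def test_event_before_start_excluded(self):
        recs, tally = compute_onsets(
            [case("1", "20231231")], ther([["1", "1", "20240101"]])
        )
        assert recs == [] and tally["event_before_start"] == 1

    def test_same_day_excluded_separately(self):
        recs, tally = compute_onsets(
            [case("1", "20240101")], ther([["1", "1", "20240101"]])
        )
        assert recs == [] and tally["same_day"] == 1

    def test_earliest_start_among_therapy_rows(self):
        recs, _ = compute_onsets(
            [case("1", "20240119")],
            ther([["1", "1", "20240110"], ["1", "1", "20240101"]]),
        )
        assert recs[0].onset_days == 18

    def test_non_ps_drug_seq_ignored(self):
        recs, tally = compute_onsets(
            [case("1", "20240119", seqs=("2",))], ther([["1", "1", "20240101"]])
        )
        assert recs == [] and tally["no_therapy_start"] == 1

    def test_partial_dates_unusable(self):
        recs, tally = compute_onsets(
            [case("1", "202401")], ther([["1", "1", "20240101"]])
        )
        assert tally["event_missing_or_partial"] == 1
        recs, tally = compute_onsets([case("1", "20240119")], ther([["1", "1", "202401"]]))
        assert tally["no_therapy_start"] == 1

    def test_exclusion_accounting_balances(self, small_quarter):
        cfg, frames, truth = small_quarter
        b = build_cohort(frames, cfg.target_name.lower())
        recs, tally = compute_onsets(b.cases, frames["THER"])
        assert len(recs) + sum(tally.values()) == len(b.cases)

    def test_matches_generator_clean_onsets(self, small_quarter):
        cfg, frames, truth = small_quarter
        b = build_cohort(frames, cfg.target_name.lower())
        recs, _ = compute_onsets(b.cases, frames["THER"])
        got = {r.primaryid: r.onset_days for r in recs}
        for pid, days in truth.clean_onsets.items():
            assert got.get(pid) == days


class TestFitWeibull:
    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(42)
        t = 32.74 * rng.weibull(0.81, size=5000)
        fit = fit_weibull(t)
        assert fit.scale_alpha == pytest.approx(32.74, rel=0.05)
        assert fit.shape_beta == pytest.approx(0.81, rel=0.05)
        assert fit.scale_ci95[0] < fit.scale_alpha < fit.scale_ci95[1]
        assert fit.shape_ci95[0] < fit.shape_beta < fit.shape_ci95[1]

    def test_matches_scipy_mle(self):
        rng = np.random.default_rng(7)
        t = 20.0 * rng.weibull(1.3, size=800)
        fit = fit_weibull(t)
        shape, _, scale = weibull_min.fit(t, floc=0)
        assert fit.shape_beta == pytest.approx(shape, rel=1e-4)
        assert fit.scale_alpha == pytest.approx(scale, rel=1e-4)

    def test_mle_optimality(self):
        """Log-likelihood at the MLE beats +/-10% perturbations."""
        rng = np.random.default_rng(3)
        t = 30.0 * rng.weibull(0.9, size=500)
        fit = fit_weibull(t)

        def loglik(alpha, beta):
            return (
                len(t) * (math.log(beta) - beta * math.log(alpha))
                + (beta - 1) * np.log(t).sum()
                - ((t / alpha) ** beta).sum()
            )

        best = loglik(fit.scale_alpha, fit.shape_beta)
        for fa in (0.9, 1.1):
            for fb in (0.9, 1.1):
                assert best >= loglik(fit.scale_alpha * fa, fit.shape_beta * fb)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        t = 15.0 * rng.weibull(1.1, size=400)
        f1 = fit_weibull(t)
        f2 = fit_weibull(t * 7.0)
        assert f2.scale_alpha == pytest.approx(7.0 * f1.scale_alpha, rel=1e-6)
        assert f2.shape_beta == pytest.approx(f1.shape_beta, rel=1e-6)

    def test_shape_ci_coverage_exponential(self):
        """With exponential data (true shape 1) the shape CI covers 1 in
        roughly 95% of replicates."""
        rng = np.random.default_rng(11)
        cover = 0
        n_rep = 300
        for _ in range(n_rep):
            t = rng.exponential(25.0, size=150)
            fit = fit_weibull(t)
            cover += fit.shape_ci95[0] <= 1.0 <= fit.shape_ci95[1]
        assert 0.90 <= cover / n_rep <= 0.99

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull([1, 2, 3])

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull([5.0] * 50)

    def test_deterministic(self):
        t = np.array([1, 3, 7, 14, 20, 30, 45, 60, 90, 180], dtype=float)
        f1, f2 = fit_weibull(t), fit_weibull(t)
        assert f1 == f2


class TestClassifyFailure:
    @pytest.mark.parametrize(
        "ci,expected",
        [((0.75, 0.87), "early"), ((0.9, 1.1), "random"), ((1.2, 1.5), "wear_out")],
    )
    def test_shape_ci_classification(self, ci, expected):
        fit = WeibullFit(
            scale_alpha=30,
            shape_beta=sum(ci) / 2,
            scale_ci95=(25, 35),
            shape_ci95=ci,
            n=100,
            median_days=18,
            iqr=(7, 46),
            failure_type="",
        )
        assert classify_failure(fit) == expected


class TestOnsetSummary:
    def test_all_first_month(self):
        s = onset_summary(list(range(1, 31)))
        assert s.bins[0][2] == pytest.approx(100.0)
        assert all(b[1] == 0 for b in s.bins[1:])

    def test_median_of_odd_sample(self):
        s = onset_summary([1, 5, 9])
        assert s.median == 5

    def test_bin_proportions_sum_to_100(self, rng):
        t = rng.integers(1, 700, size=500)
        s = onset_summary(t)
        assert sum(b[2] for b in s.bins) == pytest.approx(100.0)
        assert sum(b[1] for b in s.bins) == 500

    def test_first_month_proportion_matches_weibull_cdf(self):
        """Seeded Weibull(32.74, 0.81) onsets: the first-month share is
        within 5 points of the closed-form CDF at 30 days."""
        rng = np.random.default_rng(17)
        t = np.ceil(32.74 * rng.weibull(0.81, size=393))
        s = onset_summary(t)
        expected = 100.0 * (1 - math.exp(-((30 / 32.74) ** 0.81)))
        assert abs(s.bins[0][2] - expected) <= 5.0

    def test_monotone_under_adding_to_one_bin(self):
        base = list(range(1, 100))
        s1 = onset_summary(base)
        s2 = onset_summary(base + [400])
        assert s2.bins[-1][1] == s1.bins[-1][1] + 1
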