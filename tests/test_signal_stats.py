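"""Disproportionality statistics against independent oracles.

The generic 2x2 odds-ratio machinery in statsmodels and the Pearson
chi-square in scipy serve as cross-checks; they are never the
implementation.
"""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from faersig.cohort import background_pairs, build_cohort, cohort_pairs
from faersig.signal_stats import (
    BcpnnPriors,
    ContingencyTable,
    SignalMetrics,
    bcpnn_ic,
    build_contingency,
    compute_metrics,
    ebgm_with_bound,
    evaluate_criteria,
    prr_with_chi2,
    ror_with_ci,
    screen,
)
from faersig.synthetic import generate_frames, synthetic_pt_soc_map
from tests.conftest import small_config

WORKED = ContingencyTable(a=10, b=90, c=100, d=9900)


class TestBuildContingency:
    def test_hand_recounted_pairs(self):
        # 7 unique (report, term) pairs; target drug reports R1-R3
        pairs = [
            ("R1", "P"), ("R1", "Q"), ("R2", "P"), ("R3", "Q"),
            ("R4", "P"), ("R5", "Q"), ("R6", "Q"),
        ]
        t = build_contingency(pairs, {"R1", "R2", "R3"}, "P")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 2)

    def test_term_only_in_target_reports(self):
        pairs = [("R1", "P"), ("R2", "Q")]
        t = build_contingency(pairs, {"R1"}, "P")
        assert t.c == 0

    def test_absent_term_gives_zero_margins(self):
        pairs = [("R1", "Q")]
        t = build_contingency(pairs, {"R1"}, "Zzz")
        assert t.a == 0 and t.c == 0

    def test_duplicate_pairs_counted_once(self):
        pairs = [("R1", "P"), ("R1", "P"), ("R2", "P")]
        t = build_contingency(pairs, {"R1"}, "P")
        assert (t.a, t.c) == (1, 1)


class TestFormulas:
    def test_independence_table(self):
        t = ContingencyTable(a=10, b=10, c=10, d=10)
        assert ror_with_ci(t)[0] == pytest.approx(1.0)
        prr, chi2 = prr_with_chi2(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert bcpnn_ic(t)[0] == pytest.approx(0.0)
        assert ebgm_with_bound(t)[0] == pytest.approx(1.0)

    def test_worked_table_point_estimates(self):
        assert ror_with_ci(WORKED)[0] == pytest.approx(11.0)
        assert prr_with_chi2(WORKED)[0] == pytest.approx(10.0)
        ic, _ = bcpnn_ic(WORKED)
        assert ic == pytest.approx(math.log2(101000 / 11000))
        assert ebgm_with_bound(WORKED)[0] == pytest.approx(9.1818181818, rel=1e-9)

    def test_ror_ci_matches_independent_log_or_se(self):
        """Wald CI recomputed from first principles: log OR +/- z*sqrt(sum 1/cell)."""
        t = WORKED
        lor = math.log(t.a) + math.log(t.d) - math.log(t.b) - math.log(t.c)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        ror, lo, hi = ror_with_ci(t)
        assert math.log(ror) == pytest.approx(lor, rel=1e-12)
        assert lo == pytest.approx(math.exp(lor - 1.959963984540054 * se), rel=1e-9)
        assert hi == pytest.approx(math.exp(lor + 1.959963984540054 * se), rel=1e-9)

    def test_ror_matches_statsmodels_table2x2(self):
        sm = pytest.importorskip("statsmodels.api")
        tab = sm.stats.Table2x2(
            np.array([[WORKED.a, WORKED.b], [WORKED.c, WORKED.d]])
        )
        ror, lo, hi = ror_with_ci(WORKED)
        assert ror == pytest.approx(tab.oddsratio)
        sm_lo, sm_hi = tab.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-6)
        assert hi == pytest.approx(sm_hi, rel=1e-6)

    def test_chi2_matches_pearson_no_correction(self):
        _, chi2 = prr_with_chi2(WORKED)
        ref = chi2_contingency(
            np.array([[WORKED.a, WORKED.b], [WORKED.c, WORKED.d]]), correction=False
        ).statistic
        assert chi2 == pytest.approx(ref, rel=1e-12)

    def test_ebgm_equals_two_to_the_ic(self, rng):
        """Both statistics share the observed/expected kernel."""
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable(a=int(a), b=int(b), c=int(c), d=int(d))
            assert ebgm_with_bound(t)[0] == pytest.approx(2 ** bcpnn_ic(t)[0], rel=1e-12)

    def test_zero_cells_not_computable_never_infinite(self):
        t = ContingencyTable(a=5, b=0, c=3, d=10)
        assert all(math.isnan(v) for v in ror_with_ci(t))
        assert math.isnan(ebgm_with_bound(t)[0])
        t0 = ContingencyTable(a=0, b=5, c=3, d=10)
        assert math.isnan(bcpnn_ic(t0)[0])

    def test_ic025_below_ic_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 1000, size=4)
            ic, ic025 = bcpnn_ic(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert ic025 < ic

    def test_sign_equivalence(self, rng):
        """ror>1 iff prr>1 iff ic>0 iff ebgm>1 (all reduce to ad>bc)."""
        for _ in range(10_000):
            a, b, c, d = (int(v) for v in rng.integers(1, 200, size=4))
            t = ContingencyTable(a, b, c, d)
            signs = {
                ror_with_ci(t)[0] > 1,
                prr_with_chi2(t)[0] > 1,
                bcpnn_ic(t)[0] > 0,
                ebgm_with_bound(t)[0] > 1,
                a * d > b * c,
            }
            if a * d != b * c:
                assert len(signs) == 1

    def test_monotonic_in_a(self):
        prev = None
        for a in range(1, 40):
            t = ContingencyTable(a, 50, 30, 5000)
            point = (
                ror_with_ci(t)[0],
                prr_with_chi2(t)[0],
                bcpnn_ic(t)[0],
                ebgm_with_bound(t)[0],
            )
            if prev is not None:
                assert all(x > y for x, y in zip(point, prev))
            prev = point

    def test_deterministic(self):
        m1 = compute_metrics(WORKED, term="x")
        m2 = compute_metrics(WORKED, term="x")
        assert m1 == m2

    def test_haldane_correction_only_on_zero_cells(self):
        m = compute_metrics(ContingencyTable(5, 0, 3, 100), haldane=True)
        assert not math.isnan(m.ror)
        # fully positive tables are untouched by the switch
        assert compute_metrics(WORKED, haldane=True) == compute_metrics(WORKED)

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha1=0.0)


class TestCriteria:
    @staticmethod
    def metrics(**kw):
        m = SignalMetrics(term="t", level="PT", a=kw.pop("a", 10))
        for k, v in kw.items():
            setattr(m, k, v)
        return evaluate_criteria(m)

    def test_ror_boundary_strict(self):
        assert not self.metrics(ror_lo95=1.0).flag_ror
        assert self.metrics(ror_lo95=1.0000001).flag_ror

    def test_ror_case_count_gate(self):
        assert not self.metrics(a=2, ror_lo95=50.0).flag_ror
        assert self.metrics(a=3, ror_lo95=1.5).flag_ror

    def test_prr_boundary_inclusive(self):
        assert self.metrics(a=3, prr=2.0, chi2=4.0).flag_prr
        assert not self.metrics(a=3, prr=1.999, chi2=4.0).flag_prr
        assert not self.metrics(a=3, prr=2.0, chi2=3.999).flag_prr
        assert not self.metrics(a=2, prr=2.0, chi2=4.0).flag_prr

    def test_bcpnn_boundary_strict(self):
        assert not self.metrics(ic025=0.0).flag_bcpnn
        assert self.metrics(ic025=1e-9).flag_bcpnn

    def test_mgps_boundary_strict(self):
        assert not self.metrics(ebgm05=2.0).flag_mgps
        assert self.metrics(ebgm05=2.0000001).flag_mgps

    def test_nan_never_significant(self):
        m = self.metrics()  # all stats NaN
        assert not (m.flag_ror or m.flag_prr or m.flag_bcpnn or m.flag_mgps)

    def test_all4_is_conjunction(self):
        m = self.metrics(a=5, ror_lo95=2, prr=3, chi2=10, ic025=0.5, ebgm05=2.5)
        assert m.significant_all4
        m2 = self.metrics(a=5, ror_lo95=2, prr=3, chi2=10, ic025=-0.1, ebgm05=2.5)
        assert not m2.significant_all4


@pytest.fixture(scope="module")
def screened():
    cfg = small_config(seed=21, n_reports=5000, target_share=0.02)
    frames, truth = generate_frames(cfg)
    b = build_cohort(frames, cfg.target_name.lower())
    cp = cohort_pairs(b.cases)
    bp = background_pairs(frames["REAC"], b.retained_ids, b.ps_ids)
    res = screen(cp, bp, pt_soc_map=synthetic_pt_soc_map(cfg), level="PT")
    return cfg, frames, b, cp, bp, res


class TestScreen:

    def test_planted_signal_in_intersection(self, screened):
        *_, res = screened
        assert "Dysphonia" in res.all4_terms

    def test_per_algorithm_counts_bound_intersection(self, screened):
        *_, res = screened
        for key in ("ror", "prr", "bcpnn", "mgps"):
            assert res.venn[key] >= res.venn["all4"]

    def test_conservation_of_pairs(self, screened):
        _, _, _, cp, _, res = screened
        assert sum(m.a for m in res.metrics) == len(cp)
        # a+b is the cohort pair total for every term
        for m in res.metrics[:10]:
            assert m.a <= len(cp)

    def test_sorted_by_cases_then_term(self, screened):
        *_, res = screened
        keys = [(-m.a, m.term) for m in res.metrics]
        assert keys == sorted(keys)

    def test_soc_level_screen_and_exclusion(self, screened):
        cfg, frames, b, cp, bp, _ = screened
        mapping = synthetic_pt_soc_map(cfg)
        res = screen(cp, bp, pt_soc_map=mapping, level="SOC")
        socs = {m.term for m in res.metrics}
        assert socs <= set(mapping.values()) | {"Unmapped"}
        excl = ("Respiratory, thoracic and mediastinal disorders",)
        res2 = screen(cp, bp, pt_soc_map=mapping, level="SOC", soc_exclusions=excl)
        assert excl[0] not in res2.all4_after_exclusion

    def test_pt_exclusion_via_soc_of_pt(self, screened):
        cfg, frames, b, cp, bp, res = screened
        mapping = synthetic_pt_soc_map(cfg)
        # Dysphonia maps to the respiratory SOC; excluding it removes the PT
        res2 = screen(
            cp,
            bp,
            pt_soc_map=mapping,
            level="PT",
            soc_exclusions=("Respiratory, thoracic and mediastinal disorders",),
        )
        assert "Dysphonia" in res2.all4_terms
        assert "Dysphonia" not in res2.all4_after_exclusion

    def test_unmapped_pt_reserved_soc(self, screened):
        cfg, frames, b, cp, bp, _ = screened
        res = screen(cp, bp, pt_soc_map={"Fatigue": "General disorders"}, level="SOC")
        assert "Unmapped" in {m.term for m in res.metrics}
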