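"""Cohort profiles and demographic subgroup screens.

The profile partitions the cohort by sex, age strata, weight strata,
outcome, country (top five), reporter type and reporting year, each as
(category, count, percent-of-cohort).  Percentages are computed against
the whole cohort, missing values included, and rounded half-up to one
decimal only at presentation.

Subgroup screens re-run the disproportionality analysis with both the
cohort and the comparator restricted to the same stratum (male cohort
against male background, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import pandas as pd

from .cohort import ReportCase, cohort_pairs
from .signal_stats import BcpnnPriors, DEFAULT_PRIORS, ScreenResult, screen

Partition = list[tuple[str, int, float]]

AGE_STRATA: tuple[tuple[str, float, float], ...] = (
    ("<18", 0.0, 18.0),        # [0, 18)
    ("18-64.9", 18.0, 65.0),   # [18, 65)
    ("65-85", 65.0, 85.0),     # [65, 85]
    (">85", 85.0, float("inf")),
)

WEIGHT_STRATA: tuple[tuple[str, float, float], ...] = (
    ("<50", 0.0, 50.0),
    ("50-100", 50.0, 100.0),
    (">100", 100.0, float("inf")),
)

OUTCOME_ORDER = (
    "death",
    "hospitalization",
    "life_threatening",
    "disability",
    "congenital_anomaly",
    "required_intervention",
    "other",
    "missing",
)

REPORTER_ORDER = (
    "consumer",
    "physician",
    "health_professional",
    "pharmacist",
    "other",
    "missing",
)


def percent(count: int, total: int) -> float:
    """One-decimal percentage, rounded half-up (presentation convention)."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortProfile:
    n: int
    sex: Partition
    age: Partition
    weight: Partition
    outcome: Partition
    countries: Partition  # top 5 by count, ties alphabetical
    reporter: Partition
    year: Partition


def _age_stratum(age: float | None) -> str:
    if age is None:
        return "missing"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64.9"
    if age <= 85:
        return "65-85"
    return ">85"


def _weight_stratum(w: float | None) -> str:
    if w is None:
        return "missing"
    if w < 50:
        return "<50"
    if w <= 100:
        return "50-100"
    return ">100"


def profile(cases: list[ReportCase]) -> CohortProfile:
    """Deterministic partition counts and percentages for the cohort."""
    if not cases:
        raise ValueError("empty cohort")
    n = len(cases)

    def part(values: list[str], order: list[str]) -> Partition:
        counts = pd.Series(values).value_counts()
        return [(cat, int(counts.get(cat, 0)), percent(int(counts.get(cat, 0)), n)) for cat in order]

    sex = part([c.sex for c in cases], ["female", "male", "unknown"])
    age = part(
        [_age_stratum(c.age_years) for c in cases],
        [s[0] for s in AGE_STRATA] + ["missing"],
    )
    weight = part(
        [_weight_stratum(c.weight_kg) for c in cases],
        [s[0] for s in WEIGHT_STRATA] + ["missing"],
    )
    outcome = part([c.outcome for c in cases], list(OUTCOME_ORDER))

    ctry_counts = pd.Series([c.country or "missing" for c in cases]).value_counts()
    ranked = sorted(ctry_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    countries = [(k, int(v), percent(int(v), n)) for k, v in ranked[:5]]

    reporter = part([c.reporter for c in cases], list(REPORTER_ORDER))

    years = [str(c.report_year) if c.report_year is not None else "missing" for c in cases]
    year_order = sorted({y for y in years if y != "missing"}) + (
        ["missing"] if "missing" in years else []
    )
    year = part(years, year_order)

    return CohortProfile(
        n=n,
        sex=sex,
        age=age,
        weight=weight,
        outcome=outcome,
        countries=countries,
        reporter=reporter,
        year=year,
    )


def profile_frame(p: CohortProfile) -> pd.DataFrame:
    rows = []
    for name, partition in (
        ("sex", p.sex),
        ("age", p.age),
        ("weight", p.weight),
        ("outcome", p.outcome),
        ("country", p.countries),
        ("reporter", p.reporter),
        ("year", p.year),
    ):
        for cat, count, pct in partition:
            rows.append({"partition": name, "category": cat, "count": count, "percent": pct})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SubgroupSpec:
    """A named stratum defined by a predicate over demographic fields.

    The predicate receives any object carrying ``sex`` and ``age_years``
    attributes, so it applies to both cohort cases and background rows.
    """

    name: str
    predicate: Callable[[object], bool]


def sex_subgroups() -> list[SubgroupSpec]:
    return [
        SubgroupSpec("male", lambda r: r.sex == "male"),
        SubgroupSpec("female", lambda r: r.sex == "female"),
    ]


def age_subgroups() -> list[SubgroupSpec]:
    """Two-way adult split; under-18 reports fall outside both strata."""
    return [
        SubgroupSpec(
            "age_18_64",
            lambda r: r.age_years is not None and 18 <= r.age_years < 65,
        ),
        SubgroupSpec(
            "age_65_plus",
            lambda r: r.age_years is not None and r.age_years >= 65,
        ),
    ]


@dataclass(frozen=True)
class _BgRow:
    sex: str
    age_years: float | None


def subgroup_screen(
    cases: list[ReportCase],
    background_attrs: pd.DataFrame,
    background_pairs: pd.DataFrame,
    spec: SubgroupSpec,
    pt_soc_map: dict[str, str] | None = None,
    level: str = "PT",
    soc_exclusions: tuple[str, ...] = (),
    priors: BcpnnPriors = DEFAULT_PRIORS,
    haldane: bool = False,
) -> ScreenResult:
    """Re-run the signal screen inside one demographic stratum.

    ``background_attrs`` has columns ``primaryid``, ``sex``, ``age_years``
    for every comparator report; the comparator is restricted to the same
    stratum as the cohort.  An empty stratum yields an empty result.
    """
    strat_cases = [c for c in cases if spec.predicate(c)]
    keep_bg = {
        str(pid)
        for pid, sex, age in background_attrs[
            ["primaryid", "sex", "age_years"]
        ].itertuples(index=False)
        if spec.predicate(_BgRow(sex=sex, age_years=None if pd.isna(age) else float(age)))
    }
    bg = background_pairs[background_pairs["primaryid"].astype(str).isin(keep_bg)]
    return screen(
        cohort_pairs(strat_cases),
        bg,
        pt_soc_map=pt_soc_map,
        level=level,
        soc_exclusions=soc_exclusions,
        priors=priors,
        haldane=haldane,
    )
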