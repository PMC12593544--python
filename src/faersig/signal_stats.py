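"""Four-algorithm disproportionality analysis on 2x2 contingency tables.

For each drug-event pair the database reduces to the classic table

    ============  ===========  ============
                  target event  other events
    target drug        a             b
    other drugs        c             d
    ============  ===========  ============

counted over unique (report, term) pairs after per-report term
deduplication.  Four statistics are computed on every table:

* ROR  — reporting odds ratio ``ad/(bc)`` with a Wald CI on the log scale,
* PRR  — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square of the table,
* IC   — the BCPNN information component ``log2(a*N / ((a+b)(a+c)))`` with
  a Bayesian posterior-variance lower credibility bound (IC025),
* EBGM — the observed/expected relative reporting ratio (the same kernel
  as 2**IC) with a log-normal-style lower bound (EBGM05).

A term is a signal only when it meets all four published criteria
simultaneously: ROR lower 95% bound > 1 with at least 3 cases; PRR >= 2
with chi-square >= 4 and at least 3 cases; IC025 > 0; EBGM05 > 2.

The EBGM here is deliberately the unshrunk observed/expected ratio; no
gamma-Poisson empirical-Bayes shrinkage is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # two-sided 95% normal quantile
LN2 = math.log(2.0)

UNMAPPED_SOC = "Unmapped"


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts underlying every disproportionality statistic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN posterior variance.

    Defaults are the standard symmetric choice: marginal pseudo-counts
    ``alpha1 = beta1 = 1`` within prior totals ``alpha = beta = 2`` and a
    joint pseudo-count ``gamma11 = 1``.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha", "beta", "gamma11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be strictly positive")


DEFAULT_PRIORS = BcpnnPriors()


@dataclass
class SignalMetrics:
    """All four statistics for one term, with criteria flags.

    Not-computable statistics (zero cells) are NaN and their flag is
    False; ``significant_all4`` is the conjunction of the four flags.
    """

    term: str
    level: str  # PT | SOC
    a: int
    ror: float = math.nan
    ror_lo95: float = math.nan
    ror_hi95: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    soc: str | None = None
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False
    significant_all4: bool = False


def ror_with_ci(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% Wald CI on the log scale.

    Undefined (NaN) when any cell is zero — the published formula has no
    continuity correction, and an infinite estimate is never emitted.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, math.exp(math.log(ror) - Z95 * se), math.exp(math.log(ror) + Z95 * se))


def prr_with_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square (no
    continuity correction) of the 2x2 table."""
    n = t.n_total
    ab, cd, ac, bd = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if t.c == 0 or ab == 0 or cd == 0:
        return (math.nan, math.nan)
    prr = (t.a * cd) / (t.c * ab)
    if ac == 0 or bd == 0:
        return (prr, math.nan)
    chi2 = ((t.a * t.d - t.b * t.c) ** 2) * n / (ab * cd * ac * bd)
    return (prr, chi2)


def bcpnn_ic(
    t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS
) -> tuple[float, float]:
    """BCPNN information component and its lower 95% credibility bound.

    The point estimate is the observed/expected log2 ratio; IC025 is
    ``IC - 2*sqrt(V)`` with V the Bayesian posterior variance of the IC
    under the Dirichlet/Beta priors ``priors``.
    """
    if t.a == 0:
        return (math.nan, math.nan)
    n = t.n_total
    ab, ac = t.a + t.b, t.a + t.c
    ic = math.log2(t.a * n / (ab * ac))
    v = _ic_variance(t.a, t.b, t.c, t.d, priors)
    return (ic, ic - 2.0 * math.sqrt(v))


def ebgm_with_bound(t: ContingencyTable) -> tuple[float, float]:
    """Observed/expected relative reporting ratio (EBGM as printed, i.e.
    unshrunk) with its lower 95% bound on the log scale."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan)
    n = t.n_total
    ebgm = t.a * n / ((t.a + t.c) * (t.a + t.b))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ebgm, math.exp(math.log(ebgm) - Z95 * se))


def _ic_variance(a: float, b: float, c: float, d: float, p: BcpnnPriors) -> float:
    """BCPNN posterior variance of the IC under priors ``p`` (real-valued
    cells so the Haldane-corrected path can reuse it)."""
    n = a + b + c + d
    ab, ac = a + b, a + c
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((ab + p.alpha1) * (ac + p.beta1))
    return (1.0 / LN2) ** 2 * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta))
    )


def _metrics_from_cells(
    term: str,
    level: str,
    a: int,
    b: int,
    c: int,
    d: int,
    priors: BcpnnPriors,
    haldane: bool,
) -> SignalMetrics:
    m = SignalMetrics(term=term, level=level, a=a)
    if haldane and min(a, b, c, d) == 0:
        # Exploratory continuity correction: 0.5 on every cell.
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n = aa + bb + cc + dd
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        m.ror = aa * dd / (bb * cc)
        m.ror_lo95 = math.exp(math.log(m.ror) - Z95 * se)
        m.ror_hi95 = math.exp(math.log(m.ror) + Z95 * se)
        m.prr = aa * (cc + dd) / (cc * (aa + bb))
        m.chi2 = ((aa * dd - bb * cc) ** 2) * n / (
            (aa + bb) * (cc + dd) * (aa + cc) * (bb + dd)
        )
        m.ebgm = aa * n / ((aa + cc) * (aa + bb))
        m.ebgm05 = math.exp(math.log(m.ebgm) - Z95 * se)
        m.ic = math.log2(m.ebgm)
        m.ic025 = m.ic - 2.0 * math.sqrt(_ic_variance(aa, bb, cc, dd, priors))
    else:
        t = ContingencyTable(a=a, b=b, c=c, d=d)
        m.ror, m.ror_lo95, m.ror_hi95 = ror_with_ci(t)
        m.prr, m.chi2 = prr_with_chi2(t)
        m.ic, m.ic025 = bcpnn_ic(t, priors)
        m.ebgm, m.ebgm05 = ebgm_with_bound(t)
    return evaluate_criteria(m)


def compute_metrics(
    t: ContingencyTable,
    term: str = "",
    level: str = "PT",
    priors: BcpnnPriors = DEFAULT_PRIORS,
    haldane: bool = False,
) -> SignalMetrics:
    """Compute all four statistics and criteria flags for one table."""
    return _metrics_from_cells(term, level, t.a, t.b, t.c, t.d, priors, haldane)


def evaluate_criteria(m: SignalMetrics) -> SignalMetrics:
    """Apply the published significance criteria in place.

    ROR: lower 95% bound strictly > 1 and at least 3 cases.
    PRR: PRR >= 2, chi-square >= 4, at least 3 cases (inclusive bounds).
    BCPNN: IC025 strictly > 0.   MGPS: EBGM05 strictly > 2.
    NaN statistics never satisfy a criterion.
    """
    m.flag_ror = bool(m.ror_lo95 > 1.0 and m.a >= 3)
    m.flag_prr = bool(m.prr >= 2.0 and m.chi2 >= 4.0 and m.a >= 3)
    m.flag_bcpnn = bool(m.ic025 > 0.0)
    m.flag_mgps = bool(m.ebgm05 > 2.0)
    m.significant_all4 = m.flag_ror and m.flag_prr and m.flag_bcpnn and m.flag_mgps
    return m


def build_contingency(
    pairs: "pd.DataFrame | list[tuple[str, str]]",
    target_reports: set[str],
    term: str,
) -> ContingencyTable:
    """Count the 2x2 table for one term from unique (report, term) pairs.

    ``pairs`` holds every unique pair in the database (target and
    comparator reports together); ``target_reports`` identifies the
    cohort.  A term absent everywhere yields a valid all-zero-margin
    table whose statistics are simply not computable.
    """
    if isinstance(pairs, pd.DataFrame):
        it = pairs.iloc[:, :2].astype(str).itertuples(index=False)
    else:
        it = iter(pairs)
    a = b = c = d = 0
    seen: set[tuple[str, str]] = set()
    for rid, pt in it:
        key = (str(rid), str(pt))
        if key in seen:
            continue
        seen.add(key)
        tgt = key[0] in target_reports
        hit = key[1] == term
        if tgt and hit:
            a += 1
        elif tgt:
            b += 1
        elif hit:
            c += 1
        else:
            d += 1
    return ContingencyTable(a=a, b=b, c=c, d=d)


@dataclass
class ScreenResult:
    """Ranked metrics plus the per-algorithm hit counts (Venn inputs)."""

    level: str
    metrics: list[SignalMetrics]
    venn: dict[str, int]
    all4_terms: list[str]
    all4_after_exclusion: list[str]


def _apply_soc(pairs: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    lower = {k.strip().lower(): v for k, v in mapping.items()}
    socs = pairs["pt"].str.strip().str.lower().map(lower).fillna(UNMAPPED_SOC)
    out = pd.DataFrame({"primaryid": pairs["primaryid"], "pt": socs})
    return out.drop_duplicates(ignore_index=True)


def screen(
    cohort_pairs: pd.DataFrame,
    background_pairs: pd.DataFrame,
    pt_soc_map: dict[str, str] | None = None,
    level: str = "PT",
    soc_exclusions: tuple[str, ...] | list[str] = (),
    priors: BcpnnPriors = DEFAULT_PRIORS,
    haldane: bool = False,
) -> ScreenResult:
    """Screen every term observed in the cohort at PT or SOC level.

    ``cohort_pairs`` / ``background_pairs`` are DataFrames with columns
    ``primaryid`` and ``pt`` holding unique report-term pairs for the
    target cohort and the comparator (rest of database) respectively.
    At SOC level the PTs are first mapped through ``pt_soc_map`` (PTs
    without a mapping are grouped under the reserved SOC "Unmapped") and
    pairs re-deduplicated.

    The intersection list is additionally re-reported after dropping
    terms whose SOC is in ``soc_exclusions`` (case-insensitive match) —
    used to remove organ classes that reflect the underlying disease
    rather than the drug.  Output is sorted by descending case count,
    ties broken lexicographically by term.
    """
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    mapping = pt_soc_map or {}
    cp = cohort_pairs[["primaryid", "pt"]].astype(str).drop_duplicates()
    bp = background_pairs[["primaryid", "pt"]].astype(str).drop_duplicates()
    if level == "SOC":
        cp = _apply_soc(cp, mapping)
        bp = _apply_soc(bp, mapping)

    a_counts = cp["pt"].value_counts()
    c_counts = bp["pt"].value_counts()
    total_target = len(cp)
    total_bg = len(bp)

    lower_map = {k.strip().lower(): v for k, v in mapping.items()}
    excl = {s.strip().lower() for s in soc_exclusions}

    metrics: list[SignalMetrics] = []
    for term in a_counts.index:
        a = int(a_counts[term])
        c = int(c_counts.get(term, 0))
        b = total_target - a
        d = total_bg - c
        m = _metrics_from_cells(term, level, a, b, c, d, priors, haldane)
        if level == "PT":
            m.soc = lower_map.get(term.strip().lower(), UNMAPPED_SOC if mapping else None)
        else:
            m.soc = term
        metrics.append(m)
    metrics.sort(key=lambda m: (-m.a, m.term))

    venn = {
        "ror": sum(m.flag_ror for m in metrics),
        "prr": sum(m.flag_prr for m in metrics),
        "bcpnn": sum(m.flag_bcpnn for m in metrics),
        "mgps": sum(m.flag_mgps for m in metrics),
        "all4": sum(m.significant_all4 for m in metrics),
    }
    all4 = [m.term for m in metrics if m.significant_all4]

    def excluded(m: SignalMetrics) -> bool:
        soc = m.soc if level == "SOC" else (m.soc or "")
        return (soc or "").strip().lower() in excl

    all4_after = [m.term for m in metrics if m.significant_all4 and not excluded(m)]
    venn["all4_after_soc_exclusion"] = len(all4_after)
    return ScreenResult(
        level=level,
        metrics=metrics,
        venn=venn,
        all4_terms=all4,
        all4_after_exclusion=all4_after,
    )


def metrics_frame(result: ScreenResult) -> pd.DataFrame:
    """Tabular export mirroring the usual published column layout."""
    rows = []
    for m in result.metrics:
        rows.append(
            {
                "term": m.term,
                "soc": m.soc or "",
                "cases": m.a,
                "ror": m.ror,
                "ror_lo95": m.ror_lo95,
                "ror_hi95": m.ror_hi95,
                "prr": m.prr,
                "chi2": m.chi2,
                "ebgm": m.ebgm,
                "ebgm05": m.ebgm05,
                "ic": m.ic,
                "ic025": m.ic025,
                "flag_ror": m.flag_ror,
                "flag_prr": m.flag_prr,
                "flag_bcpnn": m.flag_bcpnn,
                "flag_mgps": m.flag_mgps,
                "significant_all4": m.significant_all4,
            }
        )
    return pd.DataFrame(rows)
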