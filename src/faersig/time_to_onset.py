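"""Time-to-onset analysis: onset intervals and Weibull hazard modeling.

The onset interval of a report is the number of days from therapy start
(earliest day-resolution START_DT of the primary-suspect drug rows) to
the event date (EVENT_DT).  Only full calendar dates support the
subtraction; partial dates, missing dates, events preceding the start and
same-day events are excluded and tallied by reason.

The retained intervals are modeled with a two-parameter Weibull density

    f(t) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta)

fit by maximum likelihood.  The shape parameter beta carries the clinical
reading: beta < 1 means a decreasing hazard (early-failure pattern —
most events shortly after initiation), beta ~ 1 a constant hazard, and
beta > 1 an increasing hazard (wear-out / delayed toxicity).  The
classification uses the 95% CI of beta, not the point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cohort import ReportCase
from .faers_io import RawTable, parse_faers_date

Z95 = 1.959963984540054

ONSET_BINS: tuple[tuple[str, int, float], ...] = (
    ("1-30", 1, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-180", 91, 180),
    ("181-360", 181, 360),
    (">360", 361, math.inf),
)


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    onset_days: int  # >= 1, day-resolution dates only


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull fit with normal-approximation CIs.

    CIs are computed on the log-parameters from the inverse observed
    information and back-transformed, which respects positivity.
    """

    scale_alpha: float
    shape_beta: float
    scale_ci95: tuple[float, float]
    shape_ci95: tuple[float, float]
    n: int
    median_days: float
    iqr: tuple[float, float]
    failure_type: str  # early | random | wear_out


@dataclass
class OnsetSummary:
    n: int
    median: float
    q1: float
    q3: float
    min: int
    max: int
    bins: list[tuple[str, int, float]]  # (label, count, percent)


def compute_onsets(
    cases: list[ReportCase], ther: "RawTable | object"
) -> tuple[list[OnsetRecord], dict[str, int]]:
    """Onset interval per report, with an exclusion tally.

    Therapy start is the earliest day-resolution START_DT among the
    report's primary-suspect target-drug therapy rows (``dsg_drug_seq``
    in the report's PS drug sequence set).  Exclusion reasons:

    - ``no_therapy_start``: no PS therapy row with a day-resolution start
    - ``event_missing_or_partial``: EVENT_DT absent or not day-resolution
    - ``event_before_start``: chronologically implausible
    - ``same_day``: interval 0 (outside the positive Weibull support)
    """
    if isinstance(ther, RawTable):
        tf = ther.to_frame()
    else:
        tf = ther
    starts: dict[str, int] = {}
    by_case = {c.primaryid: c for c in cases}
    sub = tf[tf["primaryid"].astype(str).isin(by_case)]
    for pid, seq, raw in (
        sub[["primaryid", "dsg_drug_seq", "start_dt"]].astype(str).itertuples(index=False)
    ):
        case = by_case[pid]
        if seq not in case.ps_drug_seqs:
            continue
        d = parse_faers_date(raw)
        if d.day_value is None:
            continue
        o = d.day_value.toordinal()
        if pid not in starts or o < starts[pid]:
            starts[pid] = o

    records: list[OnsetRecord] = []
    tally = {
        "no_therapy_start": 0,
        "event_missing_or_partial": 0,
        "event_before_start": 0,
        "same_day": 0,
    }
    for case in cases:
        start = starts.get(case.primaryid)
        if start is None:
            tally["no_therapy_start"] += 1
            continue
        if case.event_dt.day_value is None:
            tally["event_missing_or_partial"] += 1
            continue
        delta = case.event_dt.day_value.toordinal() - start
        if delta < 0:
            tally["event_before_start"] += 1
        elif delta == 0:
            tally["same_day"] += 1
        else:
            records.append(OnsetRecord(primaryid=case.primaryid, onset_days=delta))
    return records, tally


def _weibull_negloglik(logparams: np.ndarray, t: np.ndarray) -> float:
    log_alpha, log_beta = logparams
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = t / alpha
    return -(
        len(t) * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.log(t).sum()
        - (z**beta).sum()
    )


def _mle(t: np.ndarray) -> tuple[float, float]:
    """Profile-likelihood MLE: solve the one-dimensional shape equation by
    bracketed root finding, then the scale in closed form.

    Values are scaled by their maximum before exponentiation so the sums
    stay finite for any shape the bracket can reach.
    """
    ts = t / t.max()
    logts = np.log(ts)
    mlog = logts.mean()

    def g(beta: float) -> float:
        tb = ts**beta
        return float((tb * logts).sum() / tb.sum() - 1.0 / beta - mlog)

    lo, hi = 1e-3, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("degenerate sample: shape estimate diverges")
    beta = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
    alpha = float(t.max() * ((ts**beta).sum() / len(ts)) ** (1.0 / beta))
    return alpha, beta


def fit_weibull(onsets: "list[int] | np.ndarray") -> WeibullFit:
    """Fit the two-parameter Weibull to positive onset days by maximum
    likelihood and classify the hazard pattern.

    Requires at least 10 observations and more than one distinct value
    (a point mass has an unbounded likelihood).  Deterministic.
    """
    t = np.asarray(
        [o.onset_days if isinstance(o, OnsetRecord) else o for o in onsets],
        dtype=float,
    )
    if len(t) < 10:
        raise ValueError(f"need at least 10 onset observations, got {len(t)}")
    if np.any(t <= 0):
        raise ValueError("onset days must be strictly positive")
    if np.all(t == t[0]):
        raise ValueError("degenerate sample: all onsets identical")

    alpha, beta = _mle(t)

    # Observed information on (log alpha, log beta) by central differences.
    theta = np.array([math.log(alpha), math.log(beta)])
    h = 1e-5
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = theta.copy(); pp[i] += h; pp[j] += h
            pm = theta.copy(); pm[i] += h; pm[j] -= h
            mp = theta.copy(); mp[i] -= h; mp[j] += h
            mm = theta.copy(); mm[i] -= h; mm[j] -= h
            hess[i, j] = (
                _weibull_negloglik(pp, t)
                - _weibull_negloglik(pm, t)
                - _weibull_negloglik(mp, t)
                + _weibull_negloglik(mm, t)
            ) / (4 * h * h)
    cov = np.linalg.inv(hess)
    se_la, se_lb = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))

    scale_ci = (alpha * math.exp(-Z95 * se_la), alpha * math.exp(Z95 * se_la))
    shape_ci = (beta * math.exp(-Z95 * se_lb), beta * math.exp(Z95 * se_lb))

    q1, med, q3 = np.percentile(t, [25, 50, 75])
    fit = WeibullFit(
        scale_alpha=alpha,
        shape_beta=beta,
        scale_ci95=scale_ci,
        shape_ci95=shape_ci,
        n=len(t),
        median_days=float(med),
        iqr=(float(q1), float(q3)),
        failure_type="",
    )
    fit.failure_type = classify_failure(fit)
    return fit


def classify_failure(fit: WeibullFit) -> str:
    """Hazard pattern from the shape CI: ``early`` when the whole CI sits
    below 1 (decreasing hazard), ``wear_out`` when above 1, ``random``
    when the CI spans 1."""
    lo, hi = fit.shape_ci95
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear_out"
    return "random"


def onset_summary(onsets: "list[int] | list[OnsetRecord] | np.ndarray") -> OnsetSummary:
    """Median/IQR (linear-interpolation quantiles), range, and interval
    bins with percentages of the analyzed sample."""
    t = np.asarray(
        [o.onset_days if isinstance(o, OnsetRecord) else o for o in onsets],
        dtype=float,
    )
    if len(t) == 0:
        raise ValueError("no onset observations")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    bins: list[tuple[str, int, float]] = []
    n = len(t)
    for label, lo, hi in ONSET_BINS:
        count = int(np.sum((t >= lo) & (t <= hi)))
        bins.append((label, count, 100.0 * count / n))
    return OnsetSummary(
        n=n,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=int(t.min()),
        max=int(t.max()),
        bins=bins,
    )
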