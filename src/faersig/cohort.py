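"""Cohort construction: deduplication, drug matching and normalization.

Spontaneous-report databases carry the same case many times — follow-up
versions, manufacturer resubmissions — so every analysis starts by
collapsing to one report per case.  The rule used here keeps, per CASEID,
the version with the most recent FDA receipt date, breaking ties by the
highest PRIMARYID.  The analysis cohort is then the subset of retained
reports in which the drug of interest appears as the primary-suspect (PS)
drug, with demographics and outcomes normalized into analysis categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .faers_io import FaersDate, RawTable, parse_faers_date

SEX_LABELS = {"F": "female", "M": "male"}

REPORTER_LABELS = {
    "CN": "consumer",
    "MD": "physician",
    "HP": "health_professional",
    "PH": "pharmacist",
}

OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}

#: Severity order used to reduce a report's outcome codes to one category.
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.453592}


class IntegrityError(ValueError):
    """The input tables violate a structural assumption (e.g. duplicate
    PRIMARYID rows in DEMO)."""


@dataclass
class ReportCase:
    """One deduplicated safety report, normalized for analysis."""

    primaryid: str
    caseid: str
    fda_dt: FaersDate
    event_dt: FaersDate
    sex: str  # female | male | unknown
    age_years: float | None
    weight_kg: float | None
    country: str | None
    reporter: str  # consumer | physician | health_professional | pharmacist | other | missing
    outcome: str  # death | hospitalization | ... | missing
    report_year: int | None
    pts: frozenset[str] = field(default_factory=frozenset)
    ps_drug_seqs: frozenset[str] = field(default_factory=frozenset)


@dataclass
class CohortBuild:
    """Result of :func:`build_cohort` with the intermediate stage sets kept
    for audit (the report-count funnel)."""

    cases: list[ReportCase]
    retained_ids: set[str]
    matched_ids: set[str]
    ps_ids: set[str]
    no_reac_ids: set[str]
    counts: dict[str, int]


def _as_frame(table: RawTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, RawTable):
        return table.to_frame()
    return table


def deduplicate(demo: RawTable | pd.DataFrame) -> set[str]:
    """Return the PRIMARYIDs retained after case-level deduplication.

    Per CASEID keeps the row maximizing ``(fda_dt, primaryid)``: latest FDA
    receipt date first, highest PRIMARYID on ties.  Rows whose FDA_DT is
    not a full calendar date sort below any dated row, so they lose every
    tie-break but are retained when they are the only version of a case.
    Deterministic and independent of input row order.
    """
    df = _as_frame(demo)
    pids = df["primaryid"].astype(str)
    if pids.duplicated().any():
        dup = pids[pids.duplicated()].iloc[0]
        raise IntegrityError(f"duplicate primaryid {dup!r} in DEMO")

    def fda_key(s: str) -> int:
        d = parse_faers_date(s)
        if d.day_value is None:
            return -1
        return d.day_value.toordinal()

    def pid_key(s: str) -> int:
        return int(s) if s.isdigit() else -1

    work = pd.DataFrame(
        {
            "caseid": df["caseid"].astype(str),
            "primaryid": pids,
            "_fda": df["fda_dt"].astype(str).map(fda_key),
            "_pid": pids.map(pid_key),
        }
    )
    # Stable deterministic ordering: the last row within each case after
    # sorting by (fda, pid, primaryid-string) is the retained version.
    work = work.sort_values(
        ["caseid", "_fda", "_pid", "primaryid"], kind="mergesort"
    )
    kept = work.drop_duplicates("caseid", keep="last")
    return set(kept["primaryid"])


def match_target_drug(
    drug: RawTable | pd.DataFrame, term: str
) -> dict[str, list[tuple[str, str]]]:
    """Find reports mentioning the target drug.

    A DRUG row matches when ``term`` occurs as a case-insensitive
    substring of DRUGNAME or PROD_AI — substring because FAERS drug names
    are free text with dose and brand suffixes.  Returns
    ``{primaryid: [(drug_seq, role_cod), ...]}`` over matching rows.
    """
    if not term or not term.strip():
        raise ValueError("empty drug search term")
    df = _as_frame(drug)
    needle = term.strip().lower()
    name = df["drugname"].astype(str).str.lower()
    ai = df["prod_ai"].astype(str).str.lower()
    hit = name.str.contains(needle, regex=False) | ai.str.contains(
        needle, regex=False
    )
    out: dict[str, list[tuple[str, str]]] = {}
    sub = df.loc[hit, ["primaryid", "drug_seq", "role_cod"]].astype(str)
    for pid, seq, role in sub.itertuples(index=False):
        out.setdefault(pid, []).append((seq, role))
    return out


def filter_primary_suspect(
    matches: dict[str, list[tuple[str, str]]],
) -> set[str]:
    """Keep reports where at least one matching drug row is the primary
    suspect (role code PS, case-insensitive)."""
    return {
        pid
        for pid, rows in matches.items()
        if any(role.strip().upper() == "PS" for _, role in rows)
    }


def normalize_age(age: str, code: str) -> float | None:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    Unknown or missing unit codes, unparseable values and negative ages
    all map to missing — never an exception."""
    factor = AGE_UNIT_TO_YEARS.get((code or "").strip().upper())
    if factor is None:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    if value < 0:
        return None
    return value * factor


def normalize_weight(wt: str, code: str) -> float | None:
    """Convert a FAERS (WT, WT_COD) pair to kilograms; anything not in
    KG/LBS maps to missing."""
    factor = WEIGHT_UNIT_TO_KG.get((code or "").strip().upper())
    if factor is None:
        return None
    try:
        value = float(wt)
    except (TypeError, ValueError):
        return None
    if value < 0:
        return None
    return value * factor


def assign_outcome(codes: set[str]) -> str:
    """Reduce a report's OUTC codes to the single most severe category.

    Priority: death > life-threatening > hospitalization > disability >
    congenital anomaly > required intervention > other.  Unknown codes are
    treated as 'other'; no codes at all is 'missing'.
    """
    cleaned = {(c or "").strip().upper() for c in codes}
    cleaned.discard("")
    if not cleaned:
        return "missing"
    known = {c if c in OUTCOME_LABELS else "OT" for c in cleaned}
    for code in OUTCOME_PRIORITY:
        if code in known:
            return OUTCOME_LABELS[code]
    return "missing"  # unreachable: known is non-empty subset of priority


def _normalize_sex(raw: str) -> str:
    return SEX_LABELS.get((raw or "").strip().upper(), "unknown")


def _normalize_reporter(raw: str) -> str:
    code = (raw or "").strip().upper()
    if not code:
        return "missing"
    return REPORTER_LABELS.get(code, "other")


def build_cohort(
    tables: dict[str, RawTable | pd.DataFrame], term: str | list[str]
) -> CohortBuild:
    """Run the full cohort funnel: dedup -> drug match -> PS filter -> join.

    ``term`` may be a single search string or a list (matches are
    unioned).  Reports with no REAC rows stay in the cohort — they still
    contribute demographics — but carry an empty PT set and are excluded
    from signal analysis by the screening stage.
    """
    demo = _as_frame(tables["DEMO"])
    drug = _as_frame(tables["DRUG"])
    reac = _as_frame(tables["REAC"])
    outc = _as_frame(tables["OUTC"])

    retained = deduplicate(demo)

    terms = [term] if isinstance(term, str) else list(term)
    if not terms:
        raise ValueError("at least one drug search term is required")
    matches: dict[str, list[tuple[str, str]]] = {}
    for t in terms:
        for pid, rows in match_target_drug(drug, t).items():
            matches.setdefault(pid, []).extend(rows)

    matched_ids = set(matches) & retained
    ps_ids = filter_primary_suspect(matches) & retained

    # PT sets per retained PS report
    reac_pid = reac["primaryid"].astype(str)
    in_cohort = reac_pid.isin(ps_ids)
    pt_map: dict[str, set[str]] = {}
    for pid, pt in (
        reac.loc[in_cohort, ["primaryid", "pt"]].astype(str).itertuples(index=False)
    ):
        pt = pt.strip()
        if pt:
            pt_map.setdefault(pid, set()).add(pt)

    # Outcome codes per report
    outc_pid = outc["primaryid"].astype(str)
    oc_map: dict[str, set[str]] = {}
    for pid, code in (
        outc.loc[outc_pid.isin(ps_ids), ["primaryid", "outc_cod"]]
        .astype(str)
        .itertuples(index=False)
    ):
        oc_map.setdefault(pid, set()).add(code)

    ps_seq_map: dict[str, frozenset[str]] = {
        pid: frozenset(
            seq for seq, role in rows if role.strip().upper() == "PS"
        )
        for pid, rows in matches.items()
        if pid in ps_ids
    }

    cases: list[ReportCase] = []
    no_reac: set[str] = set()
    demo_cohort = demo[demo["primaryid"].astype(str).isin(ps_ids)]
    for row in demo_cohort.astype(str).to_dict("records"):
        pid = row["primaryid"]
        fda = parse_faers_date(row.get("fda_dt", ""))
        pts = frozenset(pt_map.get(pid, set()))
        if not pts:
            no_reac.add(pid)
        cases.append(
            ReportCase(
                primaryid=pid,
                caseid=row.get("caseid", ""),
                fda_dt=fda,
                event_dt=parse_faers_date(row.get("event_dt", "")),
                sex=_normalize_sex(row.get("sex", "")),
                age_years=normalize_age(row.get("age", ""), row.get("age_cod", "")),
                weight_kg=normalize_weight(row.get("wt", ""), row.get("wt_cod", "")),
                country=(row.get("occr_country", "").strip() or None),
                reporter=_normalize_reporter(row.get("occp_cod", "")),
                outcome=assign_outcome(oc_map.get(pid, set())),
                report_year=(
                    fda.day_value.year
                    if fda.day_value is not None
                    else (int(fda.raw[:4]) if fda.resolution in ("month", "year") else None)
                ),
                pts=pts,
                ps_drug_seqs=ps_seq_map.get(pid, frozenset()),
            )
        )
    cases.sort(key=lambda c: c.primaryid)

    counts = {
        "loaded": len(demo),
        "deduplicated": len(retained),
        "matched": len(matched_ids),
        "ps_filtered": len(cases),
    }
    return CohortBuild(
        cases=cases,
        retained_ids=retained,
        matched_ids=matched_ids,
        ps_ids=ps_ids,
        no_reac_ids=no_reac,
        counts=counts,
    )


def cohort_frame(cases: list[ReportCase]) -> pd.DataFrame:
    """Audit table: one row per report, PT set serialized ';'-joined."""
    return pd.DataFrame(
        {
            "primaryid": [c.primaryid for c in cases],
            "caseid": [c.caseid for c in cases],
            "fda_dt": [c.fda_dt.raw for c in cases],
            "event_dt": [c.event_dt.raw for c in cases],
            "sex": [c.sex for c in cases],
            "age_years": [c.age_years for c in cases],
            "weight_kg": [c.weight_kg for c in cases],
            "country": [c.country or "" for c in cases],
            "reporter": [c.reporter for c in cases],
            "outcome": [c.outcome for c in cases],
            "report_year": [c.report_year for c in cases],
            "pts": [";".join(sorted(c.pts)) for c in cases],
        }
    )


def background_pairs(
    reac: RawTable | pd.DataFrame, retained_ids: set[str], cohort_ids: set[str]
) -> pd.DataFrame:
    """Unique (report, PT) pairs for the comparator population: every
    retained report that is not in the target cohort."""
    df = _as_frame(reac)
    pid = df["primaryid"].astype(str)
    keep = pid.isin(retained_ids) & ~pid.isin(cohort_ids)
    out = df.loc[keep, ["primaryid", "pt"]].astype(str)
    out["pt"] = out["pt"].str.strip()
    out = out[out["pt"] != ""]
    return out.drop_duplicates(ignore_index=True)


def cohort_pairs(cases: list[ReportCase]) -> pd.DataFrame:
    """Unique (report, PT) pairs for the cohort."""
    pids: list[str] = []
    pts: list[str] = []
    for c in cases:
        for pt in sorted(c.pts):
            pids.append(c.primaryid)
            pts.append(pt)
    return pd.DataFrame({"primaryid": pids, "pt": pts})
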