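"""Synthetic FAERS quarter generator with known ground truth.

Emits the five quarterly tables (DEMO, DRUG, REAC, THER, OUTC) in the
FAERS ASCII dialect, emulating the structures the pipeline must survive:

* multi-table reports keyed by PRIMARYID/CASEID,
* duplicate case versions differing only in FDA_DT/PRIMARYID,
* a target drug occupying a small fraction of reports as primary suspect
  (plus a few non-PS mentions that the PS filter must reject),
* background PT frequencies with designated signal PTs whose selection
  odds are multiplied within target-drug reports,
* Weibull-distributed onset times behind START_DT/EVENT_DT,
* partial, missing and inverted dates at configurable rates,
* demographic, outcome and reporter fields.

Signals act multiplicatively on PT selection odds, which keeps the
expected contingency cells in closed form (:func:`expected_contingency`)
so recovery tests have an analytic oracle.  Everything is driven by one
integer seed; the same config yields byte-identical files.

The bundled PT->SOC mapping is a synthetic approximation for testing:
MedDRA is licensed and real analyses must supply their own mapping.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import RawTable, write_faers_table, write_pt_soc_map

_EPOCH_ORD = _dt.date(1970, 1, 1).toordinal()
_WINDOW_START = _dt.date(2023, 10, 1).toordinal()
_WINDOW_DAYS = (_dt.date(2025, 3, 31) - _dt.date(2023, 10, 1)).days + 1

#: Background PT vocabulary (name, multinomial weight), loosely echoing the
#: frequency skew of oncology cohorts: a few very common constitutional and
#: gastrointestinal terms, a long tail of rarer events.
DEFAULT_VOCAB: tuple[tuple[str, float], ...] = (
    ("Fatigue", 10.0),
    ("Nausea", 8.0),
    ("Diarrhoea", 7.0),
    ("Vomiting", 6.0),
    ("Death", 6.0),
    ("Headache", 6.0),
    ("Dyspnoea", 5.0),
    ("Pyrexia", 5.0),
    ("Rash", 5.0),
    ("Dizziness", 5.0),
    ("Drug ineffective", 4.0),
    ("Asthenia", 4.0),
    ("Decreased appetite", 4.0),
    ("Anaemia", 4.0),
    ("Pain", 4.0),
    ("Abdominal pain", 3.0),
    ("Constipation", 3.0),
    ("Hypertension", 3.0),
    ("Blood pressure increased", 3.0),
    ("Off label use", 3.0),
    ("Malignant neoplasm progression", 2.5),
    ("Arthralgia", 2.5),
    ("Cough", 2.5),
    ("Insomnia", 2.0),
    ("Anxiety", 2.0),
    ("Back pain", 2.0),
    ("Oedema peripheral", 2.0),
    ("Pruritus", 2.0),
    ("Weight decreased", 2.0),
    ("Fall", 2.0),
    ("Pneumonia", 2.0),
    ("Stomatitis", 1.5),
    ("Platelet count decreased", 1.5),
    ("Urinary tract infection", 1.5),
    ("Alopecia", 1.5),
    ("Product dose omission issue", 1.5),
    ("Dysgeusia", 1.2),
    ("Proteinuria", 1.0),
    ("Renal impairment", 1.0),
    ("Hepatic function abnormal", 1.0),
    ("Dehydration", 1.0),
    ("Dysphonia", 1.0),
    ("Tinnitus", 0.9),
    ("Myelosuppression", 0.8),
    ("Palmar-plantar erythrodysesthesia syndrome", 0.8),
    ("Hypothyroidism", 0.8),
    ("Epistaxis", 0.8),
    ("Mucosal inflammation", 0.8),
)

#: Synthetic PT -> primary SOC assignment for the default vocabulary.
SYNTHETIC_PT_SOC: dict[str, str] = {
    "Fatigue": "General disorders and administration site conditions",
    "Death": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Pain": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
    "Mucosal inflammation": "General disorders and administration site conditions",
    "Nausea": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Abdominal pain": "Gastrointestinal disorders",
    "Constipation": "Gastrointestinal disorders",
    "Stomatitis": "Gastrointestinal disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Dysgeusia": "Nervous system disorders",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "Cough": "Respiratory, thoracic and mediastinal disorders",
    "Dysphonia": "Respiratory, thoracic and mediastinal disorders",
    "Epistaxis": "Respiratory, thoracic and mediastinal disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Alopecia": "Skin and subcutaneous tissue disorders",
    "Palmar-plantar erythrodysesthesia syndrome": "Skin and subcutaneous tissue disorders",
    "Anaemia": "Blood and lymphatic system disorders",
    "Myelosuppression": "Blood and lymphatic system disorders",
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Dehydration": "Metabolism and nutrition disorders",
    "Hypertension": "Vascular disorders",
    "Blood pressure increased": "Investigations",
    "Platelet count decreased": "Investigations",
    "Weight decreased": "Investigations",
    "Off label use": "Injury, poisoning and procedural complications",
    "Product dose omission issue": "Injury, poisoning and procedural complications",
    "Fall": "Injury, poisoning and procedural complications",
    "Malignant neoplasm progression": (
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
    ),
    "Insomnia": "Psychiatric disorders",
    "Anxiety": "Psychiatric disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Back pain": "Musculoskeletal and connective tissue disorders",
    "Pneumonia": "Infections and infestations",
    "Urinary tract infection": "Infections and infestations",
    "Proteinuria": "Renal and urinary disorders",
    "Renal impairment": "Renal and urinary disorders",
    "Hepatic function abnormal": "Hepatobiliary disorders",
    "Hypothyroidism": "Endocrine disorders",
    "Tinnitus": "Ear and labyrinth disorders",
}

OTHER_DRUGS: tuple[str, ...] = (
    "OXALIPLATIN",
    "CAPECITABINE",
    "BEVACIZUMAB",
    "PEMBROLIZUMAB",
    "REGORAFENIB",
    "IRINOTECAN",
    "FLUOROURACIL",
    "TRIFLURIDINE/TIPIRACIL",
    "NIVOLUMAB",
    "ATORVASTATIN",
    "METFORMIN",
    "LISINOPRIL",
    "OMEPRAZOLE",
    "PREDNISONE",
    "ASPIRIN",
    "WARFARIN",
    "GABAPENTIN",
    "LEVOTHYROXINE",
    "AMLODIPINE",
    "IBUPROFEN",
)

_DEFAULT_DEMOGRAPHICS: dict[str, tuple[tuple[str, float], ...]] = {
    "sex": (("F", 0.411), ("M", 0.519), ("", 0.070)),
    "age_bucket": (
        ("<18", 0.056),
        ("18-64.9", 0.244),
        ("65-85", 0.196),
        (">85", 0.007),
        ("missing", 0.497),
    ),
    "weight_bucket": (
        ("<50", 0.028),
        ("50-100", 0.146),
        (">100", 0.015),
        ("missing", 0.811),
    ),
    "outcome": (
        ("DE", 0.339),
        ("HO", 0.248),
        ("LT", 0.013),
        ("DS", 0.006),
        ("OT", 0.394),
    ),
    "country": (
        ("US", 0.629),
        ("CN", 0.146),
        ("JP", 0.081),
        ("GB", 0.030),
        ("FR", 0.025),
        ("DE", 0.020),
        ("", 0.069),
    ),
    "reporter": (
        ("CN", 0.340),
        ("MD", 0.221),
        ("HP", 0.127),
        ("PH", 0.064),
        ("", 0.248),
    ),
}


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic quarter.

    Defaults echo the scale of a recently approved oncology drug in a
    spontaneous-report database: the cohort is about 1% of reports, and
    onset times follow Weibull(scale 32.74 days, shape 0.81) — an
    early-failure pattern with most events in the first treatment month.
    """

    seed: int = 0
    n_reports: int = 20_000
    target_share: float = 0.01
    target_name: str = "FRUQUINTINIB"
    vocab: tuple[tuple[str, float], ...] = DEFAULT_VOCAB
    pts_per_report: tuple[int, int] = (1, 5)
    signals: tuple[tuple[str, float], ...] = (("Dysphonia", 10.0),)
    onset_scale_days: float = 32.74
    onset_shape: float = 0.81
    duplicate_rate: float = 0.10
    partial_date_rate: float = 0.05
    inverted_date_rate: float = 0.03
    missing_event_rate: float = 0.10
    missing_start_rate: float = 0.10
    no_reac_rate: float = 0.01
    target_nonps_share: float = 0.005
    demographics: dict[str, tuple[tuple[str, float], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_DEMOGRAPHICS)
    )

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be positive")
        if not 0 <= self.target_share <= 1:
            raise ConfigError("target_share must be in [0, 1]")
        for name in (
            "duplicate_rate",
            "partial_date_rate",
            "inverted_date_rate",
            "missing_event_rate",
            "missing_start_rate",
            "no_reac_rate",
            "target_nonps_share",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.onset_scale_days <= 0 or self.onset_shape <= 0:
            raise ConfigError("onset scale and shape must be positive")
        if any(w <= 0 for _, w in self.vocab):
            raise ConfigError("vocab weights must be strictly positive")
        if len(self.vocab) < 2 and self.signals:
            raise ConfigError("signals require a vocabulary of at least 2 PTs")
        names = {pt for pt, _ in self.vocab}
        for pt, ratio in self.signals:
            if pt not in names:
                raise ConfigError(f"signal PT {pt!r} not in vocab")
            if ratio <= 0:
                raise ConfigError(f"signal ratio for {pt!r} must be positive")
        kmin, kmax = self.pts_per_report
        if not (1 <= kmin <= kmax):
            raise ConfigError("pts_per_report must satisfy 1 <= min <= max")


@dataclass
class GroundTruth:
    """What the generator intended, for oracle tests and bookkeeping."""

    n_cases: int
    n_cohort: int
    cohort_primaryids: list[str]
    retained_for_duplicated_cases: dict[str, str]  # caseid -> retained primaryid
    planted_signals: dict[str, float]
    expected_cells: dict[str, tuple[float, float, float, float]]
    onset_scale_days: float
    onset_shape: float
    clean_onsets: dict[str, int]  # cohort primaryid -> intended onset days

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1), encoding="utf-8"
        )


def _fmt_dates(ordinals: np.ndarray) -> np.ndarray:
    days = np.asarray(ordinals, dtype="int64") - _EPOCH_ORD
    s = np.datetime_as_string(days.astype("datetime64[D]"), unit="D")
    return np.char.replace(s, "-", "")


def _draw(rng: np.random.Generator, dist: tuple[tuple[str, float], ...], n: int) -> np.ndarray:
    cats = np.array([c for c, _ in dist], dtype=object)
    p = np.array([w for _, w in dist], dtype=float)
    return cats[rng.choice(len(cats), size=n, p=p / p.sum())]


def expected_contingency(
    config: SyntheticConfig, pt: str
) -> tuple[float, float, float, float]:
    """Closed-form expected contingency cells for ``pt`` under the model.

    Per report, ``k`` PT draws (k uniform over ``pts_per_report``) are
    taken i.i.d. from the background multinomial — with signal PTs' odds
    multiplied by their ratio inside target-drug reports — and collapsed
    to a set, so a PT enters a report with probability
    ``1 - (1 - p)**k``.  Cells are expectations over reports that carry
    at least one reaction row.
    """
    names = [name for name, _ in config.vocab]
    if pt not in names:
        raise ConfigError(f"unknown pt {pt!r}")
    w = np.array([wt for _, wt in config.vocab], dtype=float)
    r = np.ones_like(w)
    for s_pt, ratio in config.signals:
        r[names.index(s_pt)] = ratio
    p_b = w / w.sum()
    p_t = (w * r) / (w * r).sum()

    kmin, kmax = config.pts_per_report
    ks = np.arange(kmin, kmax + 1)

    def e_incl(p: np.ndarray) -> np.ndarray:
        # mean over k of 1 - (1-p)^k
        return np.mean(1.0 - (1.0 - p[None, :]) ** ks[:, None], axis=0)

    n_t = int(round(config.n_reports * config.target_share))
    n_b = config.n_reports - n_t
    eff_t = n_t * (1.0 - config.no_reac_rate)
    eff_b = n_b * (1.0 - config.no_reac_rate)

    incl_t = e_incl(p_t)
    incl_b = e_incl(p_b)
    j = names.index(pt)
    a = eff_t * incl_t[j]
    c = eff_b * incl_b[j]
    b = eff_t * incl_t.sum() - a
    d = eff_b * incl_b.sum() - c
    return (float(a), float(b), float(c), float(d))


def generate_frames(
    config: SyntheticConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate the five tables as string-valued DataFrames plus ground
    truth.  Reproducible: the output is a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    caseids = np.arange(1, n + 1)

    n_t = int(round(n * config.target_share))
    target_mask = np.zeros(n, dtype=bool)
    target_mask[rng.choice(n, size=n_t, replace=False)] = True

    non_target_idx = np.flatnonzero(~target_mask)
    n_nonps = int(round(n * config.target_nonps_share))
    n_nonps = min(n_nonps, len(non_target_idx))
    nonps_mask = np.zeros(n, dtype=bool)
    if n_nonps:
        nonps_mask[rng.choice(non_target_idx, size=n_nonps, replace=False)] = True

    fda_ord = _WINDOW_START + rng.integers(0, _WINDOW_DAYS, size=n)
    dup_mask = rng.random(n) < config.duplicate_rate
    tie_mask = rng.random(n) < 0.5  # duplicate shares FDA_DT with retained
    stale_higher_pid = rng.random(n) < 0.5  # stale version gets the higher pid
    stale_delta = rng.integers(1, 60, size=n)

    retained_pid = caseids * 100 + 2
    stale_pid = np.where(
        ~tie_mask & stale_higher_pid, caseids * 100 + 3, caseids * 100 + 1
    )
    stale_fda = np.where(tie_mask, fda_ord, fda_ord - stale_delta)

    # Onset times and dates
    raw_onset = config.onset_scale_days * rng.weibull(config.onset_shape, size=n)
    onset_days = np.maximum(1, np.ceil(raw_onset)).astype(np.int64)
    event_ord = _WINDOW_START + rng.integers(0, _WINDOW_DAYS, size=n)
    start_ord = event_ord - onset_days
    inv_mask = rng.random(n) < config.inverted_date_rate
    ev = np.where(inv_mask, start_ord, event_ord)
    st = np.where(inv_mask, event_ord, start_ord)
    me_mask = rng.random(n) < config.missing_event_rate
    pa_mask = rng.random(n) < config.partial_date_rate
    pa_year = rng.random(n) < 0.5  # truncate to year rather than month
    ms_mask = rng.random(n) < config.missing_start_rate

    ev_str = pd.Series(_fmt_dates(ev))
    ev_str = ev_str.where(~pa_mask, ev_str.str.slice(0, 6))
    ev_str = ev_str.where(~(pa_mask & pa_year), ev_str.str.slice(0, 4))
    ev_str = ev_str.where(~me_mask, "")
    st_str = pd.Series(_fmt_dates(st)).where(~ms_mask, "")

    # PT draws
    names = np.array([name for name, _ in config.vocab], dtype=object)
    V = len(names)
    w = np.array([wt for _, wt in config.vocab], dtype=float)
    r = np.ones_like(w)
    name_list = list(names)
    for s_pt, ratio in config.signals:
        r[name_list.index(s_pt)] = ratio
    p_b = w / w.sum()
    p_t = (w * r) / (w * r).sum()

    kmin, kmax = config.pts_per_report
    k = rng.integers(kmin, kmax + 1, size=n)
    nr_mask = rng.random(n) < config.no_reac_rate
    k = np.where(nr_mask, 0, k)

    bg_idx = np.flatnonzero(~target_mask & ~nr_mask)
    tg_idx = np.flatnonzero(target_mask & ~nr_mask)
    draws_bg = rng.choice(V, size=int(k[bg_idx].sum()), p=p_b)
    draws_tg = rng.choice(V, size=int(k[tg_idx].sum()), p=p_t)
    rep_bg = np.repeat(bg_idx, k[bg_idx])
    rep_tg = np.repeat(tg_idx, k[tg_idx])
    rep_all = np.concatenate([rep_bg, rep_tg])
    pt_all = np.concatenate([draws_bg, draws_tg])
    codes = np.unique(rep_all.astype(np.int64) * V + pt_all)
    reac_rep = (codes // V).astype(int)
    reac_pt = (codes % V).astype(int)

    # Demographics
    sex = _draw(rng, config.demographics["sex"], n)
    age_bucket = _draw(rng, config.demographics["age_bucket"], n)
    age_val = np.zeros(n)
    for bucket, lo, hi in (
        ("<18", 1.0, 17.9),
        ("18-64.9", 18.0, 64.9),
        ("65-85", 65.0, 85.0),
        (">85", 86.0, 95.0),
    ):
        m = age_bucket == bucket
        age_val[m] = np.round(lo + (hi - lo) * rng.random(int(m.sum())))
    age_dec = rng.random(n) < 0.05  # small fraction reported in decades
    age_str = np.where(
        age_bucket == "missing",
        "",
        np.where(
            age_dec,
            np.char.mod("%.1f", age_val / 10.0),
            np.char.mod("%d", age_val.astype(int)),
        ),
    )
    age_cod = np.where(age_bucket == "missing", "", np.where(age_dec, "DEC", "YR"))

    wt_bucket = _draw(rng, config.demographics["weight_bucket"], n)
    wt_val = np.zeros(n)
    for bucket, lo, hi in (("<50", 35.0, 49.9), ("50-100", 50.0, 100.0), (">100", 101.0, 140.0)):
        m = wt_bucket == bucket
        wt_val[m] = np.round(lo + (hi - lo) * rng.random(int(m.sum())), 1)
    wt_lbs = rng.random(n) < 0.10
    wt_str = np.where(
        wt_bucket == "missing",
        "",
        np.where(
            wt_lbs,
            np.char.mod("%.1f", wt_val / 0.453592),
            np.char.mod("%.1f", wt_val),
        ),
    )
    wt_cod = np.where(wt_bucket == "missing", "", np.where(wt_lbs, "LBS", "KG"))

    country = _draw(rng, config.demographics["country"], n)
    reporter = _draw(rng, config.demographics["reporter"], n)
    outc1 = _draw(rng, config.demographics["outcome"], n)
    outc_extra = rng.random(n) < 0.05
    outc2 = _draw(rng, config.demographics["outcome"], n)

    # Drug rows
    variant = rng.integers(0, 3, size=n)
    tgt_names = np.where(
        variant == 0,
        config.target_name,
        np.where(variant == 1, "FRUZAQLA", config.target_name + " 5MG"),
    )
    other1 = np.array(OTHER_DRUGS, dtype=object)[rng.integers(0, len(OTHER_DRUGS), n)]
    other2 = np.array(OTHER_DRUGS, dtype=object)[rng.integers(0, len(OTHER_DRUGS), n)]
    con_mask = rng.random(n) < 0.20
    nonps_role = np.where(rng.random(n) < 0.5, "SS", "C")
    extra_ther = rng.random(n) < 0.10
    extra_ther_delta = rng.integers(5, 30, size=n)

    pid_str = retained_pid.astype(str)
    case_str = caseids.astype(str)
    fda_str = _fmt_dates(fda_ord)

    demo = pd.DataFrame(
        {
            "primaryid": pid_str,
            "caseid": case_str,
            "fda_dt": fda_str,
            "event_dt": ev_str.to_numpy(dtype=object),
            "age": age_str,
            "age_cod": age_cod,
            "sex": sex,
            "wt": wt_str,
            "wt_cod": wt_cod,
            "occr_country": country,
            "occp_cod": reporter,
        }
    )

    ps_name = np.where(target_mask, tgt_names, other1)
    ps_ai = np.char.lower(ps_name.astype(str)).astype(object)
    # brand-name variant exposes the ingredient only through PROD_AI
    ps_ai[target_mask & (variant == 1)] = config.target_name.lower()
    drug_parts = [
        pd.DataFrame(
            {
                "primaryid": pid_str,
                "drug_seq": "1",
                "role_cod": "PS",
                "drugname": ps_name,
                "prod_ai": ps_ai,
            }
        )
    ]
    if con_mask.any():
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str[con_mask],
                    "drug_seq": "2",
                    "role_cod": "C",
                    "drugname": other2[con_mask],
                    "prod_ai": np.char.lower(other2[con_mask].astype(str)),
                }
            )
        )
    if nonps_mask.any():
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str[nonps_mask],
                    "drug_seq": "3",
                    "role_cod": nonps_role[nonps_mask],
                    "drugname": config.target_name,
                    "prod_ai": config.target_name.lower(),
                }
            )
        )
    drug = pd.concat(drug_parts, ignore_index=True)

    reac = pd.DataFrame(
        {"primaryid": pid_str[reac_rep], "pt": names[reac_pt]}
    )

    ther_parts = [
        pd.DataFrame(
            {
                "primaryid": pid_str,
                "dsg_drug_seq": "1",
                "start_dt": st_str.to_numpy(dtype=object),
            }
        )
    ]
    late = extra_ther & ~ms_mask  # a second, later therapy row for the same drug
    if late.any():
        ther_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str[late],
                    "dsg_drug_seq": "1",
                    "start_dt": _fmt_dates(st[late] + extra_ther_delta[late]),
                }
            )
        )
    ther = pd.concat(ther_parts, ignore_index=True)

    outc_parts = [pd.DataFrame({"primaryid": pid_str, "outc_cod": outc1})]
    if outc_extra.any():
        outc_parts.append(
            pd.DataFrame(
                {"primaryid": pid_str[outc_extra], "outc_cod": outc2[outc_extra]}
            )
        )
    outc = pd.concat(outc_parts, ignore_index=True)

    # Stale duplicate versions: same case content, mutated pid + fda_dt.
    if dup_mask.any():
        stale_pid_str = stale_pid.astype(str)
        stale_demo = demo[dup_mask].copy()
        stale_demo["primaryid"] = stale_pid_str[dup_mask]
        stale_demo["fda_dt"] = _fmt_dates(stale_fda[dup_mask])
        demo = pd.concat([demo, stale_demo], ignore_index=True)

        pid_to_stale = dict(zip(pid_str[dup_mask], stale_pid_str[dup_mask]))

        def with_stale(tbl: pd.DataFrame) -> pd.DataFrame:
            stale_rows = tbl[tbl["primaryid"].isin(pid_to_stale)].copy()
            stale_rows["primaryid"] = stale_rows["primaryid"].map(pid_to_stale)
            return pd.concat([tbl, stale_rows], ignore_index=True)

        drug, reac, ther, outc = map(with_stale, (drug, reac, ther, outc))

    frames = {
        "DEMO": demo.astype(str),
        "DRUG": drug.astype(str),
        "REAC": reac.astype(str),
        "THER": ther.astype(str),
        "OUTC": outc.astype(str),
    }

    clean = target_mask & ~inv_mask & ~me_mask & ~pa_mask & ~ms_mask
    truth = GroundTruth(
        n_cases=n,
        n_cohort=int(n_t),
        cohort_primaryids=sorted(pid_str[target_mask].tolist()),
        retained_for_duplicated_cases={
            case_str[i]: pid_str[i] for i in np.flatnonzero(dup_mask)
        },
        planted_signals={pt: ratio for pt, ratio in config.signals},
        expected_cells={
            pt: expected_contingency(config, pt) for pt, _ in config.signals
        },
        onset_scale_days=config.onset_scale_days,
        onset_shape=config.onset_shape,
        clean_onsets={
            pid_str[i]: int(onset_days[i]) for i in np.flatnonzero(clean)
        },
    )
    return frames, truth


def generate(config: SyntheticConfig) -> tuple[dict[str, RawTable], GroundTruth]:
    """Generate the five tables as :class:`RawTable` plus ground truth."""
    frames, truth = generate_frames(config)
    tables = {name: RawTable.from_frame(name, df) for name, df in frames.items()}
    return tables, truth


def synthetic_pt_soc_map(config: SyntheticConfig | None = None) -> dict[str, str]:
    """PT -> SOC mapping covering the configured vocabulary (synthetic
    stand-in for the licensed MedDRA hierarchy)."""
    if config is None:
        return dict(SYNTHETIC_PT_SOC)
    return {
        pt: SYNTHETIC_PT_SOC.get(pt, "Unmapped") for pt, _ in config.vocab
    }


def validate_tables(tables: dict[str, RawTable | pd.DataFrame]) -> None:
    """Assert referential integrity: every child-table PRIMARYID exists in
    DEMO."""
    demo = tables["DEMO"]
    demo_df = demo.to_frame() if isinstance(demo, RawTable) else demo
    demo_ids = set(demo_df["primaryid"].astype(str))
    for name in ("DRUG", "REAC", "THER", "OUTC"):
        tbl = tables[name]
        df = tbl.to_frame() if isinstance(tbl, RawTable) else tbl
        orphans = set(df["primaryid"].astype(str)) - demo_ids
        if orphans:
            raise AssertionError(
                f"{name} has primaryids absent from DEMO: {sorted(orphans)[:5]}"
            )


def write_quarter(
    tables: dict[str, RawTable], out_dir: str | Path, truth: GroundTruth | None = None
) -> None:
    """Write the five ASCII files (plus ground truth JSON and the
    synthetic PT->SOC map) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        write_faers_table(table, out / f"{name}.txt")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    write_pt_soc_map(SYNTHETIC_PT_SOC, out / "pt_soc_map.txt")
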