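"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarters ship as ``'$'``-delimited text files with a single header
row and no quoting or escaping.  Field casing of the header varies across
quarters, trailing fields are frequently dropped, and the three date
columns (FDA_DT, EVENT_DT, START_DT) mix full ``YYYYMMDD`` dates with
partial ``YYYYMM`` / ``YYYY`` values and outright garbage.  Everything
dialect-specific lives here so the analysis stages can assume clean,
lower-cased, rectangular tables and a single date type.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER", "OUTC")

#: Minimal column set each table kind must carry to be usable downstream.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "wt",
        "wt_cod",
        "occr_country",
        "occp_cod",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "outc_cod"),
}


class FormatError(ValueError):
    """A file violates the FAERS ASCII dialect or a column contract."""


@dataclass
class RawTable:
    """One FAERS table held as strings, exactly as on disk.

    ``columns`` are lower-cased field names; ``rows`` are lists of string
    values with the empty string standing for a missing value.  Every row
    has exactly ``len(columns)`` values.
    """

    name: str
    columns: list[str]
    rows: list[list[str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.name not in TABLE_KINDS:
            raise FormatError(f"unknown table kind {self.name!r}")
        ncol = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise FormatError(
                    f"{self.name}: row {i} has {len(row)} values, expected {ncol}"
                )

    def to_frame(self) -> pd.DataFrame:
        """View the table as a string-valued DataFrame."""
        return pd.DataFrame(self.rows, columns=self.columns, dtype=object)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "RawTable":
        cols = [str(c).lower() for c in frame.columns]
        rows = frame.astype(str).values.tolist()
        return cls(name=name, columns=cols, rows=rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawTable):
            return NotImplemented
        return (
            self.name == other.name
            and self.columns == other.columns
            and self.rows == other.rows
        )


def read_faers_table(path: str | Path, kind: str) -> RawTable:
    """Read one '$'-delimited FAERS table.

    Header names are lower-cased.  Rows with fewer fields than the header
    are padded with missing values (common in real quarters); rows with
    more fields are a fatal error because the dialect has no quoting and
    the extra fields cannot be attributed to a column.
    """
    kind = kind.upper()
    if kind not in TABLE_KINDS:
        raise FormatError(f"unknown table kind {kind!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    # split strictly on newlines: unlike str.splitlines this never treats
    # other Unicode line boundaries inside field values as record breaks
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]
    if not lines:
        raise FormatError(f"{path}: empty file, no header")
    columns = [c.strip().lower() for c in lines[0].split("$")]
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in columns]
    if missing:
        raise FormatError(
            f"{path}: {kind} table missing required columns: {', '.join(missing)}"
        )
    ncol = len(columns)
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        values = line.split("$")
        if len(values) > ncol:
            raise FormatError(
                f"{path}: line {lineno} has {len(values)} fields, header has {ncol}"
            )
        if len(values) < ncol:
            values = values + [""] * (ncol - len(values))
        rows.append(values)
    return RawTable(name=kind, columns=columns, rows=rows)


def write_faers_table(table: RawTable, path: str | Path) -> None:
    """Write a table in the FAERS '$' dialect.

    The dialect has no quoting, so a value containing ``'$'`` or a line
    break cannot be represented and is rejected outright rather than
    silently corrupting the file.
    """
    table.validate()
    path = Path(path)
    out: list[str] = ["$".join(table.columns)]
    for i, row in enumerate(table.rows):
        for v in row:
            if "$" in v or "\n" in v or "\r" in v:
                raise FormatError(
                    f"{table.name}: row {i} value {v!r} cannot be represented "
                    "in the '$' dialect"
                )
        out.append("$".join(row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Dates


@dataclass(frozen=True)
class FaersDate:
    """A FAERS date string classified by resolution.

    ``resolution`` is ``day`` for an 8-digit string forming a valid
    calendar date, ``month`` for 6 digits, ``year`` for 4 digits and
    ``invalid`` otherwise.  Only day-resolution dates support interval
    arithmetic; partial dates are kept for provenance but are unusable
    for onset computation.
    """

    raw: str
    resolution: str  # day | month | year | invalid
    day_value: _dt.date | None = None

    @property
    def is_day(self) -> bool:
        return self.resolution == "day"

    def sort_key(self) -> tuple[int, int]:
        """Orders day-resolution dates chronologically; anything without a
        full calendar date sorts lowest (never preferred in tie-breaks)."""
        if self.day_value is None:
            return (0, 0)
        return (1, self.day_value.toordinal())


def parse_faers_date(raw: str) -> FaersDate:
    """Classify a raw FAERS date string.  Never raises: unparseable input
    yields ``resolution='invalid'``."""
    s = (raw or "").strip()
    if s.isdigit():
        if len(s) == 8:
            try:
                d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
            except ValueError:
                return FaersDate(raw=raw, resolution="invalid")
            return FaersDate(raw=raw, resolution="day", day_value=d)
        if len(s) == 6:
            return FaersDate(raw=raw, resolution="month")
        if len(s) == 4:
            return FaersDate(raw=raw, resolution="year")
    return FaersDate(raw=raw, resolution="invalid")


# --------------------------------------------------------------------------
# PT -> SOC mapping


def read_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (pt, soc) mapping file.

    MedDRA itself is licensed, so the mapping is always user-supplied.
    Tab, comma and '$' delimiters are accepted; the delimiter is sniffed
    from the first line.  A header row is skipped when the first cell is
    literally ``pt``.  Returns ``{pt: soc}`` with whitespace stripped.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return {}
    delim = "\t"
    for cand in ("\t", "$", ","):
        if cand in lines[0]:
            delim = cand
            break
    mapping: dict[str, str] = {}
    reader = csv.reader(lines, delimiter=delim)
    for i, row in enumerate(reader):
        if len(row) < 2:
            continue
        pt, soc = row[0].strip(), row[1].strip()
        if i == 0 and pt.lower() == "pt":
            continue
        if pt:
            mapping[pt] = soc
    return mapping


def write_pt_soc_map(mapping: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    lines = ["pt\tsoc"] + [f"{pt}\t{soc}" for pt, soc in sorted(mapping.items())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
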