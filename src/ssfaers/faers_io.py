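"""Reading FAERS-dialect quarterly ASCII extracts and building a deduplicated case set.

FAERS quarterly data files are ``$``-delimited text tables with a single
header line.  A quarter consists of DEMO (demographics/administrative),
DRUG, REAC (reactions as MedDRA preferred terms), OUTC (outcome codes) and
THER (therapy dates) tables, plus RPSR/INDI which are read when present but
unused downstream.  Because the same case is re-submitted across quarters as
follow-up versions, analysis starts from one retained version per case:
the version with the latest receipt date (``fda_dt``), ties broken by the
largest numeric ``primaryid``.
"""

from __future__ import annotations

import calendar
import logging
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

logger = logging.getLogger(__name__)

#: tables that must exist in every quarter directory
MANDATORY_TABLES = ("demo", "drug", "reac", "outc", "ther")
#: optional tables preserved verbatim when present
OPTIONAL_TABLES = ("rpsr", "indi")

#: FAERS age-unit codes -> multiplier converting the stored value to years
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: ages above this are treated as recording errors
MAX_PLAUSIBLE_AGE_YEARS = 125.0

#: occupation codes counted as healthcare professionals (MD physician,
#: PH pharmacist, HP other health professional, OT other professional)
HEALTHCARE_OCCUPATIONS = frozenset({"MD", "PH", "HP", "OT"})
#: consumer and lawyer reports
NON_HEALTHCARE_OCCUPATIONS = frozenset({"CN", "LW"})

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: fraction of malformed rows tolerated before the file is rejected
MAX_SKIP_FRACTION = 0.01


@dataclass
class RawQuarter:
    """One quarter's record sets, each a list of header-keyed row dicts."""

    quarter: str
    demo: list[dict[str, str]] = field(default_factory=list)
    drug: list[dict[str, str]] = field(default_factory=list)
    reac: list[dict[str, str]] = field(default_factory=list)
    outc: list[dict[str, str]] = field(default_factory=list)
    ther: list[dict[str, str]] = field(default_factory=list)
    extra: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> list[dict[str, str]]:
        if name in MANDATORY_TABLES:
            return getattr(self, name)
        return self.extra.get(name, [])


@dataclass
class DrugMention:
    """One drug record on a report."""

    raw_name: str
    role: str  # PS | SS | C | I
    therapy_start_date: date | None = None
    drug_sequence: int = 1


@dataclass
class ReportCase:
    """One deduplicated spontaneous report."""

    report_id: str
    case_id: str
    receipt_date: date
    age_years: float | None = None
    sex: str | None = None  # 'female' | 'male' | None
    country: str | None = None
    reporter_class: str | None = None  # 'healthcare' | 'non-healthcare' | None
    outcome_codes: frozenset[str] = frozenset()
    event_date: date | None = None
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)


class FaersIOError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# quarter reading
# ---------------------------------------------------------------------------

def quarter_file_stem(table: str, quarter_label: str) -> str:
    """File stem for a table in a quarter, e.g. ('drug', '2024Q1') -> 'DRUG24Q1'."""
    m = re.fullmatch(r"(\d{4})Q([1-4])", quarter_label)
    if m is None:
        raise ValueError(f"quarter label {quarter_label!r} is not of the form YYYYQn")
    year, q = m.groups()
    return f"{table.upper()}{year[2:]}Q{q}"


def _find_table_file(directory: Path, table: str, quarter_label: str) -> Path | None:
    stem = quarter_file_stem(table, quarter_label)
    for suffix in (".txt", ".TXT", ""):
        candidate = directory / f"{stem}{suffix}"
        if candidate.is_file():
            return candidate
    return None


def _parse_table(path: Path) -> tuple[list[dict[str, str]], int]:
    """Parse one ``$``-delimited file; malformed rows are skipped and counted."""
    rows: list[dict[str, str]] = []
    skipped = 0
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\n\r")
        if not header_line:
            return [], 0
        header = header_line.split("$")
        n_fields = len(header)
        total = 0
        for line in fh:
            line = line.rstrip("\n\r")
            if not line:
                continue
            total += 1
            parts = line.split("$")
            if len(parts) != n_fields:
                skipped += 1
                continue
            rows.append(dict(zip(header, parts)))
    if total and skipped / total > MAX_SKIP_FRACTION:
        raise FaersIOError(
            f"{path.name}: {skipped}/{total} rows malformed "
            f"(> {MAX_SKIP_FRACTION:.0%} tolerated)"
        )
    return rows, skipped


def read_quarter(path: str | Path, quarter_label: str) -> RawQuarter:
    """Read one quarter's ASCII tables from a directory.

    Raises :class:`FaersIOError` if a mandatory table file is missing or a
    file has more than 1% malformed rows.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FaersIOError(f"quarter directory not found: {directory}")
    rq = RawQuarter(quarter=quarter_label)
    for table in MANDATORY_TABLES:
        f = _find_table_file(directory, table, quarter_label)
        if f is None:
            raise FaersIOError(
                f"mandatory file {quarter_file_stem(table, quarter_label)} "
                f"missing from {directory}"
            )
        rows, skipped = _parse_table(f)
        setattr(rq, table, rows)
        rq.skipped[table] = skipped
        logger.info("%s %s: %d rows (%d skipped)", quarter_label, table.upper(), len(rows), skipped)
    for table in OPTIONAL_TABLES:
        f = _find_table_file(directory, table, quarter_label)
        if f is not None:
            rows, skipped = _parse_table(f)
            rq.extra[table] = rows
            rq.skipped[table] = skipped
    return rq


# ---------------------------------------------------------------------------
# date and field parsing
# ---------------------------------------------------------------------------

def parse_date8(value: str | None) -> date | None:
    """Parse a full 8-digit YYYYMMDD date; partial (YYYYMM / YYYY) or invalid -> None."""
    if value is None:
        return None
    value = str(value).strip()
    if not re.fullmatch(r"\d{8}", value):
        return None
    try:
        return date(int(value[:4]), int(value[4:6]), int(value[6:8]))
    except ValueError:
        return None


def quarter_end_date(quarter_label: str) -> date:
    m = re.fullmatch(r"(\d{4})Q([1-4])", quarter_label)
    if m is None:
        raise ValueError(f"bad quarter label {quarter_label!r}")
    year, q = int(m.group(1)), int(m.group(2))
    month = 3 * q
    return date(year, month, calendar.monthrange(year, month)[1])


def parse_age_to_years(age_value, age_unit_code: str | None) -> float | None:
    """Convert a FAERS (age, unit-code) pair to years.

    A missing unit with a value present is treated as years (the dominant
    FAERS unit); negative or implausible (>125 y) results map to missing.
    """
    if age_value is None:
        return None
    try:
        value = float(str(age_value).strip())
    except (TypeError, ValueError):
        return None
    unit = (age_unit_code or "").strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit, 1.0) if unit else 1.0
    if unit and unit not in AGE_UNIT_TO_YEARS:
        factor = 1.0  # unknown unit: assume years
    years = value * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE_YEARS:
        return None
    return years


def parse_sex(code: str | None) -> str | None:
    code = (code or "").strip().upper()
    if code == "F":
        return "female"
    if code == "M":
        return "male"
    return None


def classify_reporter(occupation_code: str | None) -> str | None:
    """Map a FAERS occupation code to 'healthcare' / 'non-healthcare' / None."""
    code = (occupation_code or "").strip().upper()
    if not code:
        return None
    if code in HEALTHCARE_OCCUPATIONS:
        return "healthcare"
    if code in NON_HEALTHCARE_OCCUPATIONS:
        return "non-healthcare"
    return None


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _receipt_date(row: dict[str, str], quarter_label: str) -> date:
    d = parse_date8(row.get("fda_dt"))
    if d is None:
        # partial receipt date falls back to the end of the quarter it appeared in
        d = quarter_end_date(quarter_label)
    return d


def _numeric_id(value: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        return -1


def deduplicate_cases(quarters: list[RawQuarter]) -> list[ReportCase]:
    """Collapse case versions across quarters to one :class:`ReportCase` each.

    For every ``caseid`` the retained version is the DEMO row with the latest
    receipt date, ties broken by the largest numeric ``primaryid``; DRUG /
    REAC / OUTC / THER rows are joined for the retained ``primaryid`` only.
    """
    best: dict[str, tuple[date, int, dict[str, str]]] = {}
    for rq in quarters:
        for row in rq.demo:
            case_id = (row.get("caseid") or "").strip()
            if not case_id:
                continue
            key = (_receipt_date(row, rq.quarter), _numeric_id(row.get("primaryid", "")))
            prev = best.get(case_id)
            if prev is None or key > (prev[0], prev[1]):
                best[case_id] = (key[0], key[1], row)

    retained_pids = {row.get("primaryid", "") for _, _, row in best.values()}
    drug_rows: dict[str, list[dict[str, str]]] = {}
    reac_rows: dict[str, list[dict[str, str]]] = {}
    outc_rows: dict[str, list[dict[str, str]]] = {}
    ther_rows: dict[str, list[dict[str, str]]] = {}
    for rq in quarters:
        for row in rq.drug:
            pid = row.get("primaryid", "")
            if pid in retained_pids:
                drug_rows.setdefault(pid, []).append(row)
        for row in rq.reac:
            pid = row.get("primaryid", "")
            if pid in retained_pids:
                reac_rows.setdefault(pid, []).append(row)
        for row in rq.outc:
            pid = row.get("primaryid", "")
            if pid in retained_pids:
                outc_rows.setdefault(pid, []).append(row)
        for row in rq.ther:
            pid = row.get("primaryid", "")
            if pid in retained_pids:
                ther_rows.setdefault(pid, []).append(row)

    cases: list[ReportCase] = []
    for case_id in sorted(best, key=lambda c: (_numeric_id(c), c)):
        receipt, _, demo = best[case_id]
        pid = demo.get("primaryid", "")
        ther_by_seq: dict[str, list[date]] = {}
        for row in ther_rows.get(pid, []):
            start = parse_date8(row.get("start_dt"))
            if start is not None:
                ther_by_seq.setdefault(str(row.get("dsg_drug_seq", "")).strip(), []).append(start)
        drugs: list[DrugMention] = []
        for row in drug_rows.get(pid, []):
            seq = str(row.get("drug_seq", "")).strip()
            try:
                seq_num = int(seq)
            except ValueError:
                seq_num = 1
            starts = ther_by_seq.get(seq, [])
            drugs.append(
                DrugMention(
                    raw_name=(row.get("drugname") or "").strip(),
                    role=(row.get("role_cod") or "").strip().upper(),
                    therapy_start_date=min(starts) if starts else None,
                    drug_sequence=seq_num,
                )
            )
        outcomes = frozenset(
            code
            for row in outc_rows.get(pid, [])
            if (code := (row.get("outc_cod") or "").strip().upper()) in OUTCOME_CODES
        )
        reactions = [
            pt for row in reac_rows.get(pid, []) if (pt := (row.get("pt") or "").strip())
        ]
        cases.append(
            ReportCase(
                report_id=pid,
                case_id=case_id,
                receipt_date=receipt,
                age_years=parse_age_to_years(demo.get("age"), demo.get("age_cod")),
                sex=parse_sex(demo.get("sex")),
                country=(demo.get("reporter_country") or "").strip() or None,
                reporter_class=classify_reporter(demo.get("occp_cod")),
                outcome_codes=outcomes,
                event_date=parse_date8(demo.get("event_dt")),
                drugs=drugs,
                reactions=reactions,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def select_cohort(
    cases: list[ReportCase],
    target_pt: str,
    age_threshold: float = 65.0,
    background_scope: str = "elderly",
) -> tuple[list[ReportCase], list[ReportCase]]:
    """Split deduplicated cases into (cohort, background).

    With ``background_scope='elderly'`` (default, matching the elderly study
    frame) the background is every case aged >= ``age_threshold`` years
    (inclusive); with ``'all'`` it is every deduplicated case.  The cohort is
    always the elderly cases whose reactions contain ``target_pt``
    (case-insensitive exact preferred-term match), so cohort ⊆ background.
    """
    pt_key = target_pt.strip().casefold()
    elderly = [c for c in cases if c.age_years is not None and c.age_years >= age_threshold]
    if not elderly:
        raise FaersIOError("no elderly reports")
    if background_scope == "elderly":
        background = elderly
    elif background_scope == "all":
        background = list(cases)
    else:
        raise ValueError(f"unknown background_scope {background_scope!r}")
    cohort = [
        c for c in elderly if any(r.strip().casefold() == pt_key for r in c.reactions)
    ]
    return cohort, background
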