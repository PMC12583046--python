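"""Cohort characterization (Table 1-style descriptive summaries).

Summarizes the serotonin-syndrome cohort by sex, age band, top-10 reporting
countries, mutually exclusive worst-outcome class, reporter type and receipt
year.  Percentages are computed against the full cohort size and rounded
half-up to one decimal, matching how such tables are conventionally printed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .faers_io import ReportCase
from .tto import age_band

#: precedence for collapsing outcome codes to one mutually exclusive class
#: (worst outcome wins; CA/RI and empty fall into Other)
OUTCOME_PRECEDENCE = (
    ("DE", "Death"),
    ("LT", "Life-Threatening"),
    ("HO", "Hospitalization"),
    ("DS", "Disability"),
)
OUTCOME_OTHER = "Other"

TOP_COUNTRIES = 10
MISSING = "Missing"


def map_outcome(outcome_codes, precedence=OUTCOME_PRECEDENCE) -> str:
    """Collapse a report's outcome-code set to its single worst class."""
    codes = {str(c).strip().upper() for c in outcome_codes}
    for code, label in precedence:
        if code in codes:
            return label
    return OUTCOME_OTHER


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in such tables."""
    if total == 0:
        raise ValueError("empty denominator")
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class CohortSummary:
    """Per-characteristic category -> (count, percent) maps."""

    n: int
    sex: dict[str, tuple[int, float]] = field(default_factory=dict)
    age_band: dict[str, tuple[int, float]] = field(default_factory=dict)
    country: dict[str, tuple[int, float]] = field(default_factory=dict)
    outcome: dict[str, tuple[int, float]] = field(default_factory=dict)
    reporter: dict[str, tuple[int, float]] = field(default_factory=dict)
    year: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for characteristic in ("sex", "age_band", "country", "outcome", "reporter", "year"):
            for category, (count, pct) in getattr(self, characteristic).items():
                rows.append(
                    {
                        "characteristic": characteristic,
                        "category": category,
                        "count": count,
                        "percent": pct,
                    }
                )
        return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def _with_percent(counter: Counter, total: int) -> dict[str, tuple[int, float]]:
    return {k: (v, percent(v, total)) for k, v in counter.items()}


def summarize_cohort(cohort: list[ReportCase]) -> CohortSummary:
    """Build the descriptive summary of a nonempty cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)

    sex_labels = {"female": "Female", "male": "Male", None: MISSING}
    sex = Counter(sex_labels[c.sex] for c in cohort)
    bands = Counter(age_band(c.age_years) or MISSING for c in cohort)
    country = Counter((c.country or MISSING) for c in cohort)
    outcome = Counter(map_outcome(c.outcome_codes) for c in cohort)
    reporter_labels = {
        "healthcare": "Healthcare professionals",
        "non-healthcare": "Non-healthcare professionals",
        None: MISSING,
    }
    reporter = Counter(reporter_labels[c.reporter_class] for c in cohort)
    year = Counter(str(c.receipt_date.year) for c in cohort)

    summary = CohortSummary(n=n)
    summary.sex = _with_percent(
        Counter({k: sex[k] for k in ("Female", "Male", MISSING) if k in sex}), n
    )
    band_order = ["65-74", "75-84", "85-94", ">=95", MISSING]
    summary.age_band = _with_percent(
        Counter({k: bands[k] for k in band_order if k in bands}), n
    )
    top = Counter(dict(country.most_common())).most_common(TOP_COUNTRIES)
    summary.country = _with_percent(Counter(dict(top)), n)
    outcome_order = ["Death", "Disability", "Hospitalization", "Life-Threatening", OUTCOME_OTHER]
    summary.outcome = _with_percent(
        Counter({k: outcome[k] for k in outcome_order if k in outcome}), n
    )
    summary.reporter = _with_percent(reporter, n)
    summary.year = _with_percent(Counter(dict(sorted(year.items()))), n)
    return summary
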