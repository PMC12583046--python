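"""Time-to-onset (TTO) analysis.

TTO is the interval in days between therapy start (START_DT of the
primary-suspect drug, earliest record when several exist) and adverse-event
onset (EVENT_DT).  Same-day onset is recorded as 0.5 days so that classes
whose events cluster on day 0 carry a positive median; negative intervals
and partial/missing dates are excluded with a reason code.  Onset
distributions are heavily skewed, so groups are summarized by quartiles
(linear interpolation on (n−1) positions) and compared with rank tests:
Mann-Whitney for two groups, Kruskal-Wallis plus Benjamini-Hochberg-adjusted
pairwise Mann-Whitney for more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .faers_io import ReportCase

SAME_DAY_TTO = 0.5  # convention for day-0 onsets
EXACT_ENUMERATION_MAX_N = 10

AGE_BANDS = (("65-74", 65, 75), ("75-84", 75, 85), ("85-94", 85, 95), (">=95", 95, math.inf))


def age_band(age_years: float | None) -> str | None:
    if age_years is None:
        return None
    for name, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return name
    return None


@dataclass
class TTORecord:
    report_id: str
    drug: str
    atc_class: str
    sex: str | None
    age_band: str | None
    tto_days: float


@dataclass
class TTOSummary:
    group: str
    n: int
    q1: float
    median: float
    q3: float


def compute_tto(event_date: date | None, start_date: date | None):
    """Onset interval in days, or an exclusion.

    Returns ``(tto_days, None)`` for usable intervals and ``(None, reason)``
    otherwise; reasons are ``'missing'`` (either date absent/partial) and
    ``'negative'`` (event before therapy start).
    """
    if event_date is None or start_date is None:
        return None, "missing"
    delta = (event_date - start_date).days
    if delta < 0:
        return None, "negative"
    return (SAME_DAY_TTO if delta == 0 else float(delta)), None


def build_tto_records(
    cohort: list[ReportCase],
    name_of=lambda raw: raw,
    atc_of=lambda generic: "unclassified",
) -> tuple[list[TTORecord], dict[str, int]]:
    """One record per cohort report per primary-suspect drug.

    The earliest therapy start among the report's records for that drug is
    used.  Returns the records plus exclusion counts by reason.
    """
    records: list[TTORecord] = []
    exclusions: dict[str, int] = {"missing": 0, "negative": 0}
    for case in cohort:
        starts: dict[str, date] = {}
        for m in case.drugs:
            if m.role != "PS":
                continue
            generic = name_of(m.raw_name)
            if m.therapy_start_date is not None:
                prev = starts.get(generic)
                if prev is None or m.therapy_start_date < prev:
                    starts[generic] = m.therapy_start_date
            else:
                starts.setdefault(generic, None)
        for generic, start in starts.items():
            tto, reason = compute_tto(case.event_date, start)
            if tto is None:
                exclusions[reason] += 1
                continue
            records.append(
                TTORecord(
                    report_id=case.report_id,
                    drug=generic,
                    atc_class=atc_of(generic),
                    sex=case.sex,
                    age_band=age_band(case.age_years),
                    tto_days=tto,
                )
            )
    return records, exclusions


def _group_values(records: list[TTORecord], group_by: str | None) -> dict[str, np.ndarray]:
    if group_by is None:
        return {"overall": np.array([r.tto_days for r in records], dtype=float)}
    groups: dict[str, list[float]] = {}
    for r in records:
        key = getattr(r, group_by)
        if key is None:
            continue
        groups.setdefault(str(key), []).append(r.tto_days)
    return {k: np.array(v, dtype=float) for k, v in sorted(groups.items())}


def summarize_tto(records: list[TTORecord], group_by: str | None = None) -> list[TTOSummary]:
    """Quartile summaries per group; groups with fewer than 2 values are dropped."""
    out = []
    for key, values in _group_values(records, group_by).items():
        if len(values) < 2:
            continue
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
        out.append(TTOSummary(group=key, n=len(values), q1=float(q1), median=float(med), q3=float(q3)))
    return out


def ecdf_points(records: list[TTORecord], group_by: str | None = None) -> pd.DataFrame:
    """Per-group empirical CDF step points (t, fraction <= t); ends at 1."""
    rows = []
    for key, values in _group_values(records, group_by).items():
        if len(values) == 0:
            continue
        ts, counts = np.unique(values, return_counts=True)
        fractions = np.cumsum(counts) / len(values)
        for t, f in zip(ts, fractions):
            rows.append({"group": key, "t": float(t), "fraction": float(f)})
    return pd.DataFrame(rows, columns=["group", "t", "fraction"])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (midrank ties): rank-sum form."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) with a two-sided p-value.

    With ``method='auto'``, combined sample sizes up to 10 use exhaustive
    enumeration of all group assignments of the combined multiset (counting
    splits at least as extreme in |U − n1·n2/2|); larger samples use the
    tie-corrected normal approximation with continuity correction.  The
    choice can be forced with ``'exact'`` or ``'asymptotic'``.  Completely
    tied data yield U = n1·n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    combined = np.concatenate([x, y])
    if len(np.unique(combined)) == 1:
        return mu, 1.0

    if method == "exact" or (method == "auto" and n1 + n2 <= EXACT_ENUMERATION_MAX_N):
        d_obs = abs(u - mu)
        count = total = 0
        idx = range(n1 + n2)
        for subset in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(subset)] = True
            u_perm = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if abs(u_perm - mu) >= d_obs - 1e-12:
                count += 1
        return u, count / total

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, p


def kruskal_wallis_pairwise(groups: dict[str, np.ndarray]):
    """Kruskal-Wallis H over >= 2 groups plus BH-adjusted pairwise Mann-Whitney.

    Returns ``(H, p, pairwise)`` where ``pairwise`` is a DataFrame with one
    row per group pair (comparison, U, p, p_adj).
    """
    eligible = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    if len(eligible) < 2:
        raise ValueError("need at least two groups with n >= 2")
    samples = list(eligible.values())
    if len(np.unique(np.concatenate(samples))) == 1:
        h, p = 0.0, 1.0  # no separation; scipy rejects all-identical input
    else:
        h, p = stats.kruskal(*samples)
    rows = []
    for (ka, va), (kb, vb) in combinations(eligible.items(), 2):
        u, pu = mann_whitney_u(va, vb)
        rows.append({"comparison": f"{ka} vs {kb}", "U": u, "p": pu})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return float(h), float(p), pairwise
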