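"""Disproportionality signal detection for drug–event pairs.

For each drug, reports in the background population are cross-classified
against the target preferred term into a 2×2 table

    =============  ==========  ==========
    .              target PT   other PTs
    drug (PS)      a           b
    other drugs    c           d
    =============  ==========  ==========

and four standard measures of reporting disproportionality are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with the Woolf (log-normal) 95%
  interval; a Haldane–Anscombe 0.5 correction is applied when any cell is 0.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square statistic (no Yates correction).
* **IC** — the BCPNN information component ``log2((a+0.5)/(E+0.5))`` where
  ``E=(a+b)(a+c)/N`` is the expected count under independence, with the
  gamma-approximation lower credible bound
  ``IC025 = IC − 3.3(a+0.5)^{−1/2} − 2.0(a+0.5)^{−3/2}``.
* **EBGM** — the empirical-Bayes geometric mean of the reporting-rate ratio
  under DuMouchel's two-component gamma-mixture prior (gamma–Poisson
  shrinker), with the posterior 5th percentile EB05.

A drug is a signal when all of: ROR025 > 1, PRR ≥ 2, χ² ≥ 4, IC025 > 0 and
a ≥ 3 (strict mode additionally requires EB05 > 2).  Volcano-plot statistics
use the two-sided Fisher exact p-value (sum-of-smaller-probabilities
convention) with Bonferroni correction over the evaluable drugs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, logsumexp

from .faers_io import ReportCase

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyTable:
    """2×2 drug × event counts over the background population."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the expected count under independence."""
        if self.n == 0:
            return float("nan")
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def rr(self) -> float:
        """Observed/expected rate ratio a/E."""
        e = self.expected
        return self.a / e if e and e > 0 else float("nan")

    @property
    def evaluable(self) -> bool:
        return (self.a + self.b) > 0


@dataclass
class GpsPrior:
    """Two-component gamma mixture prior for the gamma-Poisson shrinker.

    Component i is Gamma(shape=alpha_i, rate=beta_i); w is the weight of
    component 1.  The classic default (0.2, 0.1, 2.0, 4.0, w=1/3) mixes a
    diffuse component with one concentrated near rate ratio 0.5.
    """

    w: float = 1.0 / 3.0
    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("mixture weight must lie in [0, 1]")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")


DEFAULT_GPS_PRIOR = GpsPrior()


@dataclass
class SignalMetrics:
    drug: str = ""
    a: int = 0
    ror: float = float("nan")
    ror_lo: float = float("nan")
    ror_hi: float = float("nan")
    ror_corrected: bool = False
    prr: float = float("nan")
    chi2: float = float("nan")
    ic: float = float("nan")
    ic_lo: float = float("nan")
    ebgm: float = float("nan")
    eb05: float = float("nan")
    fisher_p: float = float("nan")
    p_adj: float = float("nan")
    is_signal: bool = False


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def report_ps_drugs(case: ReportCase, name_of) -> set[str]:
    """Normalized primary-suspect drug names on one report (counted once each)."""
    return {name_of(m.raw_name) for m in case.drugs if m.role == "PS"}


def build_contingency(
    cohort: list[ReportCase],
    background: list[ReportCase],
    drug: str,
    target_pt: str | None = None,
    name_of=lambda raw: raw,
) -> ContingencyTable:
    """Count the 2×2 table for one normalized drug over the background.

    Event-positivity is cohort membership by default (which carries any
    age/reporter restriction the cohort was built with); passing
    ``target_pt`` instead matches the preferred term directly on each
    background report's reactions.  ``name_of`` maps a raw drug-name string
    to its normalized generic name; a report mentioning the drug several
    times counts once.
    """
    cohort_ids = {c.report_id for c in cohort}
    pt_key = target_pt.strip().casefold() if target_pt else None
    a = b = c_ = d = 0
    for case in background:
        has_drug = drug in report_ps_drugs(case, name_of)
        if pt_key is not None:
            has_pt = any(r.strip().casefold() == pt_key for r in case.reactions)
        else:
            has_pt = case.report_id in cohort_ids
        if has_drug and has_pt:
            a += 1
        elif has_drug:
            b += 1
        elif has_pt:
            c_ += 1
        else:
            d += 1
    table = ContingencyTable(a=a, b=b, c=c_, d=d, drug=drug)
    if not table.evaluable:
        logger.warning("drug %r absent from background: non-evaluable table", drug)
    return table


def contingency_tables(
    cohort: list[ReportCase],
    background: list[ReportCase],
    drugs: list[str],
    name_of=lambda raw: raw,
) -> list[ContingencyTable]:
    """2×2 tables for many drugs in one pass over the background.

    Equivalent to calling :func:`build_contingency` per drug (event-positive
    means cohort membership) but normalizes each report's drug names once.
    """
    cohort_ids = {c.report_id for c in cohort}
    a_counts: dict[str, int] = {d: 0 for d in drugs}
    b_counts: dict[str, int] = {d: 0 for d in drugs}
    n_total = len(background)
    n_pt = 0
    for case in background:
        has_pt = case.report_id in cohort_ids
        if has_pt:
            n_pt += 1
        for drug in report_ps_drugs(case, name_of):
            if drug not in a_counts:
                continue
            if has_pt:
                a_counts[drug] += 1
            else:
                b_counts[drug] += 1
    tables = []
    for drug in drugs:
        a, b = a_counts[drug], b_counts[drug]
        c = n_pt - a
        d = n_total - a - b - c
        tables.append(ContingencyTable(a=a, b=b, c=c, d=d, drug=drug))
    return tables


# ---------------------------------------------------------------------------
# frequentist measures
# ---------------------------------------------------------------------------

def compute_ror(t: ContingencyTable) -> tuple[float, float, float, bool]:
    """ROR with the Woolf 95% interval.

    Returns (ror, lower, upper, corrected).  If any cell is zero the
    Haldane–Anscombe correction adds 0.5 to all four cells first; a = 0
    yields missing values (such a pair cannot signal, as a ≥ 3 is required).
    """
    if t.a == 0:
        return float("nan"), float("nan"), float("nan"), False
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z_95 * se)
    hi = math.exp(math.log(ror) + Z_95 * se)
    return ror, lo, hi, corrected


def compute_prr_chi2(t: ContingencyTable) -> tuple[float, float]:
    """PRR and the Pearson chi-square statistic (no continuity correction)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if (a + b) == 0 or (c + d) == 0 or c == 0:
        return float("nan"), float("nan")
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / denom if denom > 0 else float("nan")
    return prr, chi2


def compute_ic(t: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its lower 95% credible bound."""
    e = t.expected
    if not (e > 0):
        return float("nan"), float("nan")
    a_off = t.a + 0.5
    ic = math.log2(a_off / (e + 0.5))
    ic_lo = ic - 3.3 * a_off ** -0.5 - 2.0 * a_off ** -1.5
    return ic, ic_lo


# ---------------------------------------------------------------------------
# gamma-Poisson shrinker (MGPS)
# ---------------------------------------------------------------------------

def _posterior_mixture(a: int, e: float, prior: GpsPrior):
    """Posterior of the rate ratio λ given a ~ Poisson(λE): weight and two gammas.

    Component i updates to Gamma(alpha_i + a, beta_i + E); the posterior
    weight of component 1 follows from the negative-binomial marginals of a.
    """
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    if prior.w == 1.0:
        q = 1.0
    elif prior.w == 0.0:
        q = 0.0
    else:
        logm1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
        logm2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
        log_num = math.log(prior.w) + logm1
        log_den = logsumexp([log_num, math.log1p(-prior.w) + logm2])
        q = math.exp(log_num - log_den)
    return q, shapes, rates


def compute_ebgm(
    t: ContingencyTable, prior: GpsPrior = DEFAULT_GPS_PRIOR
) -> tuple[float, float]:
    """EBGM (posterior geometric mean of λ) and EB05 (posterior 5th percentile).

    EBGM uses the digamma closed form for each component's mean log; EB05 is
    found by bisection on the posterior-mixture CDF to relative tolerance
    1e-8.
    """
    e = t.expected
    if not (e > 0):
        return float("nan"), float("nan")
    a = t.a
    q, shapes, rates = _posterior_mixture(a, e, prior)
    weights = np.array([q, 1.0 - q])
    mean_log = float(np.dot(weights, digamma(shapes) - np.log(rates)))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return float(np.dot(weights, stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    # bracket the 5th percentile between the component percentiles
    p05 = stats.gamma.ppf(0.05, shapes, scale=1.0 / rates)
    lo, hi = 0.5 * float(np.min(p05)), 2.0 * float(np.max(p05))
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < 0.05:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-8 * hi:
            break
    else:
        raise RuntimeError(f"EB05 bisection failed for table {t}")
    eb05 = 0.5 * (lo + hi)
    return ebgm, eb05


def _gps_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Negative summed log marginal likelihood of the two-gamma mixture."""
    la1, lb1, la2, lb2, logit_w = theta
    alpha1, beta1 = math.exp(la1), math.exp(lb1)
    alpha2, beta2 = math.exp(la2), math.exp(lb2)
    w = 1.0 / (1.0 + math.exp(-logit_w))
    with np.errstate(divide="ignore"):
        l1 = stats.nbinom.logpmf(a, alpha1, beta1 / (beta1 + e))
        l2 = stats.nbinom.logpmf(a, alpha2, beta2 / (beta2 + e))
    stacked = np.stack([l1 + math.log(w), l2 + math.log1p(-w)])
    ll = logsumexp(stacked, axis=0).sum()
    return -ll if np.isfinite(ll) else 1e12


#: documented multi-start points for the prior fit (alpha1, beta1, alpha2, beta2, w)
GPS_FIT_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),   # classic default prior
    (1.0, 1.0, 1.0, 1.0, 0.5),         # symmetric unit prior
    (0.5, 0.5, 5.0, 5.0, 0.2),         # diffuse + concentrated-at-1
    (0.1, 0.05, 1.0, 2.0, 0.5),        # heavier tail
    (2.0, 1.0, 0.3, 0.3, 0.7),         # components swapped
)

MIN_TABLES_FOR_FIT = 50


def marginal_loglik(prior: GpsPrior, tables: list[ContingencyTable]) -> float:
    """Summed log marginal likelihood of observed counts under a prior."""
    a = np.array([t.a for t in tables if t.expected > 0])
    e = np.array([t.expected for t in tables if t.expected > 0])
    theta = np.array([
        math.log(prior.alpha1), math.log(prior.beta1),
        math.log(prior.alpha2), math.log(prior.beta2),
        math.log(prior.w / (1 - prior.w)) if 0 < prior.w < 1 else (50.0 if prior.w == 1 else -50.0),
    ])
    return -_gps_nll(theta, a, e)


def fit_gps_prior(tables: list[ContingencyTable]) -> GpsPrior:
    """Fit the mixture prior by maximum marginal likelihood over drug tables.

    Multi-start bounded L-BFGS-B on log-transformed gamma parameters and a
    logit-transformed weight; falls back to the default prior with a warning
    when optimization fails or the data are degenerate (all a = 0).
    """
    usable = [t for t in tables if t.expected > 0]
    if len(usable) < MIN_TABLES_FOR_FIT:
        raise ValueError(
            f"need at least {MIN_TABLES_FOR_FIT} tables with E > 0 to fit the prior "
            f"(got {len(usable)}); use the default prior instead"
        )
    a = np.array([t.a for t in usable], dtype=float)
    e = np.array([t.expected for t in usable], dtype=float)
    if a.max() == 0:
        logger.warning("all observed counts are zero: degenerate fit, using default prior")
        return DEFAULT_GPS_PRIOR

    bounds = [(-7, 7)] * 4 + [(-10, 10)]
    best = None
    for start in GPS_FIT_STARTS:
        a1, b1, a2, b2, w = start
        theta0 = np.array([
            math.log(a1), math.log(b1), math.log(a2), math.log(b2),
            math.log(w / (1 - w)),
        ])
        try:
            res = optimize.minimize(
                _gps_nll, theta0, args=(a, e), method="L-BFGS-B", bounds=bounds
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        logger.warning("gamma-mixture prior fit failed; using default prior")
        return DEFAULT_GPS_PRIOR
    la1, lb1, la2, lb2, logit_w = best.x
    return GpsPrior(
        w=1.0 / (1.0 + math.exp(-logit_w)),
        alpha1=math.exp(la1),
        beta1=math.exp(lb1),
        alpha2=math.exp(la2),
        beta2=math.exp(lb2),
    )


# ---------------------------------------------------------------------------
# signal rule and volcano statistics
# ---------------------------------------------------------------------------

@dataclass
class SignalCriteria:
    """Thresholds of the combined signal rule (conjunction of all)."""

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic_lo_gt: float = 0.0
    strict_ebgm: bool = False  # additionally require EB05 > 2
    eb05_gt: float = 2.0


def evaluate_signal(m: SignalMetrics, criteria: SignalCriteria = SignalCriteria()) -> bool:
    """Apply the combined rule; any missing metric fails the drug."""
    checks = [
        m.a >= criteria.min_a,
        m.ror_lo > criteria.ror_lo_gt,
        m.prr >= criteria.prr_ge,
        m.chi2 >= criteria.chi2_ge,
        m.ic_lo > criteria.ic_lo_gt,
    ]
    if criteria.strict_ebgm:
        checks.append(m.eb05 > criteria.eb05_gt)
    # NaN comparisons are False, so missing metrics fail automatically
    return all(bool(c) for c in checks)


def volcano_stats(tables: list[ContingencyTable]) -> pd.DataFrame:
    """Two-sided Fisher exact p, Bonferroni-adjusted p and log-ROR per drug.

    Bonferroni multiplicity m = number of evaluable drugs in the run.
    """
    evaluable = [t for t in tables if t.evaluable]
    if not evaluable:
        raise ValueError("no evaluable tables for volcano statistics")
    m = len(evaluable)
    rows = []
    for t in evaluable:
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        ror, *_ = compute_ror(t)
        rows.append(
            {
                "drug": t.drug,
                "fisher_p": float(p),
                "p_adj": min(1.0, m * float(p)),
                "log_ror": math.log(ror) if ror > 0 else float("nan"),
                "n_reports": t.a,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-run orchestration
# ---------------------------------------------------------------------------

def compute_metrics(
    t: ContingencyTable,
    prior: GpsPrior = DEFAULT_GPS_PRIOR,
    criteria: SignalCriteria = SignalCriteria(),
) -> SignalMetrics:
    """All four algorithms plus the combined verdict for one table."""
    ror, lo, hi, corrected = compute_ror(t)
    prr, chi2 = compute_prr_chi2(t)
    ic, ic_lo = compute_ic(t)
    ebgm, eb05 = compute_ebgm(t, prior)
    m = SignalMetrics(
        drug=t.drug, a=t.a,
        ror=ror, ror_lo=lo, ror_hi=hi, ror_corrected=corrected,
        prr=prr, chi2=chi2, ic=ic, ic_lo=ic_lo, ebgm=ebgm, eb05=eb05,
    )
    m.is_signal = evaluate_signal(m, criteria)
    return m


def signal_table(
    tables: list[ContingencyTable],
    prior: GpsPrior = DEFAULT_GPS_PRIOR,
    criteria: SignalCriteria = SignalCriteria(),
    atc_of=None,
) -> pd.DataFrame:
    """Per-drug signal metrics table (one row per evaluable drug)."""
    evaluable = [t for t in tables if t.evaluable]
    volcano = volcano_stats(evaluable).set_index("drug") if evaluable else None
    rows = []
    for t in evaluable:
        m = compute_metrics(t, prior, criteria)
        row = {
            "drug": t.drug,
            "atc_class": atc_of(t.drug) if atc_of else "",
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": m.ror, "ror_lo": m.ror_lo, "ror_hi": m.ror_hi,
            "prr": m.prr, "chi2": m.chi2, "ic": m.ic, "ic_lo": m.ic_lo,
            "ebgm": m.ebgm, "eb05": m.eb05,
            "fisher_p": volcano.loc[t.drug, "fisher_p"],
            "p_adj": volcano.loc[t.drug, "p_adj"],
            "is_signal": m.is_signal,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("drug").reset_index(drop=True)
    return df
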