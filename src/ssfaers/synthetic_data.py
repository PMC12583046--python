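"""Synthetic FAERS-style data with known ground truth.

The generator emits quarterly ``$``-delimited DEMO/DRUG/REAC/OUTC/THER files
that exercise every stage of the pipeline: demographics drawn from mixtures
matching a large published elderly serotonin-syndrome case series (sex,
age-band, country, reporter-type and outcome proportions), trade/generic
name variants, duplicate case versions across quarters, partial and missing
dates, and — the part that makes recovery testable — per-drug planted
reporting-rate ratios (λ) for the target preferred term and ATC-class-
specific log-normal onset-time distributions.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream consumed in a fixed order (quarter by
quarter, report by report), so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import calendar
import math
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import yaml

from .faers_io import RawQuarter, quarter_file_stem

# ---------------------------------------------------------------------------
# drug roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugSpec:
    generic: str
    atc: str
    trades: tuple[str, ...] = ()
    lam: float = 1.0  # reporting-rate ratio for the target PT


#: class-specific onset-time distributions: ATC letter -> (median days, log-sd).
#: Log-normal medians follow the published per-class medians (nervous system
#: 16.5 d with a long tail, antiinfectives 1.5 d, alimentary 1.5 d,
#: musculo-skeletal 2.5 d, dermatologicals / various same-day).
ONSET_BY_CLASS = {
    "N": (16.5, 1.8),
    "J": (1.5, 1.2),
    "A": (1.5, 1.0),
    "M": (2.5, 0.1),
    "D": (0.5, 0.5),
    "V": (0.5, 0.5),
    "R": (13.5, 1.5),
}

#: drugs planted as true signals in the default roster
DEFAULT_SIGNAL_LAMBDA = 10.0
DEFAULT_SIGNAL_DRUGS = ("fluoxetine", "sertraline", "venlafaxine", "tramadol", "linezolid")


def _roster() -> tuple[DrugSpec, ...]:
    n = [  # nervous system
        ("fluoxetine", ("PROZAC",)), ("sertraline", ("ZOLOFT",)),
        ("paroxetine", ("PAXIL",)), ("citalopram", ("CELEXA",)),
        ("escitalopram", ("LEXAPRO",)), ("venlafaxine", ("EFFEXOR",)),
        ("duloxetine", ("CYMBALTA",)), ("mirtazapine", ("REMERON",)),
        ("trazodone", ("DESYREL",)), ("bupropion", ("WELLBUTRIN",)),
        ("amitriptyline", ("ELAVIL",)), ("nortriptyline", ("PAMELOR",)),
        ("clomipramine", ("ANAFRANIL",)), ("phenelzine", ("NARDIL",)),
        ("selegiline", ("EMSAM",)), ("tramadol", ("ULTRAM",)),
        ("fentanyl", ("DURAGESIC",)), ("oxycodone", ("OXYCONTIN",)),
        ("methadone", ("DOLOPHINE",)), ("buspirone", ("BUSPAR",)),
        ("lithium", ("ESKALITH",)), ("quetiapine", ("SEROQUEL",)),
        ("risperidone", ("RISPERDAL",)), ("olanzapine", ("ZYPREXA",)),
        ("aripiprazole", ("ABILIFY",)), ("lamotrigine", ("LAMICTAL",)),
        ("lacosamide", ("VIMPAT",)), ("gabapentin", ("NEURONTIN",)),
        ("pregabalin", ("LYRICA",)), ("sumatriptan", ("IMITREX",)),
    ]
    j = [
        ("linezolid", ("ZYVOX",)), ("ciprofloxacin", ("CIPRO",)),
        ("fluconazole", ("DIFLUCAN",)), ("azithromycin", ("ZITHROMAX",)),
        ("isoniazid", ()), ("metronidazole", ("FLAGYL",)),
    ]
    a = [
        ("metoclopramide", ("REGLAN",)), ("ondansetron", ("ZOFRAN",)),
        ("granisetron", ("KYTRIL",)), ("omeprazole", ("PRILOSEC",)),
        ("loperamide", ("IMODIUM",)), ("sitagliptin", ("JANUVIA",)),
    ]
    m = [
        ("cyclobenzaprine", ("FLEXERIL",)), ("methocarbamol", ("ROBAXIN",)),
        ("celecoxib", ("CELEBREX",)),
    ]
    d = [("isotretinoin", ("ACCUTANE",)), ("calcipotriol", ("DOVONEX",))]
    v = [("methylthioninium chloride", ("METHYLENE BLUE",)), ("iohexol", ("OMNIPAQUE",))]
    r = [("dextromethorphan", ("DELSYM",))]

    roster = []
    for letter, drugs in (("N", n), ("J", j), ("A", a), ("M", m), ("D", d), ("V", v), ("R", r)):
        for generic, trades in drugs:
            lam = DEFAULT_SIGNAL_LAMBDA if generic in DEFAULT_SIGNAL_DRUGS else 1.0
            roster.append(DrugSpec(generic=generic, atc=letter, trades=trades, lam=lam))
    return tuple(roster)


DEFAULT_ROSTER = _roster()

#: background MedDRA preferred terms used as filler reactions
BACKGROUND_PTS = (
    "Nausea", "Dizziness", "Fall", "Tremor", "Confusional state", "Vomiting",
    "Fatigue", "Headache", "Hypotension", "Diarrhoea", "Rash", "Insomnia",
    "Somnolence", "Hyponatraemia", "Tachycardia",
)

TARGET_PT = "Serotonin syndrome"

# Table 1-style demographic mixtures.  The elderly-band proportions are the
# published 60.7 / 29.3 / 8.6 / 1.4 split scaled by the elderly fraction.
DEFAULT_AGE_BANDS = {
    # band: (low, high, probability)
    "18-64": (18, 64, 0.25),
    "65-74": (65, 74, 0.455250),
    "75-84": (75, 84, 0.219750),
    "85-94": (85, 94, 0.064500),
    "95-105": (95, 105, 0.010500),
}
DEFAULT_SEX_PROBS = {"F": 0.615, "M": 0.376, "": 0.009}
DEFAULT_COUNTRY_WEIGHTS = {
    "US": 0.344, "ES": 0.090, "GB": 0.080, "FR": 0.050, "JP": 0.045,
    "CA": 0.034, "IT": 0.026, "DE": 0.020, "NL": 0.020, "PT": 0.017,
    # long tail of small-count countries, each below the top-10 cutoff
    **{c: 0.274 / 20 for c in (
        "AU", "BR", "CN", "IN", "SE", "CH", "BE", "DK", "NO", "FI",
        "IE", "AT", "PL", "GR", "CZ", "HU", "MX", "AR", "KR", "ZA",
    )},
}
DEFAULT_OCCUPATION_PROBS = {"MD": 0.45, "PH": 0.25, "HP": 0.10, "OT": 0.042, "CN": 0.099, "": 0.059}
DEFAULT_OUTCOME_PROBS = {"DE": 0.074, "DS": 0.007, "HO": 0.464, "LT": 0.184, "OTHER": 0.271}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_reports_per_quarter: int = 2500
    quarters: tuple[str, ...] = ("2024Q1", "2024Q2", "2024Q3", "2024Q4")
    roster: tuple[DrugSpec, ...] = DEFAULT_ROSTER
    base_rate: float = 0.02        # P(target PT | λ = 1 drug)
    duplicate_rate: float = 0.05   # fraction of cases re-emitted as a later version
    trade_name_rate: float = 0.30  # fraction of drug mentions using a trade name
    salt_suffix_rate: float = 0.10 # fraction of generic mentions carrying ' HCL'
    date_missing_rate: float = 0.20   # event / therapy-start date missingness
    negative_tto_rate: float = 0.02   # planted data-entry errors (event < start)
    age_missing_rate: float = 0.02
    age_bands: dict = field(default_factory=lambda: dict(DEFAULT_AGE_BANDS))
    sex_probs: dict = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    country_weights: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    occupation_probs: dict = field(default_factory=lambda: dict(DEFAULT_OCCUPATION_PROBS))
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    signal_lambda_threshold: float = 2.0  # λ at or above this marks a true signal
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (
            ("age_bands", {k: v[2] for k, v in self.age_bands.items()}),
            ("sex_probs", self.sex_probs),
            ("country_weights", self.country_weights),
            ("occupation_probs", self.occupation_probs),
            ("outcome_probs", self.outcome_probs),
        ):
            values = list(probs.values())
            if any(p < 0 or p > 1 for p in values) or not math.isclose(sum(values), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} probabilities must lie in [0,1] and sum to 1")
        if any(spec.lam <= 0 for spec in self.roster):
            raise ValueError("planted rate ratios must be positive")
        if not 0 <= self.base_rate <= 1:
            raise ValueError("base_rate must be a probability")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "roster" in raw:
            raw["roster"] = tuple(
                DrugSpec(
                    generic=d["generic"],
                    atc=d["atc"],
                    trades=tuple(d.get("trades", ())),
                    lam=float(d.get("lam", 1.0)),
                )
                for d in raw["roster"]
            )
        if "quarters" in raw:
            raw["quarters"] = tuple(raw["quarters"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted generator parameters, for recovery tests."""

    lam: dict[str, float]
    onset_median: dict[str, float]
    true_signals: tuple[str, ...]

    def to_rows(self) -> list[dict]:
        return [
            {
                "drug": g,
                "lambda": self.lam[g],
                "onset_median_days": self.onset_median[g],
                "is_true_signal": g in self.true_signals,
            }
            for g in sorted(self.lam)
        ]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _quarter_bounds(label: str) -> tuple[date, date]:
    m = re.fullmatch(r"(\d{4})Q([1-4])", label)
    if m is None:
        raise ValueError(f"bad quarter label {label!r}")
    year, q = int(m.group(1)), int(m.group(2))
    start = date(year, 3 * q - 2, 1)
    end_month = 3 * q
    end = date(year, end_month, calendar.monthrange(year, end_month)[1])
    return start, end


def _fmt(d: date | None) -> str:
    return "" if d is None else d.strftime("%Y%m%d")


def sample_onset_days(rng: np.random.Generator, atc: str, size: int | None = None):
    """Draw onset intervals (days, continuous) from the class log-normal."""
    median, sigma = ONSET_BY_CLASS.get(atc, (13.5, 1.5))
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def generate_reports(config: GeneratorConfig) -> tuple[list[RawQuarter], SyntheticTruth]:
    """Generate quarterly record sets plus the planted ground truth."""
    rng = np.random.default_rng(config.seed)
    roster = config.roster
    drug_idx = np.arange(len(roster))

    truth = SyntheticTruth(
        lam={s.generic: s.lam for s in roster},
        onset_median={s.generic: ONSET_BY_CLASS.get(s.atc, (13.5, 1.5))[0] for s in roster},
        true_signals=tuple(
            s.generic for s in roster if s.lam >= config.signal_lambda_threshold
        ),
    )

    quarters = [RawQuarter(quarter=q) for q in config.quarters]
    bounds = [_quarter_bounds(q) for q in config.quarters]
    case_counter = 9_000_000
    pending_dups: list[tuple[int, dict]] = []  # (target quarter index, case payload)

    band_names = list(config.age_bands)
    band_probs = np.array([config.age_bands[b][2] for b in band_names])
    sex_names = list(config.sex_probs)
    sex_probs = np.array(list(config.sex_probs.values()))
    country_names = list(config.country_weights)
    country_probs = np.array(list(config.country_weights.values()))
    country_probs = country_probs / country_probs.sum()
    occ_names = list(config.occupation_probs)
    occ_probs = np.array(list(config.occupation_probs.values()))
    out_names = list(config.outcome_probs)
    out_probs = np.array(list(config.outcome_probs.values()))

    for qi, (rq, (q_start, q_end)) in enumerate(zip(quarters, bounds)):
        n = config.n_reports_per_quarter
        n_days = (q_end - q_start).days + 1
        # one vectorized draw per attribute, consumed in fixed order
        fda_offsets = rng.integers(0, n_days, size=n)
        bands = rng.choice(len(band_names), size=n, p=band_probs)
        sexes = rng.choice(len(sex_names), size=n, p=sex_probs)
        countries = rng.choice(len(country_names), size=n, p=country_probs)
        occs = rng.choice(len(occ_names), size=n, p=occ_probs)
        outcomes = rng.choice(len(out_names), size=n, p=out_probs)
        ps_drugs = rng.choice(drug_idx, size=n)
        n_concom = np.minimum(rng.poisson(0.8, size=n), 2)
        pt_u = rng.random(size=n)
        age_u = rng.random(size=n)
        age_missing_u = rng.random(size=n)
        unit_u = rng.random(size=n)
        trade_u = rng.random(size=n)
        salt_u = rng.random(size=n)
        dup_u = rng.random(size=n)
        start_missing_u = rng.random(size=n)
        event_missing_u = rng.random(size=n)
        neg_u = rng.random(size=n)
        extra_outc_u = rng.random(size=n)
        lag_days = rng.integers(0, 61, size=n)
        n_bg_pts = 1 + rng.poisson(1.0, size=n)

        for i in range(n):
            case_counter += 1
            case_id = str(case_counter)
            primaryid = f"{case_id}1"
            fda_dt = q_start + timedelta(days=int(fda_offsets[i]))

            spec = roster[int(ps_drugs[i])]
            has_pt = pt_u[i] < min(1.0, config.base_rate * spec.lam)

            # demographics
            lo, hi, _ = config.age_bands[band_names[int(bands[i])]]
            age_years = lo + age_u[i] * (hi - lo)
            if age_missing_u[i] < config.age_missing_rate:
                age_val, age_cod = "", ""
            elif unit_u[i] < 0.04:
                age_val, age_cod = f"{age_years / 10:.2f}", "DEC"
            elif unit_u[i] < 0.07:
                age_val, age_cod = str(int(round(age_years * 12))), "MON"
            elif unit_u[i] < 0.10:
                age_val, age_cod = str(int(age_years)), ""  # unit missing: value in years
            else:
                age_val, age_cod = str(int(age_years)), "YR"

            # therapy / event dates
            onset = float(sample_onset_days(rng, spec.atc))
            onset_days = int(onset)  # whole-day dates; same-day onset -> equal dates
            start_dt = fda_dt - timedelta(days=onset_days + int(lag_days[i]))
            event_dt = start_dt + timedelta(days=onset_days)
            if neg_u[i] < config.negative_tto_rate:
                event_dt = start_dt - timedelta(days=3)  # planted data-entry error
            start_s = "" if start_missing_u[i] < config.date_missing_rate else _fmt(start_dt)
            event_s = "" if event_missing_u[i] < config.date_missing_rate else _fmt(event_dt)

            # drug name as reported
            if spec.trades and trade_u[i] < config.trade_name_rate:
                drugname = spec.trades[0]
            else:
                drugname = spec.generic.upper()
                if salt_u[i] < config.salt_suffix_rate:
                    drugname += " HCL"

            outcome_class = out_names[int(outcomes[i])]
            if outcome_class == "OTHER":
                codes = [] if extra_outc_u[i] < 0.1 else ["OT"]
            else:
                codes = [outcome_class]
                if outcome_class in ("DE", "LT") and extra_outc_u[i] < 0.3:
                    codes.append("HO")

            reactions = [TARGET_PT] if has_pt else []
            bg = rng.choice(len(BACKGROUND_PTS), size=int(n_bg_pts[i]), replace=False)
            reactions.extend(BACKGROUND_PTS[int(k)] for k in bg)

            concoms = rng.choice(drug_idx, size=int(n_concom[i]), replace=False)

            payload = {
                "case_id": case_id,
                "demo": {
                    "primaryid": primaryid,
                    "caseid": case_id,
                    "fda_dt": _fmt(fda_dt),
                    "event_dt": event_s,
                    "age": age_val,
                    "age_cod": age_cod,
                    "sex": sex_names[int(sexes[i])],
                    "occp_cod": occ_names[int(occs[i])],
                    "reporter_country": country_names[int(countries[i])],
                },
                "drug": [
                    {
                        "primaryid": primaryid,
                        "caseid": case_id,
                        "drug_seq": "1",
                        "role_cod": "PS",
                        "drugname": drugname,
                        "prod_ai": spec.generic.upper(),
                    }
                ]
                + [
                    {
                        "primaryid": primaryid,
                        "caseid": case_id,
                        "drug_seq": str(2 + k),
                        "role_cod": "C",
                        "drugname": roster[int(ci)].generic.upper(),
                        "prod_ai": roster[int(ci)].generic.upper(),
                    }
                    for k, ci in enumerate(concoms)
                ],
                "reac": [
                    {"primaryid": primaryid, "caseid": case_id, "pt": pt} for pt in reactions
                ],
                "outc": [
                    {"primaryid": primaryid, "caseid": case_id, "outc_cod": c} for c in codes
                ],
                "ther": [
                    {
                        "primaryid": primaryid,
                        "caseid": case_id,
                        "dsg_drug_seq": "1",
                        "start_dt": start_s,
                        "end_dt": "",
                    }
                ],
            }
            rq.demo.append(payload["demo"])
            rq.drug.extend(payload["drug"])
            rq.reac.extend(payload["reac"])
            rq.outc.extend(payload["outc"])
            rq.ther.extend(payload["ther"])

            # duplicate case version: re-emitted ~30 days later (next quarter
            # when one exists) with version-2 primaryid and later receipt date
            if dup_u[i] < config.duplicate_rate:
                dup_fda = fda_dt + timedelta(days=30)
                target_qi = qi + 1 if qi + 1 < len(quarters) else qi
                dup_demo = dict(payload["demo"])
                dup_pid = f"{case_id}2"
                dup_demo["primaryid"] = dup_pid
                dup_demo["fda_dt"] = _fmt(min(dup_fda, bounds[target_qi][1]))
                dup_payload = {
                    "demo": dup_demo,
                    "drug": [dict(r, primaryid=dup_pid) for r in payload["drug"]],
                    "reac": [dict(r, primaryid=dup_pid) for r in payload["reac"]],
                    "outc": [dict(r, primaryid=dup_pid) for r in payload["outc"]],
                    "ther": [dict(r, primaryid=dup_pid) for r in payload["ther"]],
                }
                pending_dups.append((target_qi, dup_payload))

    for target_qi, dup in pending_dups:
        rq = quarters[target_qi]
        rq.demo.append(dup["demo"])
        rq.drug.extend(dup["drug"])
        rq.reac.extend(dup["reac"])
        rq.outc.extend(dup["outc"])
        rq.ther.extend(dup["ther"])

    return quarters, truth


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_TABLE_FIELDS = {
    "demo": (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "occp_cod", "reporter_country",
    ),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
}


def write_faers_ascii(quarters: list[RawQuarter], out_dir: str | Path) -> list[Path]:
    """Write quarters as FAERS-dialect ASCII files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rq in quarters:
        for table, fields in _TABLE_FIELDS.items():
            path = out / f"{quarter_file_stem(table, rq.quarter)}.txt"
            rows = getattr(rq, table)
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("$".join(fields) + "\n")
                for row in rows:
                    fh.write("$".join(str(row.get(f, "")) for f in fields) + "\n")
            written.append(path)
    return written


def write_truth_csv(truth: SyntheticTruth, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["drug", "lambda", "onset_median_days", "is_true_signal"]
        )
        writer.writeheader()
        writer.writerows(truth.to_rows())
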