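"""Drug-name normalization and ATC first-level classification.

Spontaneous reports carry free-text drug names (trade names, salts, dose
forms).  Normalization canonicalizes the string and resolves it to a generic
name through a bundled synonym table; generics are then assigned a WHO ATC
first-level (anatomical main group) letter.  Both tables are two-column CSV
fixtures bundled with the package and overridable at run time.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

#: trailing salt / formulation tokens stripped before lookup (fixed list,
#: deliberately not a greedy regex, so the mapping stays auditable)
SALT_SUFFIXES = ("HCL", "HYDROCHLORIDE", "SULFATE", "TARTRATE", "MALEATE", "SUCCINATE")

#: ATC anatomical main groups
ATC_LABELS = {
    "A": "alimentary tract and metabolism",
    "B": "blood and blood forming organs",
    "C": "cardiovascular system",
    "D": "dermatologicals",
    "G": "genito urinary system and sex hormones",
    "H": "systemic hormonal preparations",
    "J": "antiinfectives for systemic use",
    "L": "antineoplastic and immunomodulating agents",
    "M": "musculo-skeletal system",
    "N": "nervous system",
    "P": "antiparasitic products",
    "R": "respiratory system",
    "S": "sensory organs",
    "V": "various",
}

UNCLASSIFIED = "unclassified"

_PUNCT = re.compile(r"[.,;:()'\"]+")
_WS = re.compile(r"\s+")


def canonicalize_name(raw: str) -> str:
    """Uppercase, trim, collapse punctuation/whitespace, strip trailing salt tokens."""
    s = _PUNCT.sub(" ", str(raw).upper())
    s = _WS.sub(" ", s).strip()
    tokens = s.split(" ")
    while len(tokens) > 1 and tokens[-1] in SALT_SUFFIXES:
        tokens.pop()
    return " ".join(tokens)


@dataclass
class NormalizedDrug:
    name: str
    mapped: bool


@dataclass
class SynonymTable:
    """Canonical raw string -> generic name, with per-entry provenance."""

    mapping: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                raw = canonicalize_name(row["raw"])
                generic = row["generic"].strip()
                if not generic:
                    raise ValueError(f"empty generic for synonym key {raw!r}")
                table.mapping[raw] = generic
                table.provenance[raw] = row.get("source", "")
        return table

    def add(self, raw: str, generic: str, source: str = "") -> None:
        key = canonicalize_name(raw)
        self.mapping[key] = generic.strip()
        self.provenance[key] = source


@dataclass
class AtcTable:
    """Generic name -> ATC first-level letter."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtcTable":
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                code = row["atc_code"].strip().upper()
                if code not in ATC_LABELS:
                    raise ValueError(f"{code!r} is not an ATC first-level letter")
                table.mapping[row["generic"].strip().casefold()] = code
        return table


def default_synonym_table() -> SynonymTable:
    with resources.as_file(resources.files("ssfaers.data") / "synonyms.csv") as p:
        return SynonymTable.from_csv(p)


def default_atc_table() -> AtcTable:
    with resources.as_file(resources.files("ssfaers.data") / "atc.csv") as p:
        return AtcTable.from_csv(p)


def normalize_drug_name(raw: str, synonyms: SynonymTable) -> NormalizedDrug:
    """Resolve a raw drug-name string to a generic name.

    Combination products (names containing '/' or '+') are left unmapped
    unless an exact synonym entry exists, because the suspect ingredient is
    ambiguous.  Unmapped inputs pass through canonicalized with
    ``mapped=False``.
    """
    key = canonicalize_name(raw)
    generic = synonyms.mapping.get(key)
    if generic is not None:
        return NormalizedDrug(name=generic, mapped=True)
    return NormalizedDrug(name=key, mapped=False)


def assign_atc_class(generic: str, atc: AtcTable) -> tuple[str, str]:
    """Return (ATC first-level letter, label), or ('unclassified', 'unclassified')."""
    code = atc.mapping.get(str(generic).strip().casefold())
    if code is None:
        logger.debug("no ATC class for %r", generic)
        return UNCLASSIFIED, UNCLASSIFIED
    return code, ATC_LABELS[code]
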