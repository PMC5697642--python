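"""Controlled vocabularies: drugs, drug classes, approval dates, ICD-10 code maps.

Everything here is data, not logic, so that real-world extracts with different
coding practices can swap in their own maps without touching the pipeline.
"""

from __future__ import annotations

from datetime import date

# ---------------------------------------------------------------------------
# Drugs and classes

DOACS = ("apixaban", "dabigatran", "rivaroxaban")

CLASS_DOAC_PREFIX = "DOAC_"
CLASS_VKA = "VKA"
CLASS_ANTIPLATELET = "antiplatelet"
CLASS_ASPIRIN = "aspirin"
CLASS_NSAID = "NSAID"


def doac_class(drug: str) -> str:
    """Class label for a DOAC, e.g. ``DOAC_apixaban``."""
    if drug not in DOACS:
        raise KeyError(f"not a DOAC: {drug!r}")
    return CLASS_DOAC_PREFIX + drug


def is_doac_class(drug_class: str) -> bool:
    return drug_class.startswith(CLASS_DOAC_PREFIX)


# First approval for stroke prevention in AF (Scotland); month resolution.
APPROVAL_DATES: dict[str, date] = {
    "dabigatran": date(2011, 9, 1),
    "rivaroxaban": date(2012, 1, 1),
    "apixaban": date(2013, 1, 1),
}

# Standard maintenance dosing, tablets/capsules per day, used to estimate
# days' supply when no usable prescriber instruction is recorded.
STANDARD_DAILY_UNITS: dict[str, float] = {
    "dabigatran": 2.0,
    "rivaroxaban": 1.0,
    "apixaban": 2.0,
    "warfarin": 1.0,
}

# Largest daily-unit instruction still considered plausible; instructions
# outside (0, MAX] fall back to standard dosing.
MAX_PLAUSIBLE_DAILY_UNITS = 10.0

# ---------------------------------------------------------------------------
# Interacting co-medication, per index DOAC.
# "Contraindicated": combination should not be used at all.
# "Avoid": combination should be avoided where possible.

CONTRAINDICATED_DRUGS: dict[str, frozenset[str]] = {
    "dabigatran": frozenset({"itraconazole", "ketoconazole"}),
    "rivaroxaban": frozenset(
        {"carbamazepine", "itraconazole", "ketoconazole", "phenytoin", "rifampicin"}
    ),
    "apixaban": frozenset(
        {"carbamazepine", "itraconazole", "ketoconazole", "phenytoin", "rifampicin"}
    ),
}

AVOID_DRUGS: dict[str, frozenset[str]] = {
    "dabigatran": frozenset({"carbamazepine", "clarithromycin", "phenytoin"}),
    "rivaroxaban": frozenset({"clarithromycin"}),
    "apixaban": frozenset({"clarithromycin"}),
}

# ---------------------------------------------------------------------------
# ICD-10 code prefixes.  Membership is by prefix match on the (dot-free)
# code, so "I48" covers I48.0-I48.9, "I481" etc.

AF_CODE_PREFIXES: tuple[str, ...] = ("I48",)

# Default CHA2DS2-VASc component map.  Editable: pass your own mapping of
# component name -> tuple of ICD-10 prefixes to ``cha2ds2_vasc``.
CHA2DS2VASC_CODE_MAP: dict[str, tuple[str, ...]] = {
    "chf": ("I50", "I110"),
    "hypertension": ("I10", "I11", "I12", "I13", "I14", "I15"),
    "diabetes": ("E10", "E11", "E12", "E13", "E14"),
    "stroke_tia": ("I60", "I61", "I62", "I63", "I64", "G45"),
    "vascular": ("I21", "I22", "I70", "I73"),
}

CHA2DS2VASC_COMPONENTS = ("chf", "hypertension", "diabetes", "stroke_tia", "vascular")


def normalise_icd10(code: str) -> str:
    """Upper-case an ICD-10 code and strip the dot: 'i48.1' -> 'I481'."""
    return code.strip().upper().replace(".", "")


def code_matches(code: str, prefixes: tuple[str, ...] | list[str]) -> bool:
    c = normalise_icd10(code)
    return any(c.startswith(normalise_icd10(p)) for p in prefixes)
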