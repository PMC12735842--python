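"""Domain model for individual case safety reports (ICSRs).

A spontaneous adverse-event report carries a registration id, demographics,
reporter metadata, and nested drug / reaction / medical-history sub-records.
Dates in such reports are frequently incomplete (year-only or year-month),
so all date fields are :class:`PartialDate` values rather than calendar
dates; interval arithmetic imputes a missing day as the 15th of the month
and refuses to use dates whose month is unknown.

The :class:`StudyDesign` bundles everything that defines one
disproportionality study: the adverse-event term of interest, the exposure
drug class, positive/negative control drugs, the wider drug class used for
the combined-exposure exclusion, the sensitivity exclusion list, and the
reporting window.
"""

from __future__ import annotations

import calendar
import datetime
import re
from dataclasses import dataclass, field
from enum import Enum

from .countries import is_eu_member

__all__ = [
    "PartialDate",
    "Role",
    "Reporter",
    "Gender",
    "DrugEntry",
    "ReactionEntry",
    "MedicalHistoryEntry",
    "ICSRReport",
    "StudyDesign",
    "GLIPTINS",
    "ANTIHYPERGLYCEMICS",
    "BP_ASSOCIATED_DRUGS",
    "normalize_substance",
]

# Day-of-month imputed when a date is known only to month precision.
# Bounds the error of any single interval endpoint by 15 days.
DAY_IMPUTE = 15

_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")


@dataclass(frozen=True, order=True)
class PartialDate:
    """A possibly incomplete calendar date: year, optional month, optional day.

    Ordering is lexicographic on (year, month, day) with missing components
    sorting first; use :meth:`to_date` for interval arithmetic.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not (1900 <= self.year <= 2100):
            raise ValueError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not (1 <= self.day <= last):
                raise ValueError(
                    f"day out of range for {self.year}-{self.month:02d}: {self.day}"
                )

    @property
    def complete(self) -> bool:
        return self.month is not None and self.day is not None

    @property
    def has_month(self) -> bool:
        return self.month is not None

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse ``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD``."""
        m = _DATE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"unparseable partial date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.isoformat()

    def to_date(self) -> datetime.date | None:
        """Calendar date for interval arithmetic.

        Missing day is imputed as the 15th; a date without a month cannot be
        placed on the calendar and returns ``None``.
        """
        if self.month is None:
            return None
        day = self.day if self.day is not None else DAY_IMPUTE
        return datetime.date(self.year, self.month, day)

    def month_key(self) -> tuple[int, int] | None:
        """(year, month) for window comparisons, or None at year precision."""
        return None if self.month is None else (self.year, self.month)


class Role(str, Enum):
    suspect = "suspect"
    concomitant = "concomitant"


class Reporter(str, Enum):
    physician = "physician"
    other_hcp = "other_hcp"
    pharmacist = "pharmacist"
    consumer = "consumer"
    unknown = "unknown"


class Gender(str, Enum):
    male = "male"
    female = "female"
    unspecified = "unspecified"


_WS_RE = re.compile(r"\s+")


def normalize_substance(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Normalize a substance name: trim, lowercase, collapse whitespace.

    ``synonyms`` optionally maps normalized brand names to substance names
    (applied after normalization).
    """
    s = _WS_RE.sub(" ", name.strip()).lower()
    if synonyms:
        s = synonyms.get(s, s)
    return s


@dataclass(frozen=True)
class DrugEntry:
    """One drug mentioned in a report, with its role and prescription dates."""

    substance: str
    role: Role = Role.suspect
    start: PartialDate | None = None
    end: PartialDate | None = None

    def __post_init__(self) -> None:
        norm = normalize_substance(self.substance)
        if not norm:
            raise ValueError("empty substance name")
        object.__setattr__(self, "substance", norm)
        object.__setattr__(self, "role", Role(self.role))
        if (
            self.start is not None
            and self.end is not None
            and self.start.complete
            and self.end.complete
            and self.end.to_date() < self.start.to_date()
        ):
            raise ValueError(
                f"drug end {self.end} before start {self.start} for {self.substance}"
            )


@dataclass(frozen=True)
class ReactionEntry:
    """One adverse reaction (preferred-term text) with onset/resolution dates."""

    term: str
    onset: PartialDate | None = None
    resolution: PartialDate | None = None

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("empty reaction term")
        object.__setattr__(self, "term", _WS_RE.sub(" ", self.term.strip()))


@dataclass(frozen=True)
class MedicalHistoryEntry:
    condition: str
    diagnosis_year: int | None = None

    def __post_init__(self) -> None:
        if not self.condition.strip():
            raise ValueError("empty history condition")
        object.__setattr__(self, "condition", _WS_RE.sub(" ", self.condition.strip()))


@dataclass
class ICSRReport:
    """One individual case safety report.

    ``eu_member`` is resolved from the bundled country table when not given
    explicitly.
    """

    registration_id: str
    receipt_date: PartialDate
    drugs: list[DrugEntry]
    reactions: list[ReactionEntry]
    country: str = "unknown"
    eu_member: bool | None = None
    reporter: Reporter = Reporter.unknown
    age_years: float | None = None
    gender: Gender = Gender.unspecified
    history: list[MedicalHistoryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.registration_id.strip():
            raise ValueError("empty registration_id")
        if not self.drugs:
            raise ValueError(f"report {self.registration_id}: no drug entries")
        if not self.reactions:
            raise ValueError(f"report {self.registration_id}: no reaction entries")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise ValueError(
                f"report {self.registration_id}: implausible age {self.age_years}"
            )
        self.reporter = Reporter(self.reporter)
        self.gender = Gender(self.gender)
        self.country = self.country.strip().upper() or "UNKNOWN"
        if self.country == "UNKNOWN":
            self.country = "unknown"
        if self.eu_member is None:
            self.eu_member = is_eu_member(self.country)

    def suspect_substances(self) -> set[str]:
        return {d.substance for d in self.drugs if d.role is Role.suspect}

    def all_substances(self) -> set[str]:
        return {d.substance for d in self.drugs}

    def reaction_terms(self) -> set[str]:
        return {r.term.lower() for r in self.reactions}


# DPP-4 inhibitors in the order the study tabulates them.
GLIPTINS: tuple[str, ...] = (
    "vildagliptin",
    "teneligliptin",
    "linagliptin",
    "alogliptin",
    "saxagliptin",
    "sitagliptin",
    "gemigliptin",
    "anagliptin",
    "trelagliptin",
)

# Non-gliptin antihyperglycemic drugs used for the combined-exposure exclusion.
ANTIHYPERGLYCEMICS: frozenset[str] = frozenset(
    {
        "metformin",
        "insulin",
        "glimepiride",
        "gliclazide",
        "glibenclamide",
        "glipizide",
        "tolbutamide",
        "pioglitazone",
        "rosiglitazone",
        "empagliflozin",
        "dapagliflozin",
        "canagliflozin",
        "ertugliflozin",
        "liraglutide",
        "semaglutide",
        "dulaglutide",
        "exenatide",
        "lixisenatide",
        "repaglinide",
        "nateglinide",
        "acarbose",
        "miglitol",
    }
)

# Drugs independently associated with bullous pemphigoid in the literature;
# the sensitivity analysis drops every report mentioning any of them.
BP_ASSOCIATED_DRUGS: tuple[str, ...] = (
    "aspirin",
    "d-penicillamine",
    "enalapril",
    "erlotinib",
    "etanercept",
    "everolimus",
    "furosemide",
    "ibuprofen",
    "levofloxacin",
    "nivolumab",
    "pembrolizumab",
    "phenacetin",
    "psoralens",
    "rifampicin",
    "serratiopeptidase",
    "sirolimus",
    "tetanus toxoid",
)


@dataclass
class StudyDesign:
    """Everything that defines one drug-event disproportionality study."""

    event_term: str = "Pemphigoid"
    exposure_drugs: frozenset[str] = frozenset(GLIPTINS)
    positive_control: str = "furosemide"
    negative_control: str = "paracetamol"
    antihyperglycemic_class: frozenset[str] = ANTIHYPERGLYCEMICS
    sensitivity_exclusion: frozenset[str] = frozenset(BP_ASSOCIATED_DRUGS)
    window_start: PartialDate = PartialDate(2007, 4)
    window_end: PartialDate = PartialDate(2024, 4)

    def __post_init__(self) -> None:
        self.exposure_drugs = frozenset(
            normalize_substance(s) for s in self.exposure_drugs
        )
        self.antihyperglycemic_class = frozenset(
            normalize_substance(s) for s in self.antihyperglycemic_class
        )
        self.sensitivity_exclusion = frozenset(
            normalize_substance(s) for s in self.sensitivity_exclusion
        )
        self.positive_control = normalize_substance(self.positive_control)
        self.negative_control = normalize_substance(self.negative_control)
        for ctrl in (self.positive_control, self.negative_control):
            if ctrl in self.exposure_drugs:
                raise ValueError(f"control drug {ctrl!r} overlaps exposure set")
        if not self._window_ok():
            raise ValueError(
                f"window_start {self.window_start} not before window_end {self.window_end}"
            )

    def _window_ok(self) -> bool:
        a = (self.window_start.year, self.window_start.month or 1)
        b = (self.window_end.year, self.window_end.month or 12)
        return a < b

    @property
    def event_term_norm(self) -> str:
        return self.event_term.strip().lower()

    def to_dict(self) -> dict:
        return {
            "event_term": self.event_term,
            "exposure_drugs": sorted(self.exposure_drugs),
            "positive_control": self.positive_control,
            "negative_control": self.negative_control,
            "antihyperglycemic_class": sorted(self.antihyperglycemic_class),
            "sensitivity_exclusion": sorted(self.sensitivity_exclusion),
            "window_start": self.window_start.isoformat(),
            "window_end": self.window_end.isoformat(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        kwargs = dict(d)
        for key in ("exposure_drugs", "antihyperglycemic_class", "sensitivity_exclusion"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        for key in ("window_start", "window_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = PartialDate.parse(kwargs[key])
        return cls(**kwargs)
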