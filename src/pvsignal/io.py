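"""Readers and writers for the project's tabular ICSR dialect and margins CSV.

ICSR TSV dialect
----------------
One row per report, UTF-8, LF line endings, tab-separated, mandatory header::

    registration_id  receipt_date  country  reporter  age_years  gender  drugs  reactions  history

The last three columns hold semicolon-separated sub-records whose fields are
pipe-separated, e.g. ``vildagliptin|suspect|2019-03|2020-02`` for a drug
(substance, role, start, end), ``Pemphigoid|2020-01|2020-06`` for a reaction
(term, onset, resolution) and ``type 2 diabetes mellitus|2011`` for history
(condition, diagnosis year).  Empty fields stay empty; dates are partial
(``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD``).

Aggregated-margin CSV
---------------------
Global totals in a leading ``#key=value`` block, then a CSV body::

    #event_total=5215
    #grand_total=11451738
    drug,a,drug_total
    vildagliptin,595,2722

``a`` is the number of event reports mentioning the drug and ``drug_total``
the total number of reports mentioning the drug (see
:func:`pvsignal.stats.contingency_from_margins` for the cell reconstruction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .model import (
    DrugEntry,
    Gender,
    ICSRReport,
    MedicalHistoryEntry,
    PartialDate,
    ReactionEntry,
    Reporter,
    Role,
)

__all__ = [
    "ICSR_COLUMNS",
    "ParseResult",
    "read_icsr_table",
    "write_icsr_table",
    "MarginRecord",
    "MarginTable",
    "read_margins",
    "write_margins",
]

logger = logging.getLogger(__name__)

ICSR_COLUMNS = (
    "registration_id",
    "receipt_date",
    "country",
    "reporter",
    "age_years",
    "gender",
    "drugs",
    "reactions",
    "history",
)

_SUB = ";"
_FIELD = "|"


@dataclass
class ParseResult:
    """Reports plus the row-level problems met while parsing them.

    ``warnings`` are recoverable field issues (the report was still built);
    ``bad_rows`` are rows that could not become a report: (line number,
    reason).  Iterating a ParseResult iterates its reports.
    """

    reports: list[ICSRReport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    bad_rows: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[ICSRReport]:
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)


def _parse_date(text: str, where: str, warnings: list[str]) -> PartialDate | None:
    if not text:
        return None
    try:
        return PartialDate.parse(text)
    except ValueError:
        warnings.append(f"{where}: unparseable partial date {text!r}; field left absent")
        return None


def _parse_drugs(cell: str, where: str, warnings: list[str]) -> list[DrugEntry]:
    out: list[DrugEntry] = []
    for token in filter(None, cell.split(_SUB)):
        parts = (token.split(_FIELD) + ["", "", ""])[:4]
        substance, role, start, end = (p.strip() for p in parts)
        try:
            out.append(
                DrugEntry(
                    substance=substance,
                    role=Role(role) if role else Role.suspect,
                    start=_parse_date(start, where, warnings),
                    end=_parse_date(end, where, warnings),
                )
            )
        except ValueError as exc:
            warnings.append(f"{where}: bad drug sub-record {token!r} ({exc}); dropped")
    return out


def _parse_reactions(cell: str, where: str, warnings: list[str]) -> list[ReactionEntry]:
    out: list[ReactionEntry] = []
    for token in filter(None, cell.split(_SUB)):
        parts = (token.split(_FIELD) + ["", ""])[:3]
        term, onset, resolution = (p.strip() for p in parts)
        try:
            out.append(
                ReactionEntry(
                    term=term,
                    onset=_parse_date(onset, where, warnings),
                    resolution=_parse_date(resolution, where, warnings),
                )
            )
        except ValueError as exc:
            warnings.append(f"{where}: bad reaction sub-record {token!r} ({exc}); dropped")
    return out


def _parse_history(cell: str, where: str, warnings: list[str]) -> list[MedicalHistoryEntry]:
    out: list[MedicalHistoryEntry] = []
    for token in filter(None, cell.split(_SUB)):
        parts = (token.split(_FIELD) + [""])[:2]
        condition, year = (p.strip() for p in parts)
        try:
            out.append(
                MedicalHistoryEntry(
                    condition=condition,
                    diagnosis_year=int(year) if year else None,
                )
            )
        except ValueError as exc:
            warnings.append(f"{where}: bad history sub-record {token!r} ({exc}); dropped")
    return out


def read_icsr_table(path: str | Path) -> ParseResult:
    """Read the ICSR TSV dialect.

    Malformed rows are collected into ``bad_rows`` rather than silently
    dropped; recoverable field problems (an unparseable age or date) leave
    the field absent and add a warning.  A missing mandatory column is a
    hard error naming the column.
    """
    path = Path(path)
    result = ParseResult()
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t") if header_line else []
        for col in ICSR_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        idx = {col: header.index(col) for col in ICSR_COLUMNS}
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            cells = raw.split("\t")
            if len(cells) < len(header):
                cells += [""] * (len(header) - len(cells))
            row = {col: cells[i] for col, i in idx.items()}
            where = f"{path.name}:{lineno}"
            warns: list[str] = []

            receipt = _parse_date(row["receipt_date"], where, warns)
            if receipt is None:
                result.bad_rows.append((lineno, "missing or unparseable receipt_date"))
                result.warnings.extend(warns)
                continue

            age: float | None = None
            if row["age_years"]:
                try:
                    age = float(row["age_years"])
                except ValueError:
                    warns.append(
                        f"{where}: unparseable age {row['age_years']!r}; field left absent"
                    )
            try:
                reporter = Reporter(row["reporter"]) if row["reporter"] else Reporter.unknown
            except ValueError:
                warns.append(f"{where}: unknown reporter {row['reporter']!r}; set to unknown")
                reporter = Reporter.unknown
            try:
                gender = Gender(row["gender"]) if row["gender"] else Gender.unspecified
            except ValueError:
                warns.append(f"{where}: unknown gender {row['gender']!r}; set to unspecified")
                gender = Gender.unspecified

            try:
                report = ICSRReport(
                    registration_id=row["registration_id"].strip(),
                    receipt_date=receipt,
                    country=row["country"] or "unknown",
                    reporter=reporter,
                    age_years=age,
                    gender=gender,
                    drugs=_parse_drugs(row["drugs"], where, warns),
                    reactions=_parse_reactions(row["reactions"], where, warns),
                    history=_parse_history(row["history"], where, warns),
                )
            except ValueError as exc:
                result.bad_rows.append((lineno, str(exc)))
                result.warnings.extend(warns)
                continue
            result.reports.append(report)
            result.warnings.extend(warns)
    for w in result.warnings:
        logger.warning(w)
    return result


def _fmt_date(d: PartialDate | None) -> str:
    return "" if d is None else d.isoformat()


def _check_clean(text: str, what: str) -> str:
    if _SUB in text or _FIELD in text or "\t" in text:
        raise ValueError(f"{what} {text!r} contains a dialect delimiter")
    return text


def _drug_cell(drugs: list[DrugEntry]) -> str:
    return _SUB.join(
        _FIELD.join(
            [
                _check_clean(d.substance, "substance"),
                d.role.value,
                _fmt_date(d.start),
                _fmt_date(d.end),
            ]
        )
        for d in drugs
    )


def _reaction_cell(reactions: list[ReactionEntry]) -> str:
    return _SUB.join(
        _FIELD.join(
            [_check_clean(r.term, "term"), _fmt_date(r.onset), _fmt_date(r.resolution)]
        )
        for r in reactions
    )


def _history_cell(history: list[MedicalHistoryEntry]) -> str:
    return _SUB.join(
        _FIELD.join(
            [
                _check_clean(h.condition, "condition"),
                "" if h.diagnosis_year is None else str(h.diagnosis_year),
            ]
        )
        for h in history
    )


def write_icsr_table(reports: list[ICSRReport], path: str | Path) -> None:
    """Write reports in the ICSR TSV dialect, ordered by registration_id."""
    path = Path(path)
    lines = ["\t".join(ICSR_COLUMNS)]
    for r in sorted(reports, key=lambda r: r.registration_id):
        age = "" if r.age_years is None else f"{r.age_years:g}"
        lines.append(
            "\t".join(
                [
                    r.registration_id,
                    r.receipt_date.isoformat(),
                    r.country,
                    r.reporter.value,
                    age,
                    r.gender.value,
                    _drug_cell(r.drugs),
                    _reaction_cell(r.reactions),
                    _history_cell(r.history),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


@dataclass(frozen=True)
class MarginRecord:
    """Per-drug margins: event-report count ``a`` and total report count."""

    drug: str
    a: int
    drug_total: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.drug_total < 0:
            raise ValueError(f"{self.drug}: negative count")
        if self.a > self.drug_total:
            raise ValueError(
                f"{self.drug}: a={self.a} exceeds drug_total={self.drug_total}"
            )


@dataclass(frozen=True)
class MarginTable:
    """Aggregated margins: per-drug records plus database-wide totals."""

    records: tuple[MarginRecord, ...]
    event_total: int
    grand_total: int

    def __post_init__(self) -> None:
        if self.event_total < 0 or self.grand_total < 0:
            raise ValueError("negative global total")
        for rec in self.records:
            if rec.a > self.event_total:
                raise ValueError(
                    f"{rec.drug}: a={rec.a} exceeds event_total={self.event_total}"
                )

    def record(self, drug: str) -> MarginRecord:
        for rec in self.records:
            if rec.drug == drug:
                return rec
        raise KeyError(drug)


def read_margins(path: str | Path) -> MarginTable:
    """Read the aggregated-margin CSV (``#key=value`` globals then CSV body)."""
    path = Path(path)
    event_total = grand_total = None
    records: list[MarginRecord] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                key = key.strip()
                if key == "event_total":
                    event_total = int(value)
                elif key == "grand_total":
                    grand_total = int(value)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown global {key!r}")
                continue
            cells = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cells != ["drug", "a", "drug_total"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'drug,a,drug_total', got {line!r}"
                    )
                header_seen = True
                continue
            drug, a, drug_total = cells[0], int(cells[1]), int(cells[2])
            records.append(MarginRecord(drug=drug, a=a, drug_total=drug_total))
    if event_total is None or grand_total is None:
        raise ValueError(f"{path}: missing #event_total= or #grand_total= global")
    if not header_seen:
        raise ValueError(f"{path}: missing CSV header")
    return MarginTable(
        records=tuple(records), event_total=event_total, grand_total=grand_total
    )


def write_margins(margins: MarginTable, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"#event_total={margins.event_total}",
        f"#grand_total={margins.grand_total}",
        "drug,a,drug_total",
    ]
    lines += [f"{r.drug},{r.a},{r.drug_total}" for r in margins.records]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
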