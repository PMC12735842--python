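"""Cohort construction: deduplication, eligibility filtering, classification.

The pipeline is deduplicate -> apply_exclusions -> classify.  Exclusions
mirror a single-suspect disproportionality design: reports outside the
reporting window, reports exposed to more than one drug of the exposure
class, reports combining an exposure drug with any other drug of the wider
therapeutic class, and reports whose medical history already contains the
event before it was reported as a reaction.  Every removal is accounted for
in an :class:`ExclusionLog` (a report may trip several reasons; it is
recorded under each but removed once).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import ICSRReport, Role, StudyDesign

__all__ = [
    "ExclusionLog",
    "ClassifiedReport",
    "deduplicate",
    "apply_exclusions",
    "classify",
    "build_cohort",
]

EXCLUSION_REASONS = (
    "duplicate",
    "outside_window",
    "multi_gliptin",
    "gliptin_plus_antihyperglycemic",
    "prior_bp_history",
)


@dataclass
class ExclusionLog:
    """Registration ids removed per exclusion reason."""

    excluded_ids: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in EXCLUSION_REASONS}
    )

    @property
    def counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.excluded_ids.items()}

    @property
    def n_removed(self) -> int:
        """Number of distinct reports removed (a report counts once)."""
        return len({i for ids in self.excluded_ids.values() for i in ids})

    def add(self, reason: str, registration_id: str) -> None:
        self.excluded_ids.setdefault(reason, []).append(registration_id)

    def merged(self, other: "ExclusionLog") -> "ExclusionLog":
        out = ExclusionLog()
        for log in (self, other):
            for reason, ids in log.excluded_ids.items():
                out.excluded_ids.setdefault(reason, []).extend(ids)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "excluded_ids": self.excluded_ids}, indent=2
        )


@dataclass(frozen=True)
class ClassifiedReport:
    """A report labeled on both study axes: case/control and exposed/unexposed.

    ``exposure_drug`` is the single exposure-class substance among the
    suspect drugs when exposed, else None.
    """

    report: ICSRReport
    is_case: bool
    exposed: bool
    exposure_drug: str | None = None

    def __post_init__(self) -> None:
        if self.exposed and not self.exposure_drug:
            raise ValueError("exposed report without exposure_drug")
        if not self.exposed and self.exposure_drug:
            raise ValueError("exposure_drug set on unexposed report")


def _receipt_sort_key(r: ICSRReport) -> tuple:
    # Earliest complete receipt date wins; incomplete dates sort after any
    # complete one so ties fall back to file order.
    d = r.receipt_date
    if d.complete:
        return (0, d.year, d.month, d.day)
    return (1,)


def deduplicate(reports: list[ICSRReport]) -> tuple[list[ICSRReport], ExclusionLog]:
    """Keep one report per registration id.

    The kept report is the one with the earliest complete receipt date,
    ties broken by file order; the others are logged as duplicates.
    """
    log = ExclusionLog()
    best: dict[str, tuple[tuple, int]] = {}
    for pos, r in enumerate(reports):
        key = _receipt_sort_key(r)
        rid = r.registration_id
        if rid not in best or (key, pos) < best[rid]:
            best[rid] = (key, pos)
    keep_pos = {pos for _, pos in best.values()}
    kept: list[ICSRReport] = []
    for pos, r in enumerate(reports):
        if pos in keep_pos:
            kept.append(r)
        else:
            log.add("duplicate", r.registration_id)
    return kept, log


def _within_window(r: ICSRReport, design: StudyDesign) -> bool:
    # Month-precision comparison; a year-only receipt date is compared by
    # year alone (kept when the year overlaps the window at all).
    key = r.receipt_date.month_key()
    ws = (design.window_start.year, design.window_start.month or 1)
    we = (design.window_end.year, design.window_end.month or 12)
    if key is None:
        return ws[0] <= r.receipt_date.year <= we[0]
    return ws <= key <= we


def _suspect_exposures(r: ICSRReport, design: StudyDesign) -> set[str]:
    return r.suspect_substances() & design.exposure_drugs


def _earliest_onset_year(r: ICSRReport, design: StudyDesign) -> int | None:
    years = [
        rx.onset.year
        for rx in r.reactions
        if rx.term.lower() == design.event_term_norm and rx.onset is not None
    ]
    if years:
        return min(years)
    return r.receipt_date.year  # fallback: the event cannot postdate receipt


def apply_exclusions(
    reports: list[ICSRReport], design: StudyDesign
) -> tuple[list[ICSRReport], ExclusionLog]:
    """Apply the eligibility exclusions; idempotent on its own output.

    Checked per report, in order: outside the reporting window (receipt
    date), two or more distinct exposure-class suspect drugs, one exposure
    drug combined with any other drug of the therapeutic class (any role),
    and a history entry matching the event term diagnosed strictly before
    the earliest event onset year.
    """
    log = ExclusionLog()
    kept: list[ICSRReport] = []
    for r in reports:
        reasons: list[str] = []
        if not _within_window(r, design):
            reasons.append("outside_window")
        exposures = _suspect_exposures(r, design)
        if len(exposures) >= 2:
            reasons.append("multi_gliptin")
        if exposures and (r.all_substances() & design.antihyperglycemic_class):
            reasons.append("gliptin_plus_antihyperglycemic")
        if _has_prior_event_history(r, design):
            reasons.append("prior_bp_history")
        if reasons:
            for reason in reasons:
                log.add(reason, r.registration_id)
        else:
            kept.append(r)
    return kept, log


def _has_prior_event_history(r: ICSRReport, design: StudyDesign) -> bool:
    term = design.event_term_norm
    onset_year = _earliest_onset_year(r, design)
    for h in r.history:
        if term in h.condition.lower():
            if h.diagnosis_year is None:
                continue
            if onset_year is None or h.diagnosis_year < onset_year:
                return True
    return False


def classify(
    reports: list[ICSRReport], design: StudyDesign
) -> list[ClassifiedReport]:
    """Label every report as case/control and exposed/unexposed.

    A case has a reaction term equal (case-insensitively) to the event
    term; exposure is at least one exposure-class drug among the suspect
    drugs.  Expects filtered input: a report still carrying two distinct
    exposure drugs raises, since its single exposure drug is undefined.
    """
    term = design.event_term_norm
    out: list[ClassifiedReport] = []
    for r in reports:
        exposures = _suspect_exposures(r, design)
        if len(exposures) > 1:
            raise ValueError(
                f"report {r.registration_id} has {len(exposures)} exposure drugs; "
                "run apply_exclusions first"
            )
        is_case = term in r.reaction_terms()
        exposed = bool(exposures)
        out.append(
            ClassifiedReport(
                report=r,
                is_case=is_case,
                exposed=exposed,
                exposure_drug=next(iter(exposures)) if exposed else None,
            )
        )
    return out


def build_cohort(
    reports: list[ICSRReport], design: StudyDesign
) -> tuple[list[ClassifiedReport], ExclusionLog]:
    """Full pipeline: deduplicate, exclude, classify; returns the merged log."""
    deduped, dlog = deduplicate(reports)
    filtered, xlog = apply_exclusions(deduped, design)
    return classify(filtered, design), dlog.merged(xlog)
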